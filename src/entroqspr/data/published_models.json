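[
  {"property": "MW", "family": "cubic", "descriptor": "Ent_ISI", "a": 323.0, "b": [18.4, -75.9, 24.7]},
  {"property": "C", "family": "cubic", "descriptor": "Ent_F", "a": 756.7, "b": [4.4, -309.8, 88.3]},
  {"property": "C", "family": "cubic", "descriptor": "Ent_R", "a": 724.6, "b": [2.1, -295.3, 84.4]},
  {"property": "MV", "family": "cubic", "descriptor": "Ent_SO", "a": 257.0, "b": [15.6, -73.0, 22.1]},
  {"property": "P", "family": "cubic", "descriptor": "Ent_ABC", "a": 15.2, "b": [2.3, -6.2, 2.4]},
  {"property": "P", "family": "cubic", "descriptor": "Ent_R", "a": 13.8, "b": [1.7, -5.8, 2.4]},
  {"property": "MR", "family": "cubic", "descriptor": "Ent_ISI", "a": 47.3, "b": [4.6, -16.4, 6.3]},
  {"property": "MR", "family": "cubic", "descriptor": "Ent_R", "a": 46.6, "b": [3.7, -16.3, 6.2]}
]
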
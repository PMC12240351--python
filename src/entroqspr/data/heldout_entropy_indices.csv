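compound,Ent_ABC,Ent_F,Ent_GA,Ent_H,Ent_ISI,Ent_M1,Ent_M2,Ent_S,Ent_SO,Ent_R
Erbitux,3.04,2.9432,3.042,3.028,3.01,3.025,2.939,3.04,3.025,3.024
Larotrectinib,3.55,3.524,3.55,3.54,3.538,3.545,3.505,3.55,3.547,3.54
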
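compound,MW,C,TSA,P,MR
Erbitux,273.37,375,40.5,27.5,69.5
Larotrectinib,428.4,659,86,41.61,122.96
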
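compound,MW,TSA,C,D,MV,P,MR
Adagrasib,604.1,88.8,1060,1.3,466.2,64.8,166.79
Bisoxatin,333.3,78.8,458,1.4,243.5,36.3,91.5
Capecitabine,359.35,121,582,1.59,240.5,32.6,82.3
Carboplatin,371.25,82.3,153,1.7,218,18.27,60.04
Docetaxel,807.9,224,1660,1.4,585.7,81.4,205.2
Fluorouracil,130.08,58.2,199,1.5,84.6,9.46,26.17
Fruquintinib,393.4,95.7,579,1.3,302.1,43.1,108.7
Irinotecan HCl,623.1,113,1200,1.4,416.8,63.1,159.1
Leucovorin Ca,511.5,221,900,1.81,281,46.33,126.66
Olsalazine,302.24,140,415,1.6,194.1,29,73.2
Oxaliplatin,397.3,132,124,1.5,265,21.9,67.52
Regorafenib,482.8,92.4,686,1.5,323.7,44.8,113.1
Tipiracil,242.66,85.3,404,1.7,141.4,22.7,57.2
Trifluridine,296.2,99.1,464,1.6,179.9,22.2,55.9
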
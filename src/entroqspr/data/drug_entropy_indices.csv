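compound,Ent_ABC,Ent_F,Ent_GA,Ent_H,Ent_ISI,Ent_M1,Ent_M2,Ent_S,Ent_SO,Ent_R
Adagrasib,3.8696,3.8292,3.87,3.8571,3.8504,3.8582,3.81,3.8677,3.8601,3.8528
Bisoxatin,3.3305,3.2658,3.3315,3.3177,3.2823,3.3154,3.253,3.3284,3.3163,3.3147
Capecitabine,3.2554,3.2124,3.256,3.2412,3.1868,3.242,3.1729,3.2539,3.246,3.2337
Carboplatin,2.635,2.4352,3.3295,2.6199,2.602,2.62,2.539,2.634,2.622,2.614
Docetaxel,4.1384,4.0772,4.1404,4.1251,4.1041,4.1237,4.0354,4.1385,4.1264,4.1177
Fluorouracil,2.194,2.1717,2.888,2.188,2.169,2.187,2.1284,2.1948,2.1909,2.1795
Fruquintinib,3.4646,3.4192,3.4651,3.44501,3.4353,3.4501,3.4002,3.4609,3.4523,3.4401
Irinotecan HCl,3.8901,3.8369,3.8909,3.8733,3.868,3.8757,3.8212,3.8874,3.8772,3.8695
Leucovorin Ca,3.5813,3.5476,3.5822,3.57,3.5582,3.5711,3.5164,3.5801,3.5634,3.5634
Olsalazine,3.1328,3.1049,3.1338,3.1247,3.1082,3.1242,3.0663,3.1327,3.1278,3.1168
Oxaliplatin,2.8317,2.7843,2.8323,2.8198,2.816,2.82,2.7807,2.8299,2.8204,2.8169
Regorafenib,3.5523,3.5161,3.5532,3.543,3.5316,3.5442,3.4946,3.5523,3.5451,3.4903
Tipiracil,2.8306,2.8043,2.8317,2.823,2.8077,2.8226,2.7686,2.8306,2.8259,2.8151
Trifluridine,3.0391,3.0028,3.0416,3.0315,3.0084,3.0302,2.9596,3.0404,3.033,3.019
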
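du,dv,count
1,3,2
2,3,6
2,2,3
2,4,4
3,3,2
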
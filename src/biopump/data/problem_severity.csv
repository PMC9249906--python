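code,severe,label
0,0,no notable constraint
1,1,too cold (permafrost or very short growing season)
2,1,too dry (hyper-arid)
3,1,steep terrain (slope greater than 30 percent)
4,1,shallow soil over bedrock
5,1,poorly drained or waterlogged
6,1,saline or sodic soil
7,1,acid sulphate soil
8,1,peat or organic soil
9,0,moderate fertility constraint
10,0,moderate texture constraint
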
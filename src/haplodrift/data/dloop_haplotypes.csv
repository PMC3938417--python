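haplotype_id,Europe,Denmark,France,Germany,Sweden,Asia,China,Japan,Vietnam,Africa,Egypt,North America,USA,French Polynesia,Society Islands,Tubai,Inbred strains,All
D1,123,0,11,112,0,0,0,0,0,0,0,1,1,2,1,1,0,126
D2,25,0,0,25,0,0,0,0,0,0,0,0,0,0,0,0,0,25
D3,1,0,0,1,0,0,0,0,0,0,0,1,1,0,0,0,12,14
D4,3,0,0,3,0,0,0,0,0,0,0,0,0,0,0,0,0,3
D5,6,0,4,1,1,1,0,1,0,1,1,0,0,1,1,0,1,10
D6,8,0,0,8,0,0,0,0,0,0,0,0,0,0,0,0,0,8
D7,3,0,0,3,0,0,0,0,0,0,0,0,0,0,0,0,0,3
D8,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1
D9,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1
D10,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
D11,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
D12,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
D13,0,0,0,0,0,1,0,0,1,0,0,0,0,0,0,0,0,1
D14,0,0,0,0,0,5,5,0,0,0,0,0,0,0,0,0,0,5
D15,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,1
D16,0,0,0,0,0,7,7,0,0,0,0,0,0,0,0,0,0,7
D17,0,0,0,0,0,4,4,0,0,0,0,0,0,0,0,0,0,4
D18,0,0,0,0,0,8,8,0,0,0,0,0,0,0,0,0,0,8
D19,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,1
D20,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,1
D21,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,1
D22,0,0,0,0,0,2,2,0,0,0,0,0,0,0,0,0,0,2
D23,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,6,6
D24,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,6,6
D25,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,2,2
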
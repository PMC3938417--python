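haplotype_id,Europe,Denmark,France,Germany,Sweden,Asia,Cambodia,China,Indonesia,Japan,Thailand,Vietnam,Africa,South Africa,North America,USA,French Polynesia,Society Islands,Inbred strains,All
C1,43,0,9,34,0,0,0,0,0,0,0,0,0,0,1,1,1,1,0,45
C2,1,0,0,1,0,1,0,0,0,1,0,0,12,12,0,0,0,0,1,15
C3,6,0,4,1,1,5,0,5,0,0,0,0,22,22,0,0,1,1,1,35
C4,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
C5,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
C6,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
C7,0,0,0,0,0,1,0,0,0,1,0,0,0,0,0,0,0,0,0,1
C8,0,0,0,0,0,6,0,6,0,0,0,0,0,0,0,0,0,0,0,6
C9,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C10,0,0,0,0,0,2,0,2,0,0,0,0,0,0,0,0,0,0,0,2
C11,0,0,0,0,0,6,0,6,0,0,0,0,0,0,0,0,0,0,0,6
C12,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C13,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C14,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C15,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C16,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C17,0,0,0,0,0,4,0,4,0,0,0,0,0,0,0,0,0,0,0,4
C18,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C19,0,0,0,0,0,4,0,4,0,0,0,0,0,0,0,0,0,0,0,4
C20,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C21,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C22,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C23,0,0,0,0,0,2,0,2,0,0,0,0,0,0,0,0,0,0,0,2
C24,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C25,0,0,0,0,0,2,0,2,0,0,0,0,0,0,0,0,0,0,0,2
C26,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C27,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C28,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C29,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C30,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,1
C31,0,0,0,0,0,8,0,0,0,0,2,6,0,0,0,0,0,0,0,8
C32,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,1
C33,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,1
C34,0,0,0,0,0,2,1,0,0,0,0,1,0,0,0,0,0,0,0,2
C35,0,0,0,0,0,1,0,0,0,0,1,0,0,0,0,0,0,0,0,1
C36,0,0,0,0,0,1,0,0,1,0,0,0,0,0,0,0,0,0,0,1
C37,0,0,0,0,0,0,0,0,0,0,0,0,2,2,0,0,0,0,0,2
C38,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,1
C39,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,3,3
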
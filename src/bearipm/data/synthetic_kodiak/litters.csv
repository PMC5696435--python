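litter_id,mother_id,year,litter_age,size,weaned
SL0000,k0000,1,0,3,0
SL0000,k0000,2,1,3,0
SL0000,k0000,3,2,3,1
SL0001,k0000,7,0,1,0
SL0001,k0000,8,1,0,0
SL0002,k0003,0,0,1,0
SL0002,k0003,1,1,1,0
SL0002,k0003,2,2,1,1
SL0003,k0003,2,0,5,0
SL0003,k0003,3,1,1,0
SL0003,k0003,4,2,1,1
SL0004,k0003,5,0,1,0
SL0004,k0003,6,1,1,0
SL0004,k0003,7,2,1,1
SL0005,k0003,7,0,2,0
SL0005,k0003,8,1,2,0
SL0005,k0003,9,2,2,0
SL0006,k0005,2,0,3,0
SL0006,k0005,3,1,2,0
SL0006,k0005,4,2,2,1
SL0007,k0005,8,0,3,0
SL0007,k0005,9,1,2,0
SL0008,k0008,1,0,1,0
SL0008,k0008,2,1,1,0
SL0008,k0008,3,2,1,0
SL0008,k0008,4,3,1,0
SL0008,k0008,5,4,1,1
SL0009,k0008,6,0,5,0
SL0009,k0008,7,1,2,0
SL0009,k0008,8,2,0,0
SL0010,k0008,8,0,1,0
SL0010,k0008,9,1,1,0
SL0011,k0009,4,0,2,0
SL0011,k0009,5,1,1,0
SL0011,k0009,6,2,1,1
SL0012,k0009,8,0,2,0
SL0012,k0009,9,1,2,0
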
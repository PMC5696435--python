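id,year,sex,age,detected,recovered_dead,repro_status,dependent_young_age
k0000,1,f,10,1,0,0,
k0000,2,f,11,0,0,0,1
k0000,3,f,12,1,0,0,
k0000,4,f,13,1,0,0,
k0000,5,f,14,1,0,0,
k0000,6,f,15,1,0,0,
k0000,7,f,16,0,0,1,
k0000,8,f,17,1,0,0,
k0000,9,f,18,1,0,1,
k0001,5,m,4,1,0,,
k0001,6,m,5,1,0,,
k0001,7,m,6,1,0,,
k0001,8,m,7,1,0,,
k0001,9,m,8,1,0,,
k0002,7,f,5,1,0,0,
k0002,8,f,6,1,0,0,
k0002,9,f,7,1,0,1,
k0003,0,f,7,1,0,0,
k0003,1,f,8,1,0,0,1
k0003,2,f,9,1,0,0,
k0003,3,f,10,1,0,0,1
k0003,4,f,11,0,0,0,
k0003,5,f,12,0,0,1,
k0003,6,f,13,1,0,0,1
k0003,7,f,14,1,0,1,
k0003,8,f,15,1,0,0,1
k0003,9,f,16,1,0,0,
k0004,3,m,13,1,0,,
k0004,4,m,14,1,0,,
k0004,5,m,15,1,0,,
k0004,6,m,16,1,0,,
k0004,7,m,17,1,0,,
k0004,8,m,18,1,0,,
k0004,9,m,19,1,0,,
k0005,0,f,3,1,0,,
k0005,1,f,4,1,0,,
k0005,2,f,5,1,0,1,
k0005,3,f,6,1,0,0,1
k0005,4,f,7,0,0,0,
k0005,5,f,8,1,0,0,
k0005,6,f,9,1,0,0,
k0005,7,f,10,1,0,0,
k0005,8,f,11,1,0,1,
k0005,9,f,12,1,0,0,
k0006,4,f,16,1,0,0,
k0006,5,f,17,1,0,0,1
k0006,6,f,18,1,0,0,1
k0006,7,f,19,1,0,0,1
k0006,8,f,20,1,1,0,
k0007,2,f,14,1,0,0,
k0007,3,f,15,1,0,0,1
k0007,4,f,16,1,1,0,
k0008,1,f,8,1,0,1,
k0008,2,f,9,1,0,0,1
k0008,3,f,10,1,0,0,1
k0008,4,f,11,0,0,0,1
k0008,5,f,12,1,0,0,
k0008,6,f,13,1,0,1,
k0008,7,f,14,1,0,0,1
k0008,8,f,15,1,0,0,
k0008,9,f,16,1,0,0,
k0009,4,f,9,1,0,0,
k0009,5,f,10,0,0,0,1
k0009,6,f,11,1,0,0,
k0009,7,f,12,1,0,0,
k0009,8,f,13,1,0,1,
k0009,9,f,14,0,0,0,
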
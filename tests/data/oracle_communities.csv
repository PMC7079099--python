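site,t7,t2,t10,t6,t4,t5,t3,t1,t9,t8
site_1,1,1,0,0,0,1,1,0,0,0
site_2,1,1,1,0,1,0,0,0,0,0
site_3,1,0,0,0,1,0,0,1,0,1
site_4,0,1,1,0,0,1,0,0,0,1
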
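species,trait_1,trait_2
t7,-2.968344159552978,1.8169556056529799
t2,-1.2027002731722298,5.602307149444096
t10,-2.1906733133952634,4.798630118556265
t6,-1.5291410104125727,4.28646989402502
t4,-1.5995851788435753,2.6570952368034066
t5,0.9519162665174729,0.30617294827821073
t3,2.1486215176376917,-0.4324486869440909
t1,1.6963571887713729,-1.0563657358665814
t9,3.6255148425748702,1.6963285580189933
t8,-3.5152220933312854,1.8771018525842638
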
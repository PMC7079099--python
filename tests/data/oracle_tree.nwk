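(((t7:5.155059426,(((t2:1.341934559,t10:1.341934559)nd6:0.4370740109,t6:1.77900857)nd5:2.960511723,t4:4.739520293)nd4:0.4155391335)nd2:3.359316139,((t5:1.161280894,(t3:0.4006609101,t1:0.4006609101)nd14:0.7606199842)nd12:2.05581314,t9:3.217094034)nd11:5.297281531)nd1:1.485624435,t8:10)nd0;
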
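(((((Mmul:5.5,Mfus:5.5)10:1.5,Mnig:7)9:3.5,(Panu:4.5,Pham:4.5)11:6)4:1,(Cmit:9,(Csab:8.5,Epat:8.5)13:0.5)12:2.5)2:6.1,(Cpol:12.3,Sent:12.3)3:5.3)1:5;
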
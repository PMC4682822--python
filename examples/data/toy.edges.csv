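pre,post,type,count
INT1,SENS1,chem,2
INT1,MOT1,chem,1
MOT1,INT1,chem,1
INT2,MOT2,chem,3
SENS2,INT2,chem,1
INT1,INT2,gap,2
SENS1,MOT1,chem,1
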
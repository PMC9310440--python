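id,atp,opa1,mfn1,mfn2,drp1,fis1,db,os,ht,ob,dp,pa,diet,age,fusion,fission,AD
1,0,0,0,0,0,0,1,0,1,0,1,0,HFO,63,0,0,0.2
2,1,1,1,1,0,1,1,0,0,1,0,1,HL,31,1,1,0.614
3,1,0,1,0,0,0,0,0,0,1,1,0,starv,70,0,0,0.278
4,1,1,0,1,0,1,0,0,1,0,1,1,CR,86,1,1,0.614
5,0,0,0,0,0,0,1,0,1,0,0,0,0,80,0,0,0.743
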
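# Published per-dimension EQ-5D-5L response-level counts by disease group
# for the 109-person rare-bone-disease cohort (43 OI, 42 FD, 24 XLH).
dimension,disease,level,count
MO,OI,1,8
MO,OI,2,14
MO,OI,3,10
MO,OI,4,6
MO,OI,5,5
MO,FD,1,18
MO,FD,2,9
MO,FD,3,8
MO,FD,4,7
MO,FD,5,0
MO,XLH,1,3
MO,XLH,2,10
MO,XLH,3,6
MO,XLH,4,2
MO,XLH,5,3
SC,OI,1,26
SC,OI,2,10
SC,OI,3,3
SC,OI,4,2
SC,OI,5,2
SC,FD,1,26
SC,FD,2,11
SC,FD,3,4
SC,FD,4,1
SC,FD,5,0
SC,XLH,1,12
SC,XLH,2,7
SC,XLH,3,1
SC,XLH,4,2
SC,XLH,5,2
UA,OI,1,15
UA,OI,2,13
UA,OI,3,8
UA,OI,4,5
UA,OI,5,2
UA,FD,1,14
UA,FD,2,13
UA,FD,3,8
UA,FD,4,4
UA,FD,5,3
UA,XLH,1,6
UA,XLH,2,10
UA,XLH,3,5
UA,XLH,4,3
UA,XLH,5,0
PD,OI,1,3
PD,OI,2,14
PD,OI,3,19
PD,OI,4,4
PD,OI,5,3
PD,FD,1,1
PD,FD,2,13
PD,FD,3,15
PD,FD,4,9
PD,FD,5,4
PD,XLH,1,2
PD,XLH,2,6
PD,XLH,3,10
PD,XLH,4,5
PD,XLH,5,1
AD,OI,1,17
AD,OI,2,17
AD,OI,3,6
AD,OI,4,3
AD,OI,5,0
AD,FD,1,16
AD,FD,2,12
AD,FD,3,10
AD,FD,4,4
AD,FD,5,0
AD,XLH,1,10
AD,XLH,2,13
AD,XLH,3,1
AD,XLH,4,0
AD,XLH,5,0
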
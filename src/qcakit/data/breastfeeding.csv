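study,Empowerment,Design,Lay-led,Quality,Intensity,raw_or,highly_effective
Anderson (2005),0,0,1,1,1,8.458,1.000
Caulfield (1998),0,0,1,0.333,1,3.783,1.000
Chapman (2004),1,1,0,1,0,1.751,0.666
Grummer-Strawn (1997),0,0,0,0,0,1.927,0.666
Karanja (2010),0,1,0,0,0,0.463,0.000
Kistin (1994),0,0,1,0,0,5.397,1.000
Long (1995),0,0,1,0,0,1.729,0.333
McInnes (1998),1,1,1,0,0,1.614,0.333
Pugh (2001),0,0,0,1,1,6.000,1.000
Pugh (2002),0,0,0,1,1,2.786,0.666
Schafer (1998),0,1,1,1,1,8.458,1.000
Shaw (1999),0,0,1,0,0,2.317,0.666
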
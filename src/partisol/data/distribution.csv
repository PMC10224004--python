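system,solute,cd_name,cd_conc_M,D,sd,logD
1-octanol/buffer,IPN,,0,2.651,0.093,0.423
1-octanol/buffer,INZ,,0,0.633,0.021,-0.199
1-octanol/buffer,iNAM,,0,0.446,0.013,-0.351
1-octanol/buffer,IPN,HP-beta-CD,0.0115,2.413,0.086,0.383
1-octanol/buffer,IPN,HP-beta-CD,0.025,2.138,0.087,0.330
1-octanol/buffer,IPN,HP-beta-CD,0.035,1.922,0.096,0.284
1-octanol/buffer,IPN,M-beta-CD,0.0115,2.558,0.081,0.408
1-octanol/buffer,IPN,M-beta-CD,0.025,2.459,0.068,0.391
1-octanol/buffer,IPN,M-beta-CD,0.035,2.363,0.072,0.373
n-hexane/buffer,IPN,,0,0.0012400,0.0000191,-2.907
n-hexane/buffer,INZ,,0,0.0008254,0.0000188,-3.083
n-hexane/buffer,iNAM,,0,0.0005742,0.0000172,-3.241
n-hexane/buffer,IPN,HP-beta-CD,0.0115,0.0009138,0.0000161,-3.039
n-hexane/buffer,IPN,HP-beta-CD,0.025,0.0004311,0.0000113,-3.365
n-hexane/buffer,IPN,HP-beta-CD,0.035,0.0001672,0.0000061,-3.777
n-hexane/buffer,IPN,M-beta-CD,0.0115,0.0010200,0.0000210,-2.991
n-hexane/buffer,IPN,M-beta-CD,0.025,0.0006763,0.0000122,-3.170
n-hexane/buffer,IPN,M-beta-CD,0.035,0.0005525,0.0000128,-3.258
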
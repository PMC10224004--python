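solute,solvent,T_K,S2_mol_per_L,sd
IPN,1-octanol,290.2,0.409,0.008
IPN,1-octanol,293.2,0.444,0.009
IPN,1-octanol,298.2,0.506,0.006
IPN,1-octanol,303.2,0.573,0.011
IPN,1-octanol,310.2,0.686,0.018
IPN,n-hexane,290.2,0.00072,0.00001
IPN,n-hexane,293.2,0.00083,0.00003
IPN,n-hexane,298.2,0.00107,0.00002
IPN,n-hexane,303.2,0.00142,0.00003
IPN,n-hexane,310.2,0.00203,0.00004
INZ,1-octanol,310.2,0.178,0.004
INZ,n-hexane,310.2,0.00137,0.00005
iNAM,1-octanol,310.2,0.126,0.002
iNAM,n-hexane,310.2,0.00110,0.00004
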
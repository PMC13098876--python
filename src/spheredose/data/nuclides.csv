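symbol,half_life_s,class,delta_mev,beta_emax_mev,daughter,branching,mode,source
Zr-89,282276.0,beta_mean,0.0902,0.902,,,,ICRP107
Zr-89,282276.0,photon,1.1300,0.902,,,,ICRP107
Zr-89,282276.0,,,0.902,Y-89,1.0,ec,ICRP107
Y-89,,,,0,,,,ICRP107
Y-90,230580.0,beta_mean,0.9336,2.280,,,,ICRP107
Y-90,230580.0,,,2.280,Zr-90,1.0,beta,ICRP107
Zr-90,,,,0,,,,ICRP107
Y-86,53064.0,beta_mean,0.2200,3.141,,,,ICRP107
Y-86,53064.0,photon,4.4000,3.141,,,,ICRP107
Y-86,53064.0,,,3.141,Sr-86,1.0,ec,ICRP107
Sr-86,,,,0,,,,ICRP107
Lu-177,574300.8,beta_mean,0.1334,0.498,,,,ICRP107
Lu-177,574300.8,photon,0.0334,0.498,,,,ICRP107
Lu-177,574300.8,conversion_electron,0.0147,0.498,,,,ICRP107
Lu-177,574300.8,,,0.498,Hf-177,1.0,beta,ICRP107
Hf-177,,,,0,,,,ICRP107
Ac-225,857088.0,alpha,5.7900,0,,,,ICRP107
Ac-225,857088.0,photon,0.0170,0,,,,ICRP107
Ac-225,857088.0,conversion_electron,0.0210,0,,,,ICRP107
Ac-225,857088.0,,,0,Fr-221,1.0,alpha,ICRP107
Fr-221,288.0,alpha,6.3000,0,,,,ICRP107
Fr-221,288.0,photon,0.0300,0,,,,ICRP107
Fr-221,288.0,,,0,At-217,1.0,alpha,ICRP107
At-217,0.0323,alpha,7.0660,0,,,,ICRP107
At-217,0.0323,,,0,Bi-213,1.0,alpha,ICRP107
Bi-213,2736.6,alpha,0.1291,1.423,,,,ICRP107
Bi-213,2736.6,beta_mean,0.4246,1.423,,,,ICRP107
Bi-213,2736.6,photon,0.1330,1.423,,,,ICRP107
Bi-213,2736.6,,,1.423,Po-213,0.9780,beta,ICRP107
Bi-213,2736.6,,,1.423,Tl-209,0.0220,alpha,ICRP107
Po-213,4.2e-06,alpha,8.3750,0,,,,ICRP107
Po-213,4.2e-06,,,0,Pb-209,1.0,alpha,ICRP107
Tl-209,129.7,beta_mean,0.6590,1.830,,,,ICRP107
Tl-209,129.7,photon,1.9900,1.830,,,,ICRP107
Tl-209,129.7,,,1.830,Pb-209,1.0,beta,ICRP107
Pb-209,11642.4,beta_mean,0.1979,0.644,,,,ICRP107
Pb-209,11642.4,,,0.644,Bi-209,1.0,beta,ICRP107
Bi-209,,,,0,,,,ICRP107
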
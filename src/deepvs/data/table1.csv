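name,deepbindbc,docking,dfcnn
Sennoside_A,1,-11.3,0.9908
Sennoside_B,1,-10.4,0.9908
Dabrafenib,0.9996,-10.2,0.994
Olmutinib,0.9994,-10.6,0.9971
CEP37440,0.9992,-10.1,0.9967
GW_4064,0.9991,-11.2,0.9976
Omipalisib,0.9991,-10.6,0.9907
FLT3-IN-1,0.9985,-10.2,0.9968
Gedatolisib,0.9984,-11,0.9967
Avitinib,0.9984,-10.2,0.9955
RO_46-8443,0.9978,-10.3,0.9944
VLX1570,0.9972,-10.5,0.993
Orexin_2_Receptor_Agonist,0.9967,-10.8,0.9955
Ponatinib,0.9964,-11.4,0.9921
DJ-V159,0.9928,-11.8,0.997
Flumethrin,0.9914,-10.7,0.9979
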
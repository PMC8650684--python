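name,deepbindbc,docking,dfcnn
ARRY380,1,-10.4,0.9982
Probucol,0.9997,-9,0.9995
Radotinib,0.9986,-10.1,0.9988
FIIN-3,0.9982,-9.8,0.9993
Rociletinib,0.9979,-10.6,0.9987
Torin_1,0.997,-9,0.9993
UM-164,0.9968,-10.9,0.9994
Fenretinide,0.9967,-9.2,0.9981
Fedratinib,0.9965,-9.7,0.9993
GNF-7,0.9964,-12.9,0.9991
DCC-2036,0.9959,-10.2,0.9995
AST_487,0.995,-10.5,0.9995
FIIN-2,0.995,-10.8,0.9994
Flumatinib,0.9947,-11,0.9994
Golvatinib,0.9942,-10.9,0.9993
CHMFL-BMX-078,0.9929,-9.4,0.9994
DDR1-IN-2,0.9925,-11.7,0.9991
K_0859,0.9922,-11.4,0.9994
A_740003,0.992,-9,0.9981
ZCL_278,0.9919,-9,0.9989
Dehydroandrographolide succinate,0.9918,-8.5,0.9993
Nilotinib,0.9916,-11.2,0.9993
TG101209,0.9915,-9.9,0.9994
Masitinib,0.9903,-10.2,0.9983
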
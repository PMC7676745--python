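patient,group,ruptured,d_max,sigma_vm,rpi,prri,p_rupt
Pat1,asymptomatic,0,63.09,373.14,0.398,6.48,2.01
Pat2,asymptomatic,0,69.23,180.21,0.202,0.20,0.13
Pat3,asymptomatic,0,61.76,368.65,0.362,4.20,1.04
Pat4,asymptomatic,0,50.37,257.04,0.288,1.55,1.22
Pat5,asymptomatic,0,62.94,349.00,0.371,4.15,1.34
Pat6,asymptomatic,0,61.10,324.35,0.363,3.81,4.30
Pat7,asymptomatic,0,54.94,301.55,0.339,3.06,0.76
Pat8,asymptomatic,0,60.14,348.62,0.390,5.36,5.52
Pat9,asymptomatic,0,57.12,380.97,0.382,5.68,1.63
Pat10,asymptomatic,0,57.94,263.15,0.295,1.65,1.46
Pat11,asymptomatic,0,57.63,324.06,0.359,3.93,1.14
Pat12,asymptomatic,0,55.35,343.26,0.356,3.84,1.22
Pat13,asymptomatic,0,66.25,281.44,0.315,2.14,2.32
Pat14,asymptomatic,0,71.25,255.60,0.286,1.49,1.21
Pat15,asymptomatic,0,70.52,394.89,0.442,8.32,8.77
Pat16,asymptomatic,0,79.94,300.20,0.342,4.06,0.76
Pat17,asymptomatic,0,53.75,291.70,0.320,1.93,0.47
Pat18,asymptomatic,0,65.81,344.30,0.393,5.37,1.98
Pat19,symptomatic/ruptured,1,57.55,230.60,0.282,1.08,0.18
Pat20,symptomatic/ruptured,0,70.40,473.52,0.551,16.38,9.77
Pat21,symptomatic/ruptured,0,70.76,538.30,0.507,15.16,7.37
Pat22,symptomatic/ruptured,0,73.32,380.57,0.452,9.47,4.12
Pat23,symptomatic/ruptured,1,77.09,738.58,0.860,30.03,24.87
Pat24,symptomatic/ruptured,1,72.80,377.91,0.404,6.51,2.38
Pat25,symptomatic/ruptured,0,52.26,197.94,0.220,0.25,0.02
Pat26,symptomatic/ruptured,1,60.95,335.47,0.376,4.92,5.02
Pat27,symptomatic/ruptured,1,60.30,359.65,0.403,6.21,5.98
Pat28,symptomatic/ruptured,1,53.75,309.83,0.347,3.23,3.12
Pat29,symptomatic/ruptured,1,55.69,340.56,0.381,4.90,5.16
Pat30,symptomatic/ruptured,1,53.53,281.85,0.316,2.47,2.09
Pat31,symptomatic/ruptured,0,60.93,412.86,0.462,10.33,10.38
Pat32,symptomatic/ruptured,1,70.52,495.17,0.555,17.27,17.66
Pat33,symptomatic/ruptured,0,67.10,393.87,0.441,8.40,8.70
Pat34,symptomatic/ruptured,1,56.59,328.43,0.368,4.21,4.35
Pat35,symptomatic/ruptured,1,60.58,329.85,0.369,4.41,1.44
Pat36,symptomatic/ruptured,0,60.93,341.59,0.346,4.11,0.89
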
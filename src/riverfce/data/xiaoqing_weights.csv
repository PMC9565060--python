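id,level,ahp,entropy,comprehensive,criticality
A1,criterion,0.2742,0.3279,0.3010,1
A2,criterion,0.2938,0.2195,0.2566,2
A3,criterion,0.2886,0.2031,0.2458,3
A4,criterion,0.1434,0.2945,0.1964,4
C1,indicator,0.0619,0.0907,0.0763,1
C2,indicator,0.0838,0.0000,0.0419,14
C3,indicator,0.0220,0.0422,0.0321,19
C4,indicator,0.0417,0.0638,0.0528,5
C5,indicator,0.0324,0.0428,0.0376,16
C6,indicator,0.0324,0.0884,0.0604,3
C7,indicator,0.0543,0.0317,0.0430,13
C8,indicator,0.0321,0.0382,0.0352,17
C9,indicator,0.0208,0.0365,0.0286,20
C10,indicator,0.0501,0.0505,0.0503,7
C11,indicator,0.0684,0.0301,0.0492,9
C12,indicator,0.0681,0.0325,0.0503,7
C13,indicator,0.1143,0.0285,0.0714,2
C14,indicator,0.0572,0.0391,0.0481,11
C15,indicator,0.0478,0.0491,0.0485,10
C16,indicator,0.0276,0.0415,0.0346,18
C17,indicator,0.0417,0.0448,0.0433,12
C18,indicator,0.0402,0.0744,0.0573,4
C19,indicator,0.0489,0.0536,0.0512,6
C20,indicator,0.0148,0.0346,0.0247,21
C21,indicator,0.0247,0.0555,0.0401,15
C22,indicator,0.0148,0.0314,0.0231,22
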
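group_id,label,member,habitat,n,d13C_mean,d13C_sd,d15N_mean,d15N_sd,d34S_mean,d34S_sd
S1,Riverine POM,,,24,-25.82,0.87,3.07,0.75,,
S1,Riverine POM,POM,FW,8,-25.60,0.90,2.96,0.85,,
S1,Riverine POM,POM,FOR,8,-26.31,0.67,2.67,0.61,,
S1,Riverine POM,POM,EFT,8,-25.54,0.88,3.57,0.54,,
S2,Marsh POM,,,8,-24.75,0.50,5.56,1.50,,
S2,Marsh POM,POM,EEM,8,-24.75,0.50,5.56,1.50,,
S3,Delta POM,,,16,-21.21,1.42,6.47,1.49,,
S3,Delta POM,POM,DMF,8,-21.81,1.38,6.53,0.86,,
S3,Delta POM,POM,EEL,8,-20.61,1.27,6.42,2.00,,
S4,Marsh Diatoms,,,14,-21.59,1.65,4.86,1.19,,
S4,Marsh Diatoms,Diatoms,EEM,14,-21.59,1.65,4.86,1.19,,
S5,Delta Diatoms,,,24,-15.81,0.71,1.98,1.01,,
S5,Delta Diatoms,Diatoms,MAD,12,-15.53,0.48,2.26,0.86,,
S5,Delta Diatoms,Diatoms,RSS,12,-16.10,0.81,1.70,1.11,,
S6,Riverine Plants,,,72,-30.57,1.66,-1.51,1.39,7.95,1.06
S6,Riverine Plants,Rubus spectabilis,FW,12,-31.42,1.36,-2.00,1.03,7.34,1.03
S6,Riverine Plants,Salix sp.,FW,6,-28.44,0.87,-0.20,0.71,7.80,0.74
S6,Riverine Plants,Urtica dioica,FW,12,-31.61,1.49,0.13,1.11,8.33,1.10
S6,Riverine Plants,leaf litter,FW,6,-28.53,0.85,-0.81,0.34,8.19,1.39
S6,Riverine Plants,Acer macrophyllum,FOR,6,-30.15,0.71,-2.76,0.77,8.22,0.84
S6,Riverine Plants,Rubus spectabilis,FOR,12,-31.53,1.44,-1.69,1.40,8.31,1.33
S6,Riverine Plants,Urtica dioica,FOR,12,-30.38,1.48,-2.35,0.93,7.83,0.76
S6,Riverine Plants,leaf litter,FOR,6,-29.86,0.87,-2.51,0.63,7.61,0.92
S7,Marsh C3 Plants,,,30,-27.34,1.21,4.79,1.42,12.00,5.89
S7,Marsh C3 Plants,Carex lyngbyei,EFT,6,-28.34,0.96,4.24,1.62,12.90,5.54
S7,Marsh C3 Plants,Eleocharis acicularis,EFT,6,-28.46,0.61,4.47,1.34,15.66,3.34
S7,Marsh C3 Plants,Typha latifolia,EFT,6,-27.03,0.51,5.49,1.27,11.45,3.31
S7,Marsh C3 Plants,Carex lyngbyei,EEM,6,-25.70,0.64,4.90,1.13,2.10,3.61
S7,Marsh C3 Plants,Salicornia pacifica,EEM,6,-27.16,1.08,3.47,1.29,16.04,1.46
S8,Marsh C4 Plants,,,12,-15.46,1.86,4.76,0.80,3.77,4.10
S8,Marsh C4 Plants,Distichlis spicata,EEM,12,-15.46,1.86,4.76,0.80,3.77,4.10
S9,Delta Plants,,,6,-10.95,1.85,7.94,1.25,19.81,3.92
S9,Delta Plants,Ulva spp,DMF,6,-12.02,1.84,7.91,0.96,22.53,1.04
S9,Delta Plants,Ulva spp,EEL,5,-10.56,2.45,8.77,1.70,22.33,1.53
S9,Delta Plants,Zostera marina,EEL,6,-10.36,0.59,7.28,0.77,14.99,1.72
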
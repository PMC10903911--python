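group_id,label,member,stratum,n,d13C_mean,d13C_sd,d15N_mean,d15N_sd,d34S_mean,d34S_sd
T1,Riverine Insects,,terrestrial,8,-26.25,2.08,1.77,2.23,6.58,1.44
T1,Riverine Insects,Coleoptera-Coccinellidae,terrestrial,1,-25.29,,2.58,,7.57,
T1,Riverine Insects,Coleoptera (other),terrestrial,1,-23.47,,2.63,,7.58,
T1,Riverine Insects,Hemiptera-Aphidae,terrestrial,2,-25.93,2.85,0.59,2.87,5.89,2.07
T1,Riverine Insects,Hemiptera-Cicadellidae,terrestrial,1,-25.31,,4.53,,6.31,
T1,Riverine Insects,Hymenoptera,terrestrial,2,-27.38,0.83,2.29,2.09,6.52,2.68
T1,Riverine Insects,Lepidoptera,terrestrial,1,-29.28,,-1.37,,6.38,
T2,Marsh Insects,,terrestrial,5,-24.01,2.14,5.77,1.31,8.76,5.65
T2,Marsh Insects,Hemiptera-Cicadellidae,terrestrial,3,-23.12,2.33,4.90,0.74,6.80,6.36
T2,Marsh Insects,Hemiptera-Lygaeidae,terrestrial,1,-24.48,,7.07,,14.69,
T2,Marsh Insects,Lepidoptera,terrestrial,1,-26.22,,7.09,,8.72,
T3,Saldidae,,terrestrial,3,-19.40,0.69,7.87,0.73,9.16,4.92
T3,Saldidae,Hemiptera-Saldidae,terrestrial,3,-19.40,0.69,7.87,0.73,9.16,4.92
T4,Dolichopodidae,,terrestrial,12,-21.41,1.21,8.98,1.07,9.81,2.92
T4,Dolichopodidae,Diptera-Dolichopodidae,terrestrial,12,-21.41,1.21,8.98,1.07,9.81,2.92
T5,Ephydridae,,terrestrial,11,-23.77,2.38,8.95,1.07,10.16,2.01
T5,Ephydridae,Diptera-Ephydridae,terrestrial,11,-23.77,2.38,8.95,1.07,10.16,2.01
T6,Riverine Dipterans,,terrestrial,7,-30.10,4.37,6.30,1.47,9.23,1.36
T6,Riverine Dipterans,Diptera-Brachycera,terrestrial,2,-25.70,1.17,6.35,0.26,8.41,0.93
T6,Riverine Dipterans,Diptera-Chironomidae,terrestrial,4,-33.26,2.59,7.01,0.88,10.27,0.88
T6,Riverine Dipterans,Diptera-Sciomyzidae,terrestrial,1,-26.29,,3.38,,7.75,
T7,Marsh Dipterans,,terrestrial,4,-22.31,3.24,7.28,0.20,10.92,2.77
T7,Marsh Dipterans,Diptera-Chironomidae,terrestrial,1,-25.74,,7.57,,7.92,
T7,Marsh Dipterans,Diptera-Muscidae,terrestrial,1,-24.31,,7.14,,9.21,
T7,Marsh Dipterans,Diptera-Tipulidae,terrestrial,2,-19.60,1.04,7.21,0.06,13.27,0.37
A1,Riverine Isopods,,aquatic,3,-19.59,2.35,7.60,0.45,19.47,0.09
A1,Riverine Isopods,Gnorimosphaeroma oregonensis,aquatic,3,-19.59,2.35,7.60,0.45,19.47,0.09
A2,Marsh Isopods,,aquatic,3,-17.24,0.77,8.07,0.36,20.08,1.05
A2,Marsh Isopods,Gnorimosphaeroma oregonensis,aquatic,3,-17.24,0.77,8.07,0.36,20.08,1.05
A3,Riverine Mysids,,aquatic,11,-17.33,4.94,10.57,3.26,16.21,0.51
A3,Riverine Mysids,Neomysis mercedis,aquatic,11,-17.33,4.94,10.57,3.26,16.21,0.51
A4,Marsh Mysids,,aquatic,3,-14.59,0.16,11.29,0.44,17.72,0.17
A4,Marsh Mysids,Neomysis mercedis,aquatic,3,-14.59,0.16,11.29,0.44,17.72,0.17
A5,Delta Mysids,,aquatic,8,-13.99,1.72,10.98,0.81,17.05,0.59
A5,Delta Mysids,Neomysis mercedis,aquatic,8,-13.99,1.72,10.98,0.81,17.05,0.59
A6,Delta Shrimp,,aquatic,3,-13.23,0.26,12.00,0.16,18.02,0.55
A6,Delta Shrimp,Crangon sp.,aquatic,3,-13.23,0.26,12.00,0.16,18.02,0.55
B1,Riverine Crustaceans,,benthic,11,-20.79,2.83,8.75,2.28,15.03,3.04
B1,Riverine Crustaceans,Amphipoda-Ampithoe sp.,benthic,4,-21.88,3.33,7.61,1.63,16.17,3.96
B1,Riverine Crustaceans,Amphipoda-Corophiidae,benthic,6,-20.37,2.74,9.80,2.40,14.07,2.57
B1,Riverine Crustaceans,Cumacea,benthic,1,-18.96,,6.96,,16.25,
B2,Marsh Crustaceans,,benthic,12,-17.20,1.28,10.28,1.44,15.80,2.43
B2,Marsh Crustaceans,Amphipoda-Ampithoe sp.,benthic,5,-17.87,1.78,9.78,1.17,15.99,3.04
B2,Marsh Crustaceans,Amphipoda-Corophiidae,benthic,6,-16.54,0.19,10.88,1.60,15.68,2.26
B2,Marsh Crustaceans,Copepoda-Harpacticoida,benthic,1,-17.74,,9.25,,,
B3,Delta Crustaceans,,benthic,16,-13.53,1.74,9.73,1.01,16.11,1.61
B3,Delta Crustaceans,Amphipoda-Ampithoe sp.,benthic,5,-14.50,1.55,9.39,0.39,16.99,1.29
B3,Delta Crustaceans,Amphipoda-Corophiidae,benthic,6,-14.24,1.14,9.82,0.13,16.07,1.50
B3,Delta Crustaceans,Amphipoda-Eogammarus sp.,benthic,1,-11.63,,12.90,,16.54,
B3,Delta Crustaceans,Copepoda-Harpacticoida,benthic,1,-11.74,,9.63,,,
B3,Delta Crustaceans,Cumacea,benthic,2,-10.87,0.76,8.46,0.59,13.11,
B3,Delta Crustaceans,Tanaidacea,benthic,1,-13.44,,10.35,,14.50,
B4,Riverine Larvae,,benthic,12,-21.10,3.96,7.05,1.16,12.18,1.33
B4,Riverine Larvae,Diptera-Ceraptogonidae,benthic,2,-18.14,3.55,6.55,0.95,,
B4,Riverine Larvae,Diptera-Chironomidae,benthic,5,-21.33,1.36,7.69,1.48,11.49,1.49
B4,Riverine Larvae,Diptera-Dolichopodidae,benthic,1,-16.89,,7.71,,14.07,
B4,Riverine Larvae,Diptera-Trichoptera,benthic,4,-23.34,5.69,6.35,0.19,12.57,0.43
B5,Riverine Polychaetes,,benthic,8,-23.43,3.80,9.12,1.74,12.13,4.29
B5,Riverine Polychaetes,Neanthes sp.,benthic,8,-23.43,3.80,9.12,1.74,12.13,4.29
B6,Delta Polychaetes,,benthic,20,-14.01,1.77,13.32,2.92,15.73,3.00
B6,Delta Polychaetes,Eteone sp.,benthic,6,-12.86,0.56,15.26,0.91,15.64,0.14
B6,Delta Polychaetes,Glycera nana,benthic,2,-13.89,0.02,14.98,0.46,15.39,0.67
B6,Delta Polychaetes,Goniada brunea,benthic,2,-15.22,0.17,13.04,0.61,10.96,2.35
B6,Delta Polychaetes,Neanthes sp.,benthic,3,-13.14,0.12,12.95,1.46,14.85,3.44
B6,Delta Polychaetes,Phyllodocidae,benthic,1,-12.78,,14.52,,15.32,
B6,Delta Polychaetes,Sabellidae,benthic,1,-13.62,,14.92,,17.39,
B6,Delta Polychaetes,Spionidae,benthic,5,-15.79,2.59,10.11,4.17,19.37,0.34
F1,Riverine Salmon (2015),,fish,4,-20.49,1.25,11.10,1.11,11.39,5.22
F2,Marsh Salmon (2015),,fish,19,-19.26,2.19,11.56,1.30,12.61,3.84
F3,Delta Salmon (2015),,fish,8,-18.27,2.57,11.15,1.34,11.97,3.11
F4,Riverine Salmon (2011),,fish,10,-24.84,1.74,10.68,0.67,7.29,1.65
F5,Marsh Salmon (2011),,fish,10,-21.03,3.97,11.59,1.10,11.04,3.29
F6,Delta Salmon (2011),,fish,14,-18.93,2.42,11.35,1.54,12.65,2.98
F7,Marsh Sculpin (2011),,fish,15,-15.98,1.50,12.44,0.43,15.46,1.29
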
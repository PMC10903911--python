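prey_group,label,member,weight
T1,Riverine Insects,T1,8
T2,Marsh Insects,T2,5
T345,Riverine/Marsh Shoreflies and Shorebugs,T3,3
T345,Riverine/Marsh Shoreflies and Shorebugs,T4,12
T345,Riverine/Marsh Shoreflies and Shorebugs,T5,11
T6,Riverine Dipterans,T6,7
T7,Marsh Dipterans,T7,4
A12,Riverine/Marsh Isopods,A1,3
A12,Riverine/Marsh Isopods,A2,3
A56,Delta Mysids and Shrimp,A3,11
A56,Delta Mysids and Shrimp,A4,3
A56,Delta Mysids and Shrimp,A5,8
A56,Delta Mysids and Shrimp,A6,3
B145,Riverine Benthics,B1,11
B145,Riverine Benthics,B4,12
B145,Riverine Benthics,B5,8
B2,Marsh Crustaceans,B2,12
B3,Delta Crustaceans,B3,16
B6,Delta Polychaetes,B6,20
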
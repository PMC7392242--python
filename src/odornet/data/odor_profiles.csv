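odor_id,label,code,valence_mean,valence_sd,arousal_mean,arousal_sd,familiarity_mean,familiarity_sd,intensity_mean,intensity_sd
1,Anise,Sniffin' B15,0.34,2.09,0.05,2.02,72.63,23.39,54.34,20.91
2,Apple,Sniffin' B11,0.84,2.08,0.20,1.98,55.07,23.54,61.89,19.19
3,Banana,Sniffin' B5,1.47,1.72,0.48,2.24,77.25,17.76,60.18,20.14
4,Burned wood,RS-420,-1.54,2.15,0.76,2.09,49.86,28.08,73.07,21.13
5,Caramel,Sniffin' P15,2.25,1.39,1.11,2.25,80.50,13.62,58.75,20.44
6,Cinnamon,Sniffin' B3,0.98,1.98,0.22,2.40,61.88,29.39,54.25,23.22
7,Cloves,Sniffin' B12,-0.33,2.30,-0.02,2.23,51.38,29.16,62.88,21.05
8,Coconut,Sniffin' P9,1.94,1.59,0.87,2.10,77.32,19.03,56.16,19.42
9,Coffee,Sniffin' B10,0.77,2.26,0.33,2.23,72.52,27.13,58.75,22.12
10,Coke,Sniffin' P2,0.37,1.77,-0.48,1.86,48.11,25.65,49.84,20.35
11,Diesel fumes,RS-423,-1.76,1.55,-0.04,2.22,48.84,23.97,60.86,21.47
12,Dusty cave,RS-425,-0.20,1.82,-0.76,1.89,36.59,22.94,43.00,25.00
13,Eucalyptus,Sniffin' P7,0.66,2.09,0.21,2.11,73.55,22.77,70.36,19.14
14,Fish,Sniffin' B16,-2.07,1.74,0.84,2.34,63.16,27.69,71.39,26.26
15,Garlic,Sniffin' B9,-1.18,2.20,0.79,2.32,68.30,26.61,77.21,18.14
16,Ginger,Sniffin' P8,0.01,1.91,-0.52,1.87,47.38,24.41,55.36,20.81
17,Grapefruit,Sniffin' P4,0.83,1.91,0.12,2.11,53.20,24.58,55.48,19.65
18,Grass,Sniffin' P5,0.07,2.04,-0.14,2.03,67.43,22.45,63.93,21.36
19,Feces,Indole,-1.97,1.86,0.53,2.16,40.61,24.86,65.13,22.17
20,Lavender,Sniffin' P10,0.93,1.88,-0.08,2.20,66.91,25.23,56.64,18.45
21,Leather,Sniffin' B2,-0.57,1.91,-0.71,1.54,41.52,25.13,46.16,20.95
22,Lemon,Sniffin' B6,1.49,1.73,0.48,2.12,60.14,25.38,53.70,21.15
23,Lilac,Sniffin' P3,0.92,2.02,-0.32,2.05,68.00,22.94,59.23,20.04
24,Liquorice,Sniffin' B7,0.92,2.13,0.00,1.93,78.23,24.00,57.04,19.83
25,Melon,Sniffin' P11,1.58,1.68,-0.12,2.38,66.66,21.52,54.64,22.07
26,Metal,RS-426,-0.71,1.75,-0.59,1.82,36.95,25.43,50.09,22.73
27,Mushroom,Sniffin' P13,-1.28,2.10,0.51,2.12,45.13,29.10,66.30,18.68
28,Onion,Sniffin' P16,-1.73,2.03,1.00,2.12,55.66,28.30,69.20,21.28
29,Orange,Sniffin' B1,2.04,1.30,0.57,2.23,76.25,19.69,54.88,24.05
30,Peach,Sniffin' P12,2.51,1.67,1.55,2.07,79.70,19.67,61.84,22.93
31,Pear,Sniffin' P1,1.14,1.74,0.02,2.11,59.00,22.74,57.23,19.97
32,Peppermint,Sniffin' B4,1.63,1.80,0.57,2.02,84.84,16.30,64.80,23.05
33,Pineapple,Sniffin' B13,1.21,2.07,0.22,2.17,58.93,26.68,64.77,18.26
34,Raspberry,Sniffin' P6,2.20,1.23,0.57,2.18,66.54,18.73,54.77,21.88
35,Rhinoceros,RS-424,-2.10,1.48,0.46,2.31,49.34,25.58,70.84,20.02
36,Rose,Sniffin' B14,1.43,1.77,-0.09,2.13,72.77,16.78,61.23,21.94
37,Smoked meat,Sniffin' P14,-0.92,1.82,-0.57,1.92,44.16,26.65,58.54,21.82
38,Tar,RS-401,-1.23,2.20,0.63,2.07,52.71,26.88,72.59,20.06
39,Turpentine,Sniffin' B8,-0.87,1.94,-0.55,2.01,46.91,26.11,57.77,18.90
40,Wintergreen,Gaultheria oil,-0.99,2.19,0.02,2.02,56.48,29.89,69.30,21.12
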
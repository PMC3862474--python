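# Dayhoff PAM amino-acid replacement model (basis of the PAM001 matrix).
# Source: Dayhoff, M.O., Schwartz, R.M., Orcutt, B.C. (1978) "A model of
# evolutionary change in proteins", Atlas of Protein Sequence and
# Structure 5(3):345-352.  Exchangeabilities and stationary frequencies
# as distributed with standard phylogenetics software.
# Format: 19 lines of lower-triangular exchangeabilities s(i,j) for rows
# 2..20, then one line of 20 stationary frequencies.
# Amino-acid order: A R N D C Q E G H I L K M F P S T W Y V
27
98 120
36 89 198
240 23 65 41
26 72 18 250 409
371 0 24 208 32 0
23 246 1 9 240 64 15
464 90 14 103 154 26 201 8
24 905 0 103 148 139 535 77 34
318 1 14 42 495 229 23 95 15 0
134 1153 125 86 24 0 71 0 0 13 95
66 0 0 18 0 0 11 28 44 0 0 0
0 19 161 16 0 96 49 716 28 606 18 73 153
114 0 153 56 53 0 0 35 81 43 61 11 83 30
0 51 79 34 0 22 37 10 0 7 27 17 15 34 234
30 0 0 54 7 44 26 0 48 94 35 22 27 127 44 257
46 336 196 12 24 192 0 37 889 18 527 157 32 17 33 46 28
175 243 0 33 96 136 0 13 10 92 17 62 104 0 0 258 11 46
13 76 698 12 245 78 0 0 48 550 75 34 30 0 42 157 61 0 28
0.0871269128730871 0.0409039590960409 0.0404319595680404 0.0468719531280469 0.0334739665260335 0.0382549617450383 0.0495299504700495 0.0886119113880886 0.0336179663820336 0.0368859631140369 0.0853569146430854 0.0804819195180805 0.0147529852470148 0.0397719602280398 0.0506799493200507 0.0695769304230696 0.0585419414580585 0.0104939895060105 0.0299159700840299 0.0647179352820647
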
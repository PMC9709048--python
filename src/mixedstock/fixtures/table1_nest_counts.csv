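rookery,period,size
CEFL,historical,1353
SOFL,historical,827
MXQR,historical,1039
MXCA,historical,636
MXTV,historical,528
TORT,historical,86667
SWCB,historical,159
SURN,historical,6562
AVES,historical,1500
CEFL,recent,10129
SOFL,recent,6549
MXQR,recent,11907
MXCA,recent,11281
MXTV,recent,10713
TORT,recent,129060
SWCB,recent,242
SURN,recent,19646
AVES,recent,3000
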
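group,vowel,f1_hz,f2_hz
DS,IY,462,1810
DS,IH,600,1860
DS,EH,745,1664
DS,EY,528,1827
DS,AE,903,1632
DS,AH,726,1553
DS,UW,499,1408
DS,UH,627,1632
DS,OW,617,1361
DS,AA,897,1472
TD,IY,452,3081
TD,IH,511,2552
TD,EH,749,2267
TD,EY,564,2656
TD,AE,717,2501
TD,AH,586,1719
TD,UW,494,1345
TD,UH,568,1490
TD,OW,597,1137
TD,AA,1002,1688
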
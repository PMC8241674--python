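gene,artemisinin_b,dexrazoxane,doxorubicin
ANPEP,503.888,154.716,-1166.090
BACE1,-60.065,-38.736,131.002
C1QBP,251.246,296.638,-1196.785
MGLL,41.710,205.947,-229.316
MT1A,3050.855,2360.951,-2028.899
MT1B,1895.162,1362.674,-1498.303
NT5E,774.197,603.894,-510.647
RGS4,256.294,348.026,-361.650
RPL23A,-611.567,-612.719,676.744
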
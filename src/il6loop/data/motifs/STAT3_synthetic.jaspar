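>SYN0002.1 STAT3_synthetic
A  [  3   4   3   3   3   4   3  88  91 ]
C  [  3   4  91  88   3   4   3   4   3 ]
G  [  3   4   3   6  91  88  91   4   3 ]
T  [ 91  88   3   3   3   4   3   4   3 ]
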
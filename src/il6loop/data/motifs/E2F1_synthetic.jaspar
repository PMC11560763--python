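>SYN0001.1 E2F1_synthetic
A  [  3   3   3   4   3   3   3   3 ]
C  [  3   3   3  88  91  88   3  91 ]
G  [  3   3   3   4   3   6  91   3 ]
T  [ 91  91  91   4   3   3   3   3 ]
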
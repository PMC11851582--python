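1 3 6 9 11 21 26 29 31 33 41 43 47 49 51 52 53 54 56 61 62 63 66 67 71 73 78 81 82 83 84 86 89 90 93 97 99 102 103 108 115 120
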
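1 2 5 6 7 8 11 14 15 17 18 21 23 28 29 31 32 34 38 41 43 45 57 59 62 66 67 69 70 72 73 74 77 78 79 80 81 82 84 92 97 98 101 102 103 104 110 112 115 117
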
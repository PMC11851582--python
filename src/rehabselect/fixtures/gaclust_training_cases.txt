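1 4 5 7 8 10 11 12 13 14 15 17 18 20 21 24 25 26 29 30 31 33 34 36 38 43 45 49 51 54 55 58 59 61 62 66 67 70 72 73 74 76 77 78 80 82 84 85 86 88 89 92 93 95 96 97 98 101 102 103 109 115 116 118
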
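1 4 6 10 11 15 17 19 21 29 30 31 33 34 42 43 45 51 54 57 62 65 66 70 73 74 77 78 80 82 84 85 89 92 96 97 98 102 103 105 109 112 115
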
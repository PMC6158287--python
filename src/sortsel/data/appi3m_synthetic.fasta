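>appi3m_synthetic Kunitz-domain parent ORF (synthetic back-translation; numbering_offset=3)
GAAGTTTGTTCTGAACAAGCTGAAACTGGTCCGTGTCGTGCTGGTTTTTCTCGTTGGTAT
TTTGATGTTACTGAAGGTAAATGTGCTCCGTTTGTTTATGGTGGTTGTGGTGGTAATCGT
AATAATTTTGATACTGAAGAATATTGTATGGCTGTTTGTGGTTCTGCTATT
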
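>AluSyn1
GTGCCTATGCCCCCGGTGGTCAGAAGCTGGCCACGCCATACTGTGGAGGTCGACCAGCTGGGGACCCATC
GCTGATTTGACTGCTGGCCCATCGCGACAATGCGTCGGCGGTATAGGACGAGGGGCCCACTGAAAAACCT
CTGGTGGCTCTACGTCGGGGTCCCACTTAGCGGCTCGGCACGGGATGTGTAAACCCGAGAGACTGGGGCG
AGTTACCAGGCTGAGTCGGGAGGTGCGTTAAGCGTCCCGACAGTCCGCCCCAGGCAGAAAAAAAAAAAAA
AAAAAAA
>AluSyn2
GTGCCTATGCCCCCGGCTCTCAGATGCTGACCACGCCATACTGTGCAGGTCGACCAGCTGAGTACCCATC
GCAGATATGACTGCTGCCCCATTGCGACAATGCGTCGGCGGTATACGACGAGGGGCCCACTGAAAAACCT
CGGGTGGCTCTACTTCGGGGTCCCACTTAGCGGCGCGGCTCGCGATGTGCAAACTCGAGAGAATGGGGCG
AGTTGCCAAGCCGACTCGGGAGGTGCTTTAACCGTCCCGACAGTCCGCCCCAGGCAGAAAAAAAAAAAAA
AAAAAAA
>AluSyn3
GTGCCTATGCCCCCGGTTGTCAGAATCGAGCCACGCCTTACTGTGGACGTCGACCAGCTTGGGACCGATC
GCTGATTTGACTCCTGACCCATCGCGACAATCGGTCGGCCGTAGAGGACGAGTGGCCCAGTGAAAAACCT
CTGGTGGCTCTACGTCGGGGTCCCACATAGCGGCTCGGCACGGGATGTGTCAAGCCGAGAGTCTGGGGCG
AGATACCCGTCTGAGTCGGGAGGTACTTTTAGCGTGCCGACATTCCGCCCCAGGCACAAAAAAAAAAAAA
AAAAAAA
>AluSyn4
GTGCCTATGGCCCCGCTGGTAAGAGGCTGGCCACGCCATACTGTGGAGGTCGACCAGCTGGGGACCCATC
GCAAATCTGACTGTTGGCCCATCGCGACAATGCATCGGCGATATAGGACGCGGGGCCCACTGAAAAACCT
CTGTTGGCTCTACGTCGGGGTCCCACTTAGCGGCTCTGGTAGGGATGTGTACACCCGAGAAACTGGGGCG
GGTTAGGAGGTTGAGTTGGGAGGGGCGTTAAGCGTGTCGAAAGTCCGGCCCAGGGCGAAAAAAAAAAAAA
AAAAAAA
>AluSyn5
GTGCCTATGCCCCCGCCGGTCAGAAGTTGGCCACGCCACACTGTGTACGTCCACCAGCTGGGGACCCTTC
GCTGAATTGACTGCTGGCCCATCGCGACAATGCGTAGGGAGTATAGCACGAGGGGTCCACTGAAAAACCT
CACGTGGCTCTCCGTCGGGGTGCCACTTAGCTGGTCGGCCCGGCATCCGTAAACCCGAGAGACTGCGCCG
AGTGACCAGGCTGAGTCGGGAGATGCGTTAAGCGTCCCGTCAGTCCCCCACAGGCCTAAAAAAAAAAAAA
AAAAAAA
>AluSyn6
GTGCCTATGCCCCCAGTCGTCAGAAGCTGGCCACGCCAGACTGTGGAGGTCAACCAGCTGGGGACCCATC
GGTGAATTGAATGCTGGCCCATCGCGACTATGCGTCGGCGCTATCGGACGAGGGACCCACTCAAAAACCC
GTGGTGGCTCTACGTCGGGGTCCCACTTTGTGGCTCGGCACGGGATGTGTAAACCCAAGAGGAAGGGTCG
CGTTACCAGTCTGAGTCGGGAGGTGCGCTAACCGTGTCGACAGTCTGCCCCAAGTAGAAAAAAAAAAAAA
AAAAAAA
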
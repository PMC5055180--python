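>V01
TAGAAAATCAAGCCGTCTCCTTCTCTCCATAGGGCGGCCATAAAGCTTTCCCTCTGGCTCCTGTAGAATTGTGCAAGAAGAGAACCGTATGTGATTTTCGGCGGGGTGAGGTCAACTATCTTGAAGTGGCTCCATTAGTGGTTTTTCCAGTAAAGCGTAGATGGACAGTCGTAAGGTCTGGGTCTGCCGCATAGTTACCCAATGGTTCCGACAGCGGCCGTTGCCTCCAGCAGCTGCCGGTTCCTTAAAGCTCTCACTTAATTTTGACATATGTGTAGAC
>V02
CGAGAGCGGACTTGATCCTGGGTCTGGCCGCTCCATCACAACTGGCCACGTGTTGACCGGTCATATAGATAGCGTCGGATGATTCGGGGTATACCCTGTCGGCAGTCTGGGGCCTACCTGAACCCATCGTCCATCGTCGTGCAAGTACGCAGGGGGCGGCGAGCTCTCAACCGCGACCCAGATGTTATTGCTAGAGAAAGCCCCCATATCCGGTCGATACGGGACTAGGTCACCCCGTCCGTGTAGAGTTAACTCCACCCCATGGTGTATTTGCCCTATG
>V03
AACAATTCTCATCCCCTGCGCTTAAAGGTTAGATCTTTAGAACTGACGGATTCCCGCTACTCGCCAACACTCAGCTCTGTACCTCAGCTTCCCTGCACACATAGGATTAGAGATCACAATGACGAAGGGGGTATTTAGTGAAAGTAATCTTTATCTACGGCGGACTGCTATGAGAAGACTTACTGTATTCATTACCTAGGGCCAAACCCGGGCACTAGATAACGGCATCGCACCTATCGCTAATTAAATCAGTAGGTTATGACCGAACGGATGTCAAACA
>V04
AAATAGAGGGACTTCAACTCTCGAACACACCCTCCAGCGACACATACTCCCATCCCGCACCCGTTCACTGGCTAACGGCGGCCCTGATGGCAAGAGTTGTTCCCCATTGATGCTGATCCGCTAAGGATAGTCGTTGAGTGAAGACTCATTTGCTGTACAATTCATAAACGTCACGTCAGCCCCCACGACTTCTAATAGCTTCCTAACCGTAAGATAACGAGGCGGAAGCTCCACCCAAGGCCTGCCGACTCAGTTTTGTTCCTCTTGCGCCTGCACAGGC
>V05
GTTCCCGTTGGCAAACCCTGATAATTAGCCGACAAATATGAGCATTGTAAACTGTATGAGGAGTATCCGTATTGTATAATACACGGGTAGTCGCATAAACCGAATATGTCGGGTGAGCCCTTGAGTCTCTTAGTCGGGCCCCAAATCTGAGGGACACGAAACGATACTGAGTACCTCCCTACCTTGTCTTAGAACCAAAAATCTAATGTTCCGACTACCGCTCCCCATTTCGAGATATAATGGTGGCATCATAGGTCTAGATACAGTCGGTTGTACTCTC
>V06
GGCTCTAAGTTTCCTACGACGCGCCCATTGTATAAGATCAAAGAATGGCCCCTATAGATACTACGAGTTAGATTGCTTATAGTGAGTGGTGATACTGAACTATGTTCACCCTACATTTCGCCCGCTAGGCGGGCATACACGCCCGCACGAGAATAGACCCCTCCACAGCTATCAACTACCTGTATCTCCCGTACGCGATCTCTACCAAGCCAGTGACAATGCGCTGGCATCTAACGGATCTAGTACCTACAACGAATGGGAGAGGCACCTTTGCGAAGCA
>V07
TTTCCTCAATCTTTGAGGGCGTGTTTTCAGACCCAACGTTACCAAAGATACTTGCACGGTTTGTACATAGGAGCGAATGGCGAGATTGCAGAAAACACATCCACGTAATGCGTGGGCTAGGGCCTAACTTCCCGCACTGAACTGCGATCTCGGTCAGCAGCGCATTGTGGAGGAATCGTAGGGCTCATAAACACGCGAATCATAGATCTTTCTACCGGCCAGCACAAACGCCATACCTGGAACGGGTCCTTCCGTACGCTGGCCACTTCGCTGTGTCGGA
>V08
CAGAGCCGGAGAGTTGTTAGTAGACTGTAGAATATTCTGGATGCATACGGAGCGCGTAGTGAAATGGTGCTGCTTTCACTCTGAACTGGGCCCCGAACAGGGACTGATTGGCTTTTTGTAGGTCTCGCTAAATCTGAGATCAGGGGTATAAGAGCGTTACACTCGGGATACAACAACTCCTACTTGGAATACGGAAAGTATCATGATCCGTTCCGCCTGCACACGAGCTCCTCGAATCAGGCGAGCTCAGTTCAGCATGAGGATAATTCATTGCGCCAAT
>J01
AATCGTCTGTTTGGCGCTGGATTAGCGGTCACGACTTGCGTGAATTCGGA
>J02
CTAATCGCTTTCGGCAGCGGCCGAAGTCAAAGACACCGCGTCTTCCGTCG
>J03
ATGGCAAGTTTTGGTTGTGGCCCCGAAATGCCTAGGACGTAAGACGTCGC
>J04
GGATCTCTGTTCGGAGAGGGCGATTTGCCCAAGCTCGTGCTCGCAGATAT
>J05
CGACCCAAGTTTGGTGGCGGACACGCGCTTGGCAGTACTGATCTTGAATC
>J06
CAGGCCGATTTCGGCCGGGGCCGAATCATTGCTCACCATGTATTTATGCT
>C01
GGATGCGTTTGAGCCATCAGAAGCAGAGGATATTCTAACGGGTCATTGATGGTCTGCCGACTTACGGT
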
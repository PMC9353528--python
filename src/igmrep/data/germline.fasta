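>IGHV1-1*01
TTTTTGATGTACACGAGTCGCGCTTTGAACTAGCTTTCGGCGGGTGCTTAGGTACATGACAGGATACAAAAGGTAGCCTGATATGTAGCTTAAAGCTCACCCTGAGCTGAACTCTGCCTTTATTGCGGTGGTCGCTACCAACCCGTACACGACGCACAAATTAACAACTGGTCTTTAACGATCGGAACTCGATGATGGAGCATAGTTTACCAAGACCCGACCAGCGCGCAGGTCAAGATAAGATGTACCGGCCCACGGCGATCCGTTTCCCCAGCATGATTGTGCAAGAGAG
>IGHV2-1*01
GCGCTTGGAAACTAGATGGCGGCCCCCCGCGCACTAGCTCCTAACTGCTTATCTACTCGGCACGGACTGCGGTGCAGAACTTACCGTGTAGGGTAGAAAAAAATGCTAATCGTTGAAAGCGGGACGCCGCACTTTAAATTTCCGACCACGCCGTTATCATATGGAACCTAGGCCTCCCATCTATCAACGTGGGGATTTGATTAACCGCACTACGGCCAGAGGGGGTGCACGTACTGCACGTCTCCCAATCGCTATAAGATGATCGGGACTAGGATACGGGTGTGCAAGAGAT
>IGHV3-1*01
CAAAGGAAAAGCTACTATCAATGAAGCTGAATGCGTCCGTTTAAAACAAAGTGATCGATTGTATTCAGTGGTGCTCACCGCTGCAGGTAAGGGACTAATCTTAATTTTAATTCTTAAATGGCCATATGTGCCAGAAAGGTACACAGAGCATTGCCATTTCGACGGAGTCGTCGCGTGAGTGGAGACATCGTCTGCCAGCTGCGCGCTGTACGCCGGGATTCCGTGGATGTTAGTTTCGGGCCAAAGAATCGCGAATTCAAGTAGATAGCTGAATTCCGTGTGTGCAAGACAT
>IGHV4-1*01
CGAATCTAGGTCGTTGCGTACACCGCCCTCCAGTCAGCTAGCGGACGGGATAATTTCATCATCAGTAATTGGAGGGGCGTAATCATAATGCAACGCGCGATCTTCTGTGATTTATTATGCGGTCTACTCTCCTGGTCACTAATACTACTTAAGGGCGCTCTTACGCATCGTCCTAGCCGATGGGGGGTAACTCTGCTAGGCTAAAAACAGTACTAGGGGGGTCGGGAGAAGATCACGATAGCGTTTCCAACATCTGCGGCCCTGACAGGACGATGCCAGTTGTGCAAGGGAG
>IGHV5-1*01
TGTGCGCAACCTAGGCGACGCGGCACGACAGGCGCATCCTCCCCTGGGATTAGTTGGCGCCTACGTGGTCGAATGTAGGTGTAATTTAATAGGGATATATTAGCAAGTCTTATTGGCTTTCCTACTCTCAGTATCACAGGACGATCCATGGCAGGCTTTGCTTATCGGTGACAGAATAATCCGCCCACTGATAGATAAGAAGGGACGCAACTCATCGATTTAAGCGAAATCAAATGGCTTCCGAGCACCGTTCTGTGCACTTTCGCACGACCTTGATAGTTGTGCCAGAGAT
>IGHV6-1*01
CGTGGTATAAGTCCTCCGGTGGGAAAAGCCCAAACCGTCATGTGGGTTCAGGCAACTCAGGCCATCTAGTCCGAAGTAGTGTATGGGTACGGTACGCTTGCAAAAAAAGCGGCACCAGTATTGTTCCCGATCCTGACCCCGCCGCAGGTCGGTATAATGTTAAAGTAGCGACTGCCCCGTCCTAACCCTACCCGGACCGCGCTGCGACTTAGAAAGCCTAGGCCTTCAAAATGAAGATTTACTTCCCGCGCCGTGAAGTCCTTCTGTCATGTGTGGTCAATGTGCTAGAGAA
>IGHV10-1*01
AGCGAGATCGGCTCGCCACGCAACCCTGAGGCGTGGCCTGTTATAGGCAAGACGCGTGTCTTCCCGATCCCAGCACACGAAAGTGGGACACCAGGATGGGGTCATACATTCGGACGTCATGTTTTCATCCAGCCCTCTGCTACCTGTGGGCACCTTACAGAAAGTCAGCTATCTGGAACCGAGCGGACCCACCGTCTCCGAACCCACTTAGAGACCCATGAGGTTACAGGGCAACTCGAGGCTACCCTTGGGTACCTATTCGCATAAACTGGGTATTAAGTGTGCAAGATAT
>IGHV11-2*01
ATCGGTAGCAAAGGGCAAGTAAGCGACACCAACGACTGGAGACACCAAGAGTAATACGTTGCATATACTTCACGTAAAAACCTAACCGCGGAACCGGTACGTGTCACCGACCGTTAGCTCAAGATTTTTCTGGCCCTGTCTCTCGACTCTATGGGGAGAGCTCAACATGCTGACAAGGATGCATATACTACCGAGCCAGACCAAGGTTGTGGCGAGACAGGCGCGGGTGGACCAAACAACCCTGAAGACGGCCTTACTCCCCCGTCTTCCGTAGATATTATGTATGAGATAC
>IGHV12-3*01
CCCGACAGGGCGAACCAGAAACCAGACGGGCGCGTGTTTTTGCAAACCCGACAGGGGTCGTTGAATTCGGAGATCAACAAGAGCGTGACTTACGAGCAGATGCCGCGCCATTCACGCACCCCGGCGTGGCTATAACAGTTCTCCCGATCGCACGACAGCGCGTAGCCACCACAACCTGATAAACCATTCACTAAATTACAGGCGATCGAAAGCCGGCATTTATTGGATCTAATGGACAAACTTCGGGCTGGTGCATAAATACAGACGTCAAGCATATATGTGTGCAGGAGAC
>IGHV14-1*01
ATTGGTATAAGGCAAACACACGAGATTCTTGCCTGGGCAGGAACACACACGAACGGCAGAGGCCCAAATAGTAGTCGGCAGTGACTAGCCAGATGTTAACGAAACAATCGCCACGTCCTGCTTATGAGTCCTCACCAGAGTCACTTTCTTTAGGCTACCGGTGCGTCTAAAGTCATCATGTGCAAGATCAGTCTCCCCGTATAAGTATTGTCATGCGGATGGCGGCGAGTAGTTCATTACACAGAGTCATGGCTACGCTCCATTTTAAATCAAGAGGGCCTGTGCAAGGGAT
>IGHD1-1*01
TATTACTACGGTAGTAGCTAC
>IGHD1-2*01
TATTACTATGATTACGACTAC
>IGHD2*01
TACGACGGCTACTGG
>IGHD3*01
TCTACTATGGTAACTACG
>IGHJ1*01
TACTTCGATGTCTGGGGCGCAGGGACCACGGTCACCGTCTCCTCA
>IGHJ2*01
TACTTTGACTACTGGGGCCAAGGCACCACTCTCACAGTCTCCTCA
>IGHJ3*01
TGGTTTGCTTACTGGGGCCAAGGGACTCTGGTCACTGTCTCTGCA
>IGHJ4*01
TACTATGCTATGGACTACTGGGGTCAAGGAACCTCAGTCACCGTCTCCTCA
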
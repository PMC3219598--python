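>AluY
GGCCGGGTGCCGGACCGCTTATGACTCCTTTTCGGGGAGGTACCACCTCCTTCCGGCGCACACACTCCCG
AGCAGGCATACGTCGCAAGTAGCCCAGCAGTAGCGAACGGGTACGTAAAGCACGGGGCTGAAAAATACAA
AATCAATGGTCGTGTATAGGTCAGAGCCGGCGCCAGTCCCGGCGGCGGTGGTCACCGCCGGGCCGCCCCG
CTTTATGCGCCGGCCTGTCCGGGGTACCATAAGTGGCCGCTGGCACACGAATAAGGATTGTTCCGTCCCT
C
>AluYa5
GGCCGGGTGCCGGACCGCTTATGACTCCTTTTCGGGGAGGTACCACCTCCTTCCGGCTCACACACTCCCG
AGCAGGCATACGTCGCAAGTAGCCCAGCAGTCGCGAACGGGTACGTAAAGCACGGGGCTGAAAAATACAA
AATCAATGGTGGTGTATAGGTCAGAGCCGGCGCCAGTCCCGGCGGCGGTGGTCACCGCCGGGCCGCCCCG
CCTTATGCGCCGGCCTGTCCGGGGTACCATAAGTGGCCGCTTGCACACGAATAAGGATTGTTCCGTCCCT
C
>AluYb8
GGCCGGGTGCCGGACCGCTTATGACTCCTTCTCGGGGAGGTACCACCTCCTTCCGGCGCACACACTTCCG
AGCAGGCATACGTCGCAAGTAGCCCGGCAGTAGCGAACGGGTACGTAAAGCACAGGGCTGAAAAATACAA
AATCAATGGTCGTGTATAGGTCAGAGCCGGTGCCAGTCCCGGCGGCGGTGGTCACCGCCGGGCCGTCCCG
CTTTATGCGCCGGCCTGTCCGGGGTACCATGAGTGGGAGGCGGCCGCTGGCACACGAATAAGGGTTGTTC
CGTCCCTC
>L1
GAATGGAACGCTTTTGATTAAAAGCACAGACGTAATAAGTGACTACGTGAAGCATAGGGCGGACAACGAC
AGGATCCAACCAAACAAACTACAGTACACGAAGTTTGCCATTTAAATATAGATCCTTAAAGTACAGGTCT
ATACTACCCCTTTCAAAAGCAACTATCGTTACGAACGCGGAACAGTGAAGTCTGAGAGAAAATTCTTTAA
CATGCTCAATACGTCCCTTTTGGCTACTTATGTTATGGATGGGATCACCGGGTTTTATTACTATATATTT
AGGGCCAAAACTAAAGAATGAAAGTCCGACAAATATAAATCCCTACGATAACGAGTAGGGGAGCTCACCT
TATTGATAAGATTGCCTCAACCTTTTGAGTGCTGTAATTGCAAGATCAACTATCGAGGATACACAAACTG
ATCCCCATATCCTTCCCGCATTGATTATATAACCGCATCCCTATAATAACGCAAAAGGACACTATGGTCT
TATGCATGTAATACGCATTTAAGTGTGAGGACCCAATTTTGTCATATCATTCTATTCAAGTAACGACAAC
AGAGTTTCAACAAAAATTCCTGTTGCAAGGACAGGATGCAGTTCATGTCAGCGTTCAGCTAGTTTATTAT
CGTGATTTTAGTTGCTTGTACACCATGGTTGTAGCGAGTACGGTAAGTATTGAGGATCGTTATTAGGACT
TAGTAAGTGTCAACCATCTATCAGCGATTAACCTTGCTCTACCAATTAAAAGTAGTTACCTTCCTGCTGT
TTTCAGCTTCGGTAAACCATCCATCAAAGGGGTTATATTTTGACTGACACGTTGTCGCAGTAAGCCTGAA
GATTCGGTAAACAACCCACTAGACATCGGTATCATAACAAAACTAACAATTATATCGTCTTAGTGGACCA
ACAGCACAGTTATCCATGCCGGTGAAATTCTTTCGCCGCCGCTTCGAATGCTATAGATGCTTGAACCCTA
TATTAAGCTTAAGGGAATTATCTGTCGTACGTGGATTTGGGTATTATTAGTCTTATAGGGAAGAGGAATC
CGTTAGTATCTAGCCGATAGATTCTGACATTTTGGATGCCACCTTGAGGCGTGATTCGACGATTGCAATA
GACTGCTGAAAAGGACAGTACATAGCCTAGATAAAGTGTACTAGGCGGTACAAGATACATACCAATGATA
TTGGAAGCGCGGGTTGCAGCGTGAAGATTACATTAACTTACGCGCCTCTCACGTGAAGCACACACAATTG
CCTTGATGAGCATTATTGTGGTTATTACAAGTGGATCGTACCTAGATCCTCGATACCTACGAGTACCAAT
CAGAATTGCGCGTTTAATAGGCATATCAAACTAGATTTGGGGCAACAACTTAATTTGATTTATGATGATA
TATACTCGGTCCGCAATAACTCGATCTCATCATAACGCACTAATAAAAGCCGATAATATTTGAATCATAG
TCATAAAAGGTCCCGAGCATACCCCCGGTGCATTATGACGGATGGGATCAGACTTCTGGGTTGCAATAAG
TGCGAGAAACCGATTTAGCACTTTTTAAGTGGATCGCAAACTTTATTCTTGCTATAGCTAACCCGTGTCA
AACACAGTTCCGTCACACTTCTCGTATATAACCGGTATCCTACATAAATAAGTACTGATGAAAGTAATGA
TTGTATGTGCTACTGCTACTAAAATGTTATGAGCGGAAAGTTCACATGATACCTTTTTCGGATTGTGAAG
CAATTTTGATTAGGATAAATAAACTTACAAGCTGATGTAAACCACACTGTGACTGTTTGGAGATTACTAA
TACCATTGAACTGATTGAGTAGAGGGAACGCAGTTAAAAGCTTGGCTGCAAGGCACTGATTAAGTGTCAA
TGGATATGACTATATAAGCCACGCCATCGTGGCATAGTGTAACTTATAACATGCCATTGCGCATTCAGAA
CTCATCGGACATAAACATGAACGGAAGATTGATGGACCGTTCGCCCTATGCGCGCTGGCTGATATGCGAC
TATAGAGCTGGCAATGTGAACGTGATAAGTATGGAAGGAAGGCCGCTATTGTCCGATATGTCTGCTACGC
GTCATTTAGATCTAAGTCCTAGTTTCAAAAATGCTCTTGACGATAGGCTGTACGTACTTTTTTTGATAAC
AAAAACGTGAACATTGAACTATCAAACATCTTTTAGACAGGTCACGACATAATGTTGCGTTTCTTAAGGG
AGGAATTATAGAGAACTCGTGACGCAGTTCCAGGGTGATAATTAAATCAAATCTAGATGGCATTTACGCC
AGTTGCGTACTGAGAGGAGCAAGAGTGGAACTTAGTGTACAGCTTTCTAGGTCGCGAGCGGCTCGACTAG
TCCCACACATACTGTTGGCCATCGTACATACCCAACAAGTTATATTGCACCGTCGGCAGACGTATCATTA
GTGTGGGCATTGACCTTGAGGAGGGGAGGAGTGTAATACAACGTGCGGTTTACTTTCACCTGTCAGATTT
GCCCTAGAGCCTGGTGATGTTGTATAAGAATACGAACTTTTGCATCTTTTTGCACTCGCCAGTTGCATTT
TGACATTGAGTAGAATCCGAAGCAAAAGTTATCTGACATGAGTTAAGACTCACGCGTGACTTTAACTAGA
GCTTGGTCTGTTTGTGTAGTAAGTCCCGTGAAACCATGTGCATCATTAATCGCTAGTTAAAATTTGATAT
GTTCCGAATGGATTTGATCTCCGTTGTTCAAGTTTACGGCTAAATAAGGCTGCGTTTATCAATCCTAGAC
CGACTCGCAAGATGTCGTCGCAGATTCCACTTCAGTCGAAACGAATTGCATAGAATTATACTTTTCCCTC
GAGGTAACTGAAAGAGATTACATGGCTAATCGCTGGGGTGCGGAGGATGTAATTAGTATCGAAGCCTGTT
ACGTGTAACCGTCCGCACGTACGTATCTGAAATGCACCTTAATGCAAGCTGGTGGCCCTAAACGAAACGT
GTAATCGTTATATAACATTGGCGTGGTTGAAATAATATTCTTCATCAAAGCCTATGAAAGGACATTTTCA
ACTTCGTCCCGGTGGCACCTCATAGTTGGCACTGATTACATGTCTTAGTCGGTGGTCAAGGCATTATAAG
CGCTTTTATCCTTTGACTCTAGGACTACGACCTACATTCTATTAAATAGACGCAGTGATAGGGCTACATG
CATACAAGCCACTGTGCTTCGCTATGTTCTAAAACAAAGCGTAACCACATTAGAAAAATACCACCATTTT
TGGATTCATACTCTACGACTTTGGACGCTAGACCTGTTAGTTCGCAACATATAATCTTTTAGGGCGTATT
TTTTGACTTTTCGTTATGGCGAAAACTGAAATAGAAACAATTTAGATTTCTTATCAATTGATCAATCGAC
GATAGTGTCGACCCTAGAATCAAAGAAGTGAAAGATAGGATGTAACACTTACATTTATTTTGACTTTAAA
AGAAATTGGAAGCAGTTATAGCTAGCGAGCCGGTTACTACCCGGACTCGGTTTATCTTATCCTATCGCCT
ACTTAGAGACTATCCTTACCTTGCCGATGCACTCAACAGAGTTCCACCGAGCAAAGTTTAGCGCACGAGT
GTCAAAAGTGGAATAAGTGGTCATTACTGATAATTTGGATCCAAATTGGGACGCAGGATAGGCTTACAGA
GAGAAGACGGTATACCATGCAGTATTAGTAGCCCATCTTGCATTTTCTTGGTTTTTGTATTCCTAATCAA
AACTTTACGACATTTTTTATTTTGTTGCTACTTTAGAAAACACGAAGCACACTGAAGAATAATTGACCTT
GCTGAGTTGTTAAATTTGGGGTAAACTGACGGTGTCACTACTAATCATTACATTTTCGTTAGATTCTCTT
AGGGAAGTCTGTGTTATAAGATTTATTAATAAAGCCTATTAGTTGGTCGAAGTTCGACCGGTACCGATGT
TAGTATTCTTATTAGAGAATAGGGTGCCGTGACAAAATTAGTACATGACGATCCTATACGTTGGCAGAAA
ATCTCTGAATAACGAATATACACTGCTTTGAGTATGCCCGGAATTCATTTACATTGAAAAGTTGACATAA
GAATCTCAATTTCGTGACCTAAACGATTTTCGAACAAGTCAAAGATTAAACCGAAGATGAACAACTGGCT
CAATTAGTAGAACCGTCAGTCTATTGACTCTCCTTGCCGCAGAACAGCGTTTAATTTCTTAGTCTAATGA
TAAAATTAACGTAATATTGGAACGAACCATGTATTTGGCTATAATTGGTTAGCGTCGATACCTGTACTAA
GGGTGTGTTTACTGCTTCGATTAACAACAAAAATAAGAGACCTACAGGGCTGATGCAGCTGACTAGCAGA
CCCTTGTATCAACAAAATCGGCTCTCAACTGTTCCACGCGTGATAGCTGCAGGCAGCTTTGATCCCAGGA
TGGGACATGAAGCATTGCCGAGGTTGCAGCATACAGCCGTTGGGATCGTTAAGAATGTTGTGTTGAAAAT
GAACATTCAAAGCAGTATCCAGCACCTGTAAAAACGACTTTGCACTGCCTACACCTCGCCGCAAGCTTTT
AGAATTGAAAGCGGCATATACATTACTCTGCGAGGAATTCTTCCTGAATTAATGCGATAAGGTCGTTAAC
AACTCGCTTAACTTGCTTCGTAAGCGTTTGGACAAAGAAACTGATCGGGGTCTTTGCAAGTGTAAATGAC
ATGTAATGAATTTTTATACCCGCGATGTCTAGTCGGAACAGGATCCATCATGCTAGGATTTACATCAGGT
ACCTAGGTTGTGGACCTCCAATTTACGCAACGTTTCTGTACAGAATAATCATATAAGTAGAGCCATTATG
GTGAGTTATCCCGTGCAACTGGCTCACTCTTGAAGTAGTATTCTTAAGAGACTGTTAGATCAATCATGCT
TTCAATTAACGTCGATTCGTATGTTTTATGTCTTCCTAGCGCAGAAACAGTTACCTATCATGAAAACTCC
CATACGACATTTTGAGTAAGGAGGAACTCTTCCAACTTAGGACTTAGCTTTGTCAGGGTTTGGACCTTGC
TTATATGATGGTTCCTAGATAAATCCATCTGAACTTTTTTGAGTGCCATGTTCTTTCCCTTTAGACCACC
CGACCAGTAGACGTACGCACAAACAGGCGCATTGTAGATGGAATTGAGTATAGTATAACGAACGGCTGTA
GTTACATAAAGAACTATAGTGATAGTTGATAAACATTTTGGACTAACATTTGTTTTGTCTAACTACCATT
TGACTAGGTTCCTCGACTCGACACGGGAATCGTGACTCTTTTCTAGAAGGAAAGCAATATACCCGGGTAG
TCTTTGCTACTCGTTCTCGTACCTTGGGATTTTGTCAAACACGGCGCATTAACCTCCAAAGGCGTCGATT
CAATACGCCCTAGACCTAATGCGATAGTCACGGGAGCTAGGTCAGTATATTAACCTGCAGGTTCATCGAT
TCATTTGTGAATGCGTTATGGATCTCTTGGATTATCAAATTTTATCCTAAACGCGAGACTAATTTAATCG
TGCCTGTTTTAGTCATGTTTCATTTTCTTTGCTGAACAGGATTTAGGATGGCGTCTTGATACCGATGGAA
GCGTCGACTCAGAACCGACTGGTAATCTTTTAGCTTCTAGGACGGATATGATCACAGCCAGTTGTATCCC
CTGCGACACTAGTCTCCCTCCACTTAAAATCTTCTTTAGAGAATGTCAGATGCCAAATGCTCCAAAGTGA
TTCTAACACACGTAAGATGTGCAATGCTTCTCCATATTTAAATACTCTGAATATGTAATCTGCAACACAT
AGGCAGCACTGTAAACTTTAACGAGCTACCACACAAGCGTAGAATTCCTGGTGGGGCCGCAGGATCATAT
TTAGTATGTACGATATGCTGACGAAACCTGCATCGAGCATATCCTTTTGC
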
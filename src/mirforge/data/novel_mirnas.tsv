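id	mature_5p	mature_3p	precursor
ssa-mir-novel-1	UCAGUGAUGUGUACGCCAAAGGU	UCGGCAUACACAUCACUGACA	UCAGUGAUGUGUACGCCAAAGGUGUAAAGCUUCAAGUUCCUCGGCAUACACAUCACUGACA
ssa-mir-novel-2	AGUUUCCCGGACACAGAUUAAGCC	UUUUGUCUGUCUGGGAAACCGG	AGUUUCCCGGACACAGAUUAAGCCUAGUCAUAAUUAUUAUGUUUUGUCUGUCUGGGAAACCGG
ssa-mir-novel-3	UGACGAUACCUUUGGAACAAGA	UUGUACCAAUAGUAAAGUCUGA	UGACGAUACCUUUGGAACAAGAGGUGAAUUACGUCUUAUGCUCUUGUACCAAUAGUAAAGUCUGA
ssa-mir-novel-4	CGGAUCGCUGCGUUCACCAUU	AUGGUGAAUGCAACGAUAAGGC	CGGAUCGCUGCGUUCACCAUUAUAUUUAACUUCAACAGAAUGGUGAAUGCAACGAUAAGGC
ssa-mir-novel-5	UACGGUAUGUACUGUAGGCUAC	UAGGCUACGGUAUGUACUGAAG	UACGGUAUGUACUGUAGGCUACGGUAUGUUAUGUACUGUAGGCUACGGUAUGUACUGAAG
ssa-mir-novel-6	UGAGCCUUGUCCUGGACUAAGA	UCAGUCCAUGACUAGGCUUAAC	UGAGCCUUGUCCUGGACUAAGAAGUACUUCCAAUGGCUAUUUUCAGUCCAUGACUAGGCUUAAC
ssa-mir-novel-7	UUGCUGGUGACACUGUCUGUGA	AAGGCACACUUCACCAGUAUGG	UUGCUGGUGACACUGUCUGUGAUUUAUUUAGAAUUCAAGGCACACUUCACCAGUAUGG
ssa-mir-novel-8	AGACACCUGACACAGCCCCCAUU	UGGGUCUGUGUCUAUUGUCUCU	AGACACCUGACACAGCCCCCAUUCUAUCUCAUAAAAGUGGGUCUGUGUCUAUUGUCUCU
ssa-mir-novel-9	UAGGCGUGUCACUGCGUGUCACA	UGCGCACGGGGCCACGCUCUGC	UAGGCGUGUCACUGCGUGUCACAGUCACUGCUUGCGCACGGGGCCACGCUCUGC
ssa-mir-novel-10	AGGUCUGUUUGUGCUGUCUUCC	GUGACUGCACAAACGGAUCUGG	AGGUCUGUUUGUGCUGUCUUCCAUGGCUUUGGUGACUGCACAAACGGAUCUGG
ssa-mir-novel-11	AUUGUUCAGGGCAUUCAUUUCU	UAAGUGAACCCUUGAGACAAUU	AUUGUUCAGGGCAUUCAUUUCUUGUGAACCAAUCAAUAAGUGAACCCUUGAGACAAUU
ssa-mir-novel-12	UUCGCCCCUGAGGACACACGGU	CCGAAUCCACAGAAGUGAUGC	UUCGCCCCUGAGGACACACGGUGUUUUCUUUUAAUAGCACCGAAUCCACAGAAGUGAUGC
ssa-mir-novel-13	CCUUGACCACGUAACCUGACCA	UUAGGUCAGAUGUGGUCAGGAGA	CCUUGACCACGUAACCUGACCAUAGUUUUCUUGGUUAGGUCAGAUGUGGUCAGGAGA
ssa-mir-novel-14	GGGAAUAUACAUGACUGUGAUU	UCACAGUCGUGUAUAUUCCCUC	GGGAAUAUACAUGACUGUGAUUAUGAUUGAAGAGAAUAAUCACAGUCGUGUAUAUUCCCUC
ssa-mir-novel-15	CAGAGCUCUGCUAUCUGCUGUCU	AAGGAGAAAACAGAGCUCUGCU	CAGAGCUCUGCUAUCUGCUGUCUGUAUCUUGUUAAAGGGGAAGGAGAAAACAGAGCUCUGCU
ssa-mir-novel-16	UUGCUGUUGACACUGUCUGUG	UCAAGGCACACUUAACCAGCAUGG	UUGCUGUUGACACUGUCUGUGAUUUAUUUAAGGCACACUUCAAGGCACACUUAACCAGCAUGG
ssa-mir-novel-17	GCGUCUCAGAGGUCAAACACAGU	UGUGUUAGGCCUCCGAGUCUGA	GCGUCUCAGAGGUCAAACACAGUAAGUCAUAUUAAGCUGUGUUAGGCCUCCGAGUCUGA
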
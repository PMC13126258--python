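{
 "seed": 20240917,
 "genes": [
  {
   "name": "HLA-A",
   "wildtype_promoter": "ATCATGTAAAGATAACTGTC",
   "wildtype_coding": "ACGTTTTACGGAGGAAATTGTTTCAACACAATGGAACCCCAGCCCAGGGCAAGGCAGCAC",
   "wildtype_protein": "TFYGGNCFNTMEPQPRARQH",
   "effect_category": "antigen_presentation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "HLA-B",
   "wildtype_promoter": "TCCGTAAGCGACGGAGCAGT",
   "wildtype_coding": "CCACCCATTTATTGGCACGCGGTCTCCCTTCCGATGACACCAACGGCTCCGCCCATCGGG",
   "wildtype_protein": "PPIYWHAVSLPMTPTAPPIG",
   "effect_category": "antigen_presentation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "HLA-C",
   "wildtype_promoter": "TTTATTGGGTTTTGTGGAAG",
   "wildtype_coding": "CTGTCGATCACCAGCCTAGGCAAGGGTAAGGGTGCTAAATGCAGGACTGCGAGGAACAAA",
   "wildtype_protein": "LSITSLGKGKGAKCRTARNK",
   "effect_category": "antigen_presentation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "JAK1",
   "wildtype_promoter": "CGTTCTCTGCGACTAGGAGG",
   "wildtype_coding": "TTGACCGTGGCGAGATCCCGTGAAGATAAACCTAGAAGATTGGATCATCAGAGTGAACAT",
   "wildtype_protein": "LTVARSREDKPRRLDHQSEH",
   "effect_category": "antigen_presentation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "JAK2",
   "wildtype_promoter": "GACCAGGCCCTATCGAGTTG",
   "wildtype_coding": "TTATGGGTTCTAGATTTACAGCGCTGGATGACTATGCGACTCTCCCGATTCTGGTTATCA",
   "wildtype_protein": "LWVLDLQRWMTMRLSRFWLS",
   "effect_category": "antigen_presentation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "B2M",
   "wildtype_promoter": "AGGTATCGCGTTATTCGCAT",
   "wildtype_coding": "GCTTTCGCCAGAAGGTATTTAATTCGCATGTACTGTCGAGAGAGAGAAAACCATGGGTGG",
   "wildtype_protein": "AFARRYLIRMYCRERENHGW",
   "effect_category": "antigen_presentation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "TAP1",
   "wildtype_promoter": "TTACCCCTGCAAGTGGAAAA",
   "wildtype_coding": "ACTGACACCCACTTGGCAAGTTTGTGTAGACGCCAGATGGTACCTGTATATCCTGTGCCC",
   "wildtype_protein": "TDTHLASLCRRQMVPVYPVP",
   "effect_category": "antigen_presentation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "TAP2",
   "wildtype_promoter": "CCGGGACAGGCCAGGATTTA",
   "wildtype_coding": "ATTGATTTAAGCTGGAGGAAACCTTTACGCAGTTGTAGACGATCCAGATCTTGTCACAGA",
   "wildtype_protein": "IDLSWRKPLRSCRRSRSCHR",
   "effect_category": "antigen_presentation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "CD274",
   "wildtype_promoter": "CTATTTTAGTAGAGAAGTAA",
   "wildtype_coding": "CTGGTCGAGGACAGGATTGGGCGTTGGAAAAGAGCGGTATGTCTGTCCTTTACGGGGTGG",
   "wildtype_protein": "LVEDRIGRWKRAVCLSFTGW",
   "effect_category": "checkpoint",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "BRCA1",
   "wildtype_promoter": "GACCTCCACGGACACTCCTT",
   "wildtype_coding": "TTTGTACCTGACAACGCATTTTTATACAATCCGCATACTTATCCATGGGTCATAACGTCA",
   "wildtype_protein": "FVPDNAFLYNPHTYPWVITS",
   "effect_category": "genomic_instability",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "BRCA2",
   "wildtype_promoter": "CGCGTTCGGGTCATCAATCC",
   "wildtype_coding": "AGTCATTGGCCATTCGCTGAGTCCCATGGGGGAAGAACTTTCCACTTTCAGTTCGGCACA",
   "wildtype_protein": "SHWPFAESHGGRTFHFQFGT",
   "effect_category": "genomic_instability",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "TP53",
   "wildtype_promoter": "TGGCACGCCCCTTGAGGAAT",
   "wildtype_coding": "CCTTACTTGACTCAACTTGCGGCTAGCGTAAGCGTCGATGGTAGCGAGTCTCATTTGATA",
   "wildtype_protein": "PYLTQLAASVSVDGSESHLI",
   "effect_category": "tumor_suppressor",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "RB1",
   "wildtype_promoter": "TTTGCGCTAGGCGGGACTTA",
   "wildtype_coding": "ACCGCCCCGCATTGTCTTTTTACGTTATTTATCAACGCGTCCTCCTACGAGACTCCCGAA",
   "wildtype_protein": "TAPHCLFTLFINASSYETPE",
   "effect_category": "tumor_suppressor",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "CDKN2A",
   "wildtype_promoter": "TTCCCCCTGATCCCGGTTTC",
   "wildtype_coding": "ACTAAGTTAAAGGCTGCAACGACTAGGAGACAATCAAGGGTTCCAAGTCTTCCTTGTCCA",
   "wildtype_protein": "TKLKAATTRRQSRVPSLPCP",
   "effect_category": "tumor_suppressor",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "MYC",
   "wildtype_promoter": "ATGGCAGGGAATAATCGTAT",
   "wildtype_coding": "CGTGTACAACCCAGAGCCAAGCAGTGCCATCTTGGCAATCGAATGTGTTTGGGCAGTCAC",
   "wildtype_protein": "RVQPRAKQCHLGNRMCLGSH",
   "effect_category": "proliferation",
   "effect_direction": "mutation_benefits_tumor"
  },
  {
   "name": "RAS",
   "wildtype_promoter": "AGCAATGCCTACCGTCGCTT",
   "wildtype_coding": "ACGTTATTGGTATTCCACCGACAGTGCGCCTGTCAAGCGCATGCACCCATAATGGAGTAT",
   "wildtype_protein": "TLLVFHRQCACQAHAPIMEY",
   "effect_category": "proliferation",
   "effect_direction": "mutation_harms_tumor"
  },
  {
   "name": "EGFR",
   "wildtype_promoter": "ACCTTACCGGTTACTAACTG",
   "wildtype_coding": "CCAAATGTTTCCCTAAAGCGGCGTTTAGCCTATGGTGAACTAGCGGGCCAAAATGATGTC",
   "wildtype_protein": "PNVSLKRRLAYGELAGQNDV",
   "effect_category": "proliferation",
   "effect_direction": "mutation_harms_tumor"
  },
  {
   "name": "HER2",
   "wildtype_promoter": "TGTGGGGGTCTAAAAAGAGT",
   "wildtype_coding": "AGCGATATCGATATCCGCCTTGTGTTCCAAACCCTTGAACAGTTCGACCGTGCTAACAGG",
   "wildtype_protein": "SDIDIRLVFQTLEQFDRANR",
   "effect_category": "proliferation",
   "effect_direction": "mutation_harms_tumor"
  },
  {
   "name": "APC",
   "wildtype_promoter": "TTACCACCCCATCACATAAT",
   "wildtype_coding": "TCGTTCTGGCAAGCACCACATTTGCGCCGTCAGGGTGATGAGAACAGCGCTGACGGGGCG",
   "wildtype_protein": "SFWQAPHLRRQGDENSADGA",
   "effect_category": "division_reduction",
   "effect_direction": "mutation_benefits_tumor"
  }
 ]
}
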
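{
  "asgard_core": {
    "variant": "archaeal",
    "provenance": "Canonical complete Lokiarchaeote (MK-D1-like) arrangement: the S10-spc core of 14 universal genes with the 4 Archaea-Eukarya-specific genes (RNP1, S4e, L32e, L19e) interleaved; the small S10 cluster uL3-uL4-uL23 elsewhere with uL2 independent",
    "mutation_rate": 0.05,
    "contigs": [
      [
        {"fillers": 3},
        {"block": ["uS19", "uL22", "uS3", "uL29", "RNP1", "uS17", "uL14",
                   "uL24", "S4e", "uL5", "uS14", "uS8", "uL6", "L32e", "L19e",
                   "uL18", "uS5", "uL30", "uL15"], "strand": "+"},
        {"fillers": 15},
        {"block": ["uL3", "uL4", "uL23"], "strand": "+"},
        {"fillers": 6},
        {"block": ["uL2"], "strand": "+"},
        {"fillers": 3}
      ]
    ]
  },
  "ecoli_s10_spc": {
    "variant": "bacterial",
    "provenance": "E. coli-like contiguous 21-gene S10+spc block (including the 5-gene small S10 cluster) followed immediately by the alpha-operon block",
    "mutation_rate": 0.05,
    "contigs": [
      [
        {"fillers": 3},
        {"block": ["uS10", "uL3", "uL4", "uL23", "uL2", "uS19", "uL22", "uS3",
                   "uL16", "uL29", "uS17", "uL14", "uL24", "uL5", "uS14",
                   "uS8", "uL6", "uL18", "uS5", "uL30", "uL15"], "strand": "+"},
        {"block": ["bL36", "uS13", "uS11", "uS4", "rpoA", "bL17"], "strand": "+"},
        {"fillers": 3}
      ]
    ]
  },
  "bsubtilis_str": {
    "variant": "bacterial",
    "provenance": "B. subtilis-like str cluster of nine contiguous genes co-occurring with the L11-L1-L10-L12 cluster",
    "mutation_rate": 0.05,
    "contigs": [
      [
        {"fillers": 3},
        {"block": ["nusG", "rpoB", "rpoC", "nusA", "uS12", "uS7", "fusA",
                   "EF1a", "uS10"], "strand": "+"},
        {"block": ["uL11", "uL1", "uL10", "uL12"], "strand": "+"},
        {"fillers": 3}
      ]
    ]
  },
  "bin6_split": {
    "variant": "archaeal",
    "provenance": "Heimdallarchaeote bin6-like complete genome in which the S10-spc cluster is split into three segments: uL22..uS14 (ten genes), uS8-uL6, and L32e-L19e-uL18-uS5-uL30-uL15",
    "mutation_rate": 0.05,
    "contigs": [
      [
        {"fillers": 2},
        {"block": ["uL22", "uS3", "uL29", "RNP1", "uS17", "uL14", "uL24",
                   "S4e", "uL5", "uS14"], "strand": "+"},
        {"fillers": 8},
        {"block": ["uS8", "uL6"], "strand": "+"},
        {"fillers": 8},
        {"block": ["L32e", "L19e", "uL18", "uS5", "uL30", "uL15"], "strand": "+"},
        {"fillers": 2}
      ]
    ]
  },
  "b35_misannotated": {
    "variant": "archaeal",
    "provenance": "Lokiarchaeote B-35-like genome: complete S10-spc core with six members (uS3, RNP1, uL24, uS14, L32e, uL15) mislabelled as hypothetical proteins",
    "mutation_rate": 0.1,
    "relabel": ["uS3", "RNP1", "uL24", "uS14", "L32e", "uL15"],
    "contigs": [
      [
        {"fillers": 3},
        {"block": ["uS19", "uL22", "uS3", "uL29", "RNP1", "uS17", "uL14",
                   "uL24", "S4e", "uL5", "uS14", "uS8", "uL6", "L32e", "L19e",
                   "uL18", "uS5", "uL30", "uL15"], "strand": "+"},
        {"fillers": 3}
      ]
    ]
  },
  "thor_hsp20": {
    "variant": "archaeal",
    "provenance": "Thorarchaeote bin8/bin27-like genome: complete S10-spc core with a horizontally acquired Hsp20 (small heat shock protein) gene inserted inside the cluster and uL18 annotated as a pseudogene",
    "mutation_rate": 0.05,
    "pseudo": ["uL18"],
    "contigs": [
      [
        {"fillers": 3},
        {"block": ["uS19", "uL22", "uS3", "uL29", "RNP1", "uS17", "Hsp20",
                   "uL14", "uL24", "S4e", "uL5", "uS14", "uS8", "uL6", "L32e",
                   "L19e", "uL18", "uS5", "uL30", "uL15"], "strand": "+"},
        {"fillers": 3}
      ]
    ]
  },
  "bin132_missing": {
    "variant": "archaeal",
    "provenance": "Lokiarchaeote bin132-like genome: S10-spc core present but the universal genes uL3-uL4-uL23 entirely missing; uL2 occurs independently",
    "mutation_rate": 0.05,
    "contigs": [
      [
        {"fillers": 2},
        {"block": ["uS19", "uL22", "uS3", "uL29", "RNP1", "uS17", "uL14",
                   "uL24", "S4e", "uL5", "uS14", "uS8", "uL6", "L32e", "L19e",
                   "uL18", "uS5", "uL30", "uL15"], "strand": "+"},
        {"fillers": 6},
        {"block": ["uL2"], "strand": "+"},
        {"fillers": 2}
      ]
    ]
  },
  "ar10": {
    "variant": "archaeal",
    "provenance": "DPANN archaeon GW2011_AR10-like complete single-scaffold genome: str-L30e, S10-spc (small cluster + big core), alpha-L18e, and L7ae/S24e-S27ae clusters co-occur contiguously; the L31e and L11-L1-L10-L12 clusters occur separately",
    "mutation_rate": 0.05,
    "contigs": [
      [
        {"fillers": 2},
        {"block": ["rpoH", "rpoB", "HP", "rpoA1", "rpoA2", "L30e", "nusA",
                   "uS12", "uS7", "fusA", "EF1a", "uS10"], "strand": "+"},
        {"fillers": 5},
        {"block": ["uL3", "uL4", "uL23", "uL2", "uS19", "uL22", "uS3", "uL29",
                   "IF(Sui)", "RNP1", "uS17", "uL14", "uL24", "S4e", "uL5",
                   "uS14", "uS8", "uL6", "L32e", "L19e", "uL18", "uS5", "uL30",
                   "uL15", "secY"], "strand": "+"},
        {"block": ["HP", "L34e", "L14e"], "strand": "+"},
        {"block": ["uS13", "uS4", "uS11", "rpoD", "tRNA(leu)", "L18e", "uL13",
                   "uS9", "rpoN", "uS2"], "strand": "+"},
        {"block": ["HP", "gltX", "HP"], "strand": "+"},
        {"block": ["L7ae", "S28e", "L24e", "ndk", "dut", "infB", "S6e",
                   "eIF2g", "Utp24", "rpoE1", "rpoE2", "S24e", "S27ae"],
         "strand": "+"},
        {"fillers": 10},
        {"block": ["gcp", "uS15", "HP", "S3ae"], "strand": "+"},
        {"fillers": 20},
        {"block": ["S19e", "COG2118", "L39e", "L31e"], "strand": "+"},
        {"fillers": 20},
        {"block": ["uL11", "uL1", "uL10", "uL12"], "strand": "+"},
        {"fillers": 2}
      ]
    ]
  },
  "pr6_strand_mix": {
    "variant": "archaeal",
    "provenance": "Heimdallarchaeote PR6-like genome: uL12-uL10-uL1 on the minus strand contiguous with the S19e..eIF6 section on the plus strand, followed by RBP..spt5 on the minus strand; uL11 split from its cluster; ftsY-pfdA-LXa independent",
    "mutation_rate": 0.05,
    "contigs": [
      [
        {"fillers": 2},
        {"block": ["uL12", "uL10", "uL1"], "strand": "-"},
        {"block": ["S19e", "COG2118", "L39e", "L31e", "eIF6"], "strand": "+"},
        {"block": ["RBP", "ftsZ", "secE", "spt5"], "strand": "-"},
        {"fillers": 15},
        {"block": ["uL11"], "strand": "+"},
        {"fillers": 15},
        {"block": ["ftsY", "pfdA", "LXa"], "strand": "+"},
        {"fillers": 2}
      ]
    ]
  }
}
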
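{
  "name": "malaria_host_v1",
  "amplicons": [
    {
      "amplicon_id": "G6PD_1",
      "gene": "G6PD",
      "chrom": "X",
      "start": 154532700,
      "end": 154533199,
      "sites": [
        {"chrom": "X", "pos": 154532738, "rsid": "rs2230036", "ref": "C", "alt": "T", "label": ""},
        {"chrom": "X", "pos": 154533025, "rsid": "rs76723693", "ref": "A", "alt": "G", "label": "968"},
        {"chrom": "X", "pos": 154533122, "rsid": "rs137852327", "ref": "C", "alt": "T", "label": ""}
      ]
    },
    {
      "amplicon_id": "G6PD_2",
      "gene": "G6PD",
      "chrom": "X",
      "start": 154534050,
      "end": 154534649,
      "sites": [
        {"chrom": "X", "pos": 154534125, "rsid": "rs137852328", "ref": "C", "alt": "A", "label": "680"},
        {"chrom": "X", "pos": 154534177, "rsid": "rs5986875", "ref": "G", "alt": "A", "label": ""},
        {"chrom": "X", "pos": 154534440, "rsid": "rs5030872", "ref": "T", "alt": "A", "label": "542"},
        {"chrom": "X", "pos": 154534527, "rsid": "NA", "ref": "T", "alt": "C", "label": ""}
      ]
    },
    {
      "amplicon_id": "G6PD_3",
      "gene": "G6PD",
      "chrom": "X",
      "start": 154535100,
      "end": 154535599,
      "sites": [
        {"chrom": "X", "pos": 154535277, "rsid": "rs1050829", "ref": "T", "alt": "C", "label": "376"},
        {"chrom": "X", "pos": 154535443, "rsid": "NA", "ref": "G", "alt": "A", "label": ""},
        {"chrom": "X", "pos": 154535468, "rsid": "NA", "ref": "G", "alt": "T", "label": ""}
      ]
    },
    {
      "amplicon_id": "G6PD_4",
      "gene": "G6PD",
      "chrom": "X",
      "start": 154535760,
      "end": 154536259,
      "sites": [
        {"chrom": "X", "pos": 154536002, "rsid": "rs1050828", "ref": "C", "alt": "T", "label": "202"}
      ]
    },
    {
      "amplicon_id": "HBB_1",
      "gene": "HBB",
      "chrom": "11",
      "start": 5226800,
      "end": 5227299,
      "sites": [
        {"chrom": "11", "pos": 5226867, "rsid": "NA", "ref": "C", "alt": "G", "label": ""},
        {"chrom": "11", "pos": 5226925, "rsid": "rs33915217", "ref": "C", "alt": "A", "label": "beta_thal"},
        {"chrom": "11", "pos": 5226932, "rsid": "rs35578002", "ref": "G", "alt": "T", "label": ""},
        {"chrom": "11", "pos": 5226943, "rsid": "rs33950507", "ref": "C", "alt": "T", "label": "HbE"},
        {"chrom": "11", "pos": 5226963, "rsid": "rs33972047", "ref": "T", "alt": "C", "label": "beta_thal"},
        {"chrom": "11", "pos": 5226966, "rsid": "rs35382661", "ref": "A", "alt": "C", "label": ""},
        {"chrom": "11", "pos": 5227002, "rsid": "rs334", "ref": "T", "alt": "A", "label": "HbS"},
        {"chrom": "11", "pos": 5227003, "rsid": "rs33930165", "ref": "C", "alt": "T", "label": "HbC"},
        {"chrom": "11", "pos": 5227013, "rsid": "rs713040", "ref": "A", "alt": "G", "label": "beta_thal_HPFH"},
        {"chrom": "11", "pos": 5227072, "rsid": "rs386134236", "ref": "A", "alt": "G", "label": ""}
      ]
    },
    {
      "amplicon_id": "ACKR1_1",
      "gene": "ACKR1",
      "chrom": "1",
      "start": 159204550,
      "end": 159205049,
      "sites": [
        {"chrom": "1", "pos": 159204646, "rsid": "NA", "ref": "A", "alt": "C", "label": ""},
        {"chrom": "1", "pos": 159204893, "rsid": "rs2814778", "ref": "T", "alt": "C", "label": "Fy"}
      ]
    },
    {
      "amplicon_id": "DANTU_1",
      "gene": "Dantu_intergenic",
      "chrom": "4",
      "start": 143781100,
      "end": 143781599,
      "sites": [
        {"chrom": "4", "pos": 143781321, "rsid": "rs186873296", "ref": "A", "alt": "G", "label": "Dantu"},
        {"chrom": "4", "pos": 143781342, "rsid": "NA", "ref": "G", "alt": "T", "label": ""}
      ]
    }
  ]
}
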
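"""Published study metadata used as inputs to bookkeeping computations.

These tables transcribe the printed strain and cohort counts for the fifteen
major traditional probiotic (sub)species and the eight public fecal-metagenome
cohorts. They are inputs (sample sizes), not results: every derived quantity
(pair counts, totals) is computed from them at run time.
"""

from __future__ import annotations

#: retained high-quality genomes per (sub)species after the three-stage QC
RETAINED_STRAINS: dict[str, int] = {
    "Ba. subtilis": 38,
    "Bi. infantis": 19,
    "Bi. longum": 35,
    "Bi. lactis": 22,
    "Lb. acidophilus": 20,
    "Lb. bulgaricus": 15,
    "Lb. casei": 33,
    "Lb. fermentum": 31,
    "Lb. gasseri": 25,
    "Lb. helveticus": 16,
    "Lb. paracasei": 52,
    "Lb. plantarum": 9,
    "Lc. cremoris": 25,
    "Lc. lactis": 61,
    "Sc. thermophilus": 43,
}

#: per-cohort fecal metagenome sample sizes: (total, control, case)
COHORT_SAMPLES: dict[str, tuple[int, int, int]] = {
    "Obesity": (200, 105, 95),
    "T2D": (368, 185, 183),
    "ACVD": (385, 171, 214),
    "CD": (102, 53, 49),
    "CRC": (147, 57, 90),
    "LC": (237, 114, 123),
    "AS": (207, 114, 93),
    "RA": (169, 74, 95),
}

#: published pan-genome index per (sub)species (openness statistic)
PAN_GENOME_INDEX: dict[str, float] = {
    "Lb. acidophilus": 1.24,
    "Bi. lactis": 1.29,
    "Lb. plantarum": 1.70,
    "Bi. infantis": 1.81,
    "Ba. subtilis": 1.82,
    "Lb. bulgaricus": 2.02,
    "Lb. gasseri": 2.44,
    "Lb. helveticus": 2.55,
    "Lb. casei": 2.64,
    "Lc. cremoris": 2.68,
    "Bi. longum": 2.73,
    "Sc. thermophilus": 2.76,
    "Lb. fermentum": 2.81,
    "Lb. paracasei": 3.10,
    "Lc. lactis": 4.19,
}
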
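"""Tumor-level tandem-duplication and chromothripsis scores.

The TDP score summarizes abundance, chromosomal dispersion and total size
of tandem duplications (amplified 1 kb - 2 Mb segments); the chromothripsis
state score sums, over chromosomes, the squared count of (2,1,2)
copy-number triples — interspersed single-copy losses on a disomic
background.
"""

import pandas as pd

import cnsig

build = cnsig.load_genome_build("toy")

# two tandem duplications on chr1 (1 Mb and 1.5 Mb at copy number 3)
td_profile = cnsig.CNProfile(
    "td_tumor",
    pd.DataFrame(
        {"chromosome": ["chr1"] * 5 + ["chr2"],
         "start": [1, 2_000_001, 3_000_001, 10_000_001, 11_500_001, 1],
         "end": [2_000_000, 3_000_000, 10_000_000, 11_500_000, 30_000_000,
                 20_000_000],
         "cn": [2, 3, 2, 3, 2, 2]}
    ),
)
res = cnsig.tdp_score(td_profile, build)
print(f"TDs: {res.td_total}, total size {res.total_size_mb:.1f} Mb")
print(f"observed per chromosome: {res.td_obs}")
print(f"expected per chromosome: { {c: round(e, 2) for c, e in res.td_exp.items()} }")
print(f"TDP score: {res.score:.4f}")

# oscillating chromosome: cn 2,1,2,1,2 -> two overlapping (2,1,2) triples
osc_profile = cnsig.CNProfile(
    "ct_tumor",
    pd.DataFrame(
        {"chromosome": ["chr1"] * 5,
         "start": [1 + 100_000 * i for i in range(5)],
         "end": [100_000 * (i + 1) for i in range(5)],
         "cn": [2, 1, 2, 1, 2]}
    ),
)
print(f"\nchromothripsis state score: {cnsig.chromothripsis_score(osc_profile):.0f}")
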
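"""Tally a segmented copy-number profile into the fixed 80-component catalog.

Builds a tiny two-chromosome profile by hand, computes the 8 feature
distributions and prints the nonzero catalog entries. Each count says how
many observations of a feature fell into that component bin — e.g. CN[2]
counts diploid segments, BP10MB[1] counts 10 Mb windows with one breakpoint.
"""

import pandas as pd

import cnsig

build = cnsig.load_genome_build("toy")

segments = pd.DataFrame(
    {
        "sample": ["demo"] * 4,
        "chromosome": ["chr1", "chr1", "chr1", "chr2"],
        "start": [1, 10_000_001, 20_000_001, 1],
        "end": [10_000_000, 20_000_000, 30_000_000, 20_000_000],
        "segVal": [2, 3, 2, 2],
    }
)
(profile,) = cnsig.read_segments(segments)

obs = cnsig.compute_features(profile, build)
for name in ("BP10MB", "BPArm", "CN", "CNCP", "OsCN", "NC50", "BoChr"):
    print(f"{name:>6}: {obs[name]}")

catalog = cnsig.tally_cn_catalog([profile], build)
row = catalog.loc["demo"]
print(f"\ncatalog: {catalog.shape[1]} components, {int(row.sum())} observations")
print("nonzero components:")
print(row[row > 0].to_string())
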
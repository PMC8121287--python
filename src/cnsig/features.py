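"""Genome-wide distributions of the 8 copy-number features.

For one normalized profile the features are:

- ``BP10MB`` breakpoint count per 10 Mb window (windows tiled from base 1
  on each chromosome present in the profile, last partial window included;
  a junction sits at the end coordinate of its left segment)
- ``BPArm``  breakpoint count per chromosome arm, two observations (p then
  q) for every chromosome of the build
- ``CN``     absolute copy number, one observation per segment
- ``CNCP``   absolute copy-number change across each junction
- ``OsCN``   lengths of oscillating copy-number segment chains
- ``SS``     log10 segment size in bp
- ``NC50``   minimal number of chromosomes carrying >= 50% of altered
  segments (single observation)
- ``BoChr``  chromosome index (1..22, X = 23) of each altered segment

"Altered" means cn differs from the diploid baseline (default 2);
chrX is treated autosome-like with the same baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBuild
from .profiles import CNProfile

__all__ = [
    "FeatureObservations",
    "compute_features",
    "oscillation_chains",
    "nc50",
    "bochr",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("BP10MB", "BPArm", "CN", "CNCP", "OsCN", "SS", "NC50", "BoChr")

WINDOW_BP = 10_000_000


@dataclass
class FeatureObservations:
    """Observation lists for the 8 features of one sample."""

    sample: str
    observations: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            self.observations.setdefault(name, [])
        extra = set(self.observations) - set(FEATURE_NAMES)
        if extra:
            raise ValueError(f"unknown feature(s) {sorted(extra)}")

    def __getitem__(self, feature: str) -> list[float]:
        return self.observations[feature]


def _junctions(profile: CNProfile):
    """Yield (chromosome, position of left segment end, |delta cn|) per junction."""
    for chrom, sub in profile.by_chromosome():
        ends = sub["end"].to_numpy()
        cns = sub["cn"].to_numpy()
        for i in range(len(sub) - 1):
            yield chrom, int(ends[i]), abs(int(cns[i + 1]) - int(cns[i]))


def oscillation_chains(profile: CNProfile) -> list[int]:
    """Lengths of oscillating copy-number chains (OsCN).

    Per chromosome with >= 3 segments, walk segments i = 3..n keeping a
    counter that increments while cn_i == cn_{i-2} and cn_i != cn_{i-1}.
    When the condition fails and a chain was open, its length is emitted
    and the counter reset; at the chromosome end the counter is emitted
    unconditionally (so a chromosome where the condition never held
    contributes a single 0). Chromosomes with < 3 segments emit nothing.
    """
    chains: list[int] = []
    for chrom, sub in profile.by_chromosome():
        cn = sub["cn"].to_numpy()
        if len(cn) < 3:
            continue
        count = 0
        for i in range(2, len(cn)):
            if cn[i] == cn[i - 2] and cn[i] != cn[i - 1]:
                count += 1
            elif count > 0:
                chains.append(count)
                count = 0
        chains.append(count)
    return chains


def nc50(profile: CNProfile, baseline: int = 2) -> int:
    """Minimal number of chromosomes jointly holding >= half the altered segments."""
    counts = (
        profile.segments[profile.segments["cn"] != baseline]
        .groupby("chromosome")
        .size()
        .sort_values(ascending=False)
        .to_numpy()
    )
    total = counts.sum()
    if total == 0:
        return 0
    cum = np.cumsum(counts)
    return int(np.searchsorted(cum, total / 2) + 1)


def bochr(profile: CNProfile, build: GenomeBuild, baseline: int = 2) -> list[int]:
    """Chromosome index (1..23) of every altered segment."""
    altered = profile.segments[profile.segments["cn"] != baseline]
    return [build.chrom_index(c) for c in altered["chromosome"]]


def compute_features(
    profile: CNProfile, build: GenomeBuild, baseline: int = 2
) -> FeatureObservations:
    """Compute all 8 feature observation lists for one normalized profile."""
    profile.validate(build)
    obs = FeatureObservations(sample=profile.sample)

    junctions = list(_junctions(profile))

    # BP10MB: per-window junction counts over chromosomes present in the profile
    for chrom in profile.chromosomes():
        n_windows = -(-build.lengths[chrom] // WINDOW_BP)  # ceil
        counts = np.zeros(n_windows, dtype=int)
        for jc, pos, _ in junctions:
            if jc == chrom:
                counts[(pos - 1) // WINDOW_BP] += 1
        obs["BP10MB"].extend(counts.tolist())

    # BPArm: p then q counts for every chromosome of the build
    for chrom in build.chromosomes:
        (p_lo, p_hi), _ = build.arms(chrom)
        p_count = sum(1 for jc, pos, _ in junctions if jc == chrom and pos <= p_hi)
        q_count = sum(1 for jc, pos, _ in junctions if jc == chrom and pos > p_hi)
        obs["BPArm"].extend([p_count, q_count])

    seg = profile.segments
    obs["CN"].extend(int(c) for c in seg["cn"])
    obs["CNCP"].extend(delta for _, _, delta in junctions)
    obs["SS"].extend(np.log10(seg["end"] - seg["start"] + 1).tolist())
    obs["OsCN"].extend(oscillation_chains(profile))
    obs["NC50"].append(nc50(profile, baseline))
    obs["BoChr"].extend(bochr(profile, build, baseline))
    return obs


def features_long_table(all_obs) -> "pd.DataFrame":
    """Long-format (sample, feature, value) table across samples."""
    import pandas as pd

    rows = [
        (o.sample, feature, value)
        for o in all_obs
        for feature in FEATURE_NAMES
        for value in o[feature]
    ]
    return pd.DataFrame(rows, columns=["sample", "feature", "value"])
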
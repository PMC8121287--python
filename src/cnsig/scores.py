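"""Per-tumor summary scores for two structural phenotypes.

Tandem-duplication phenotype (TDP): a TD is an amplified segment
(cn above the diploid baseline) of 1 kb - 2 Mb. With TD_total the number
of TDs, TD_obs/TD_exp the observed/expected TDs per chromosome (expected
apportioned by chromosome length share of the tallied genome) and L the
total TD size in Mb,

    TDP = TD_total / (sum_chr |TD_obs - TD_exp| + 1) * L

so the score grows with TD abundance and total size and shrinks when TDs
concentrate on few chromosomes.

Chromothripsis state score: sum over chromosomes of the squared count of
consecutive segment triples with copy numbers exactly (2, 1, 2) —
interspersed one-copy losses on a disomic background, the oscillating
pattern characteristic of a shattered-and-rejoined chromosome. Overlapping
triples each count. This is a simplified state estimate, not a structural-
variant-based chromothripsis caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GenomeBuild
from .profiles import CNProfile

__all__ = ["TDPResult", "tdp_score", "chromothripsis_score", "score_table"]


@dataclass
class TDPResult:
    td_total: int
    td_obs: dict[str, int]
    td_exp: dict[str, float]
    total_size_mb: float
    score: float


def tdp_score(
    profile: CNProfile,
    build: GenomeBuild,
    min_size: int = 1_000,
    max_size: int = 2_000_000,
    baseline: int = 2,
) -> TDPResult:
    """Tandem-duplication phenotype score of one normalized profile."""
    seg = profile.segments
    sizes = seg["end"] - seg["start"] + 1
    is_td = (seg["cn"] > baseline) & (sizes >= min_size) & (sizes <= max_size)
    tds = seg[is_td]

    td_total = int(is_td.sum())
    obs = {c: 0 for c in build.chromosomes}
    for chrom, n in tds.groupby("chromosome").size().items():
        obs[chrom] = int(n)
    genome_len = build.total_length
    exp = {c: td_total * build.lengths[c] / genome_len for c in build.chromosomes}
    total_size_mb = float((tds["end"] - tds["start"] + 1).sum() / 1e6)

    if td_total == 0:
        score = 0.0
    else:
        dispersion = sum(abs(obs[c] - exp[c]) for c in build.chromosomes)
        score = td_total / (dispersion + 1.0) * total_size_mb
    return TDPResult(
        td_total=td_total,
        td_obs=obs,
        td_exp=exp,
        total_size_mb=total_size_mb,
        score=score,
    )


def chromothripsis_score(profile: CNProfile) -> float:
    """Sum over chromosomes of squared (2,1,2)-triple counts."""
    score = 0.0
    for _, sub in profile.by_chromosome():
        cn = sub["cn"].to_numpy()
        n_osc = sum(
            1
            for i in range(len(cn) - 2)
            if cn[i] == 2 and cn[i + 1] == 1 and cn[i + 2] == 2
        )
        score += n_osc**2
    return score


def score_table(profiles, build: GenomeBuild, **tdp_kwargs) -> pd.DataFrame:
    """Per-sample score table (sample, td_total, L_mb, tdp_score, chromothripsis_score)."""
    rows = []
    for prof in profiles:
        td = tdp_score(prof, build, **tdp_kwargs)
        rows.append(
            {
                "sample": prof.sample,
                "td_total": td.td_total,
                "L_mb": td.total_size_mb,
                "tdp_score": td.score,
                "chromothripsis_score": chromothripsis_score(prof),
            }
        )
    return pd.DataFrame(rows).set_index("sample")
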
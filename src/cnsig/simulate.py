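"""Synthetic cohort generator with planted copy-number processes.

Each sample starts as a diploid genome and accumulates events from five
planted processes mirroring recognised copy-number etiologies:

- ``FOCAL_AMP``      short (10-100 kb) focal amplifications to very high
  copy number (>= 9)
- ``TANDEM_DUP``     medium (100 kb - 2 Mb) single-copy-gain segments
  spread uniformly over the genome
- ``WGD``            whole-genome duplication: baseline ploidy shifts from
  2 to 4 (Bernoulli in the process weight; a baseline shift, not inserted
  events)
- ``CHROMOTHRIPSIS`` one chromosome region rewritten into an oscillating
  chain of 20-60 segments alternating copy numbers 2 and 1
- ``QUIET``          contributes nothing

Per-sample process weights are Dirichlet-distributed; insertion counts are
Poisson with mean weight x rate. Event placement is uniform over the
tallied genome with rejection of overlaps. Default rates give median
per-sample segment counts in the 50-200 range typical of exome-derived
profiles. Fixed seed implies byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild, load_genome_build
from .profiles import CNProfile, normalize_profile
from .tally import ComponentScheme, default_scheme, tally_cn_catalog

__all__ = ["PROCESS_NAMES", "SimConfig", "SimTruth", "simulate_profile", "simulate_cohort"]

PROCESS_NAMES = ("FOCAL_AMP", "TANDEM_DUP", "WGD", "CHROMOTHRIPSIS", "QUIET")

_MAX_PLACEMENT_TRIES = 30


@dataclass
class SimConfig:
    """Cohort-level simulation settings.

    rates are expected event counts at process weight 1 (pure process);
    a sample's actual count is Poisson(weight x rate). ``dirichlet``
    is the concentration of the per-sample process-weight prior.
    """

    genome: GenomeBuild = field(default_factory=lambda: load_genome_build("hg38"))
    n_samples: int = 200
    dirichlet: tuple[float, ...] = (1.0,) * 5
    focal_amp_rate: float = 120.0
    tandem_dup_rate: float = 120.0
    chromothripsis_rate: float = 5.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.dirichlet) != len(PROCESS_NAMES):
            raise ValueError(f"dirichlet needs {len(PROCESS_NAMES)} concentrations")
        for r in (self.focal_amp_rate, self.tandem_dup_rate, self.chromothripsis_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class SimTruth:
    """Planted ground truth of one simulated cohort."""

    weights: pd.DataFrame  # samples x processes, rows sum to 1
    process_profiles: pd.DataFrame  # processes x 80 components (mean pure catalogs)


def _place_interval(
    rng: np.random.Generator,
    build: GenomeBuild,
    size: int,
    used: dict[str, list[tuple[int, int]]],
    chrom: str | None = None,
) -> tuple[str, int, int] | None:
    """Uniformly place a non-overlapping interval; None when space runs out."""
    chroms = list(build.chromosomes)
    lengths = np.array([build.lengths[c] for c in chroms], dtype=float)
    for _ in range(_MAX_PLACEMENT_TRIES):
        c = chrom or rng.choice(chroms, p=lengths / lengths.sum())
        if build.lengths[c] < size + 2:
            continue
        start = int(rng.integers(2, build.lengths[c] - size))
        end = start + size - 1
        if all(end < s or start > e for s, e in used[c]):
            used[c].append((start, end))
            return c, start, end
    return None


def simulate_profile(
    mix, config: SimConfig, rng: np.random.Generator, sample: str = "S"
) -> CNProfile:
    """Generate one profile from a process-weight vector."""
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (len(PROCESS_NAMES),) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
        raise ValueError("mix must be a nonnegative weight vector over the 5 processes summing to 1")
    w = dict(zip(PROCESS_NAMES, mix))
    build = config.genome

    baseline = 4 if rng.random() < w["WGD"] else 2
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in build.chromosomes}
    events: list[tuple[str, int, int, int]] = []

    n_focal = rng.poisson(w["FOCAL_AMP"] * config.focal_amp_rate)
    for _ in range(n_focal):
        size = int(rng.integers(10_000, 100_001))
        spot = _place_interval(rng, build, size, used)
        if spot is None:
            continue
        c, s, e = spot
        events.append((c, s, e, 9 + int(rng.poisson(2.0))))

    n_td = rng.poisson(w["TANDEM_DUP"] * config.tandem_dup_rate)
    for _ in range(n_td):
        size = int(rng.integers(100_000, 2_000_001))
        spot = _place_interval(rng, build, size, used)
        if spot is None:
            continue
        c, s, e = spot
        events.append((c, s, e, 3))

    n_ct = rng.poisson(w["CHROMOTHRIPSIS"] * config.chromothripsis_rate)
    for _ in range(n_ct):
        n_seg = int(rng.integers(20, 61))
        seg_sizes = rng.integers(50_000, 500_001, size=n_seg)
        region = int(seg_sizes.sum())
        spot = _place_interval(rng, build, region, used)
        if spot is None:
            continue
        c, s, _ = spot
        pos = s
        for j, sz in enumerate(seg_sizes):
            events.append((c, pos, pos + int(sz) - 1, 2 if j % 2 == 0 else 1))
            pos += int(sz)

    rows = []
    for chrom in build.chromosomes:
        chrom_events = sorted([e for e in events if e[0] == chrom], key=lambda e: e[1])
        cursor = 1
        for _, s, e, cn in chrom_events:
            if s > cursor:
                rows.append({"chromosome": chrom, "start": cursor, "end": s - 1, "cn": baseline})
            rows.append({"chromosome": chrom, "start": s, "end": e, "cn": cn})
            cursor = e + 1
        if cursor <= build.lengths[chrom]:
            rows.append(
                {"chromosome": chrom, "start": cursor, "end": build.lengths[chrom], "cn": baseline}
            )
    return normalize_profile(CNProfile(sample=sample, segments=pd.DataFrame(rows)))


def _pure_process_profiles(
    config: SimConfig,
    scheme: ComponentScheme,
    rng: np.random.Generator,
    n_per_process: int = 20,
) -> pd.DataFrame:
    """Expected catalog per process: mean tally of pure-process samples."""
    rows = {}
    for p, name in enumerate(PROCESS_NAMES):
        mix = np.zeros(len(PROCESS_NAMES))
        mix[p] = 1.0
        profiles = [
            simulate_profile(mix, config, rng, sample=f"{name}_{i}")
            for i in range(n_per_process)
        ]
        catalog = tally_cn_catalog(profiles, config.genome, scheme)
        rows[name] = catalog.mean(axis=0)
    return pd.DataFrame(rows).T


def simulate_cohort(
    config: SimConfig | None = None, scheme: ComponentScheme | None = None
) -> tuple[list[CNProfile], SimTruth]:
    """Generate a cohort of profiles plus its planted ground truth."""
    if config is None:
        config = SimConfig()
    if scheme is None:
        scheme = default_scheme()
    rng = np.random.default_rng(config.seed)

    weights = rng.dirichlet(config.dirichlet, size=config.n_samples)
    width = len(str(config.n_samples))
    profiles = [
        simulate_profile(weights[i], config, rng, sample=f"SIM{i + 1:0{width}d}")
        for i in range(config.n_samples)
    ]
    truth = SimTruth(
        weights=pd.DataFrame(
            weights,
            index=[p.sample for p in profiles],
            columns=list(PROCESS_NAMES),
        ),
        process_profiles=_pure_process_profiles(config, scheme, rng),
    )
    return profiles, truth
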
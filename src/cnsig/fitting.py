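"""Single-sample exposure fitting against fixed signatures.

Exposures are fit per sample by nonnegative least squares (the quadratic
program min ||W x - v||^2, x >= 0). Stability is assessed by refitting
bootstrap catalogs: multinomial redraws of the sample's events at its
observed component probabilities. The per-signature instability is the
RMSE between bootstrap and original relative exposures; the presence
p-value is the fraction of bootstrap fits in which a signature's relative
exposure stays at or below a small cutoff. Cohort-level detection and
sampling-fraction detection-probability curves build on these per-tumor
calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .signatures import SignatureSet

__all__ = [
    "fit_exposures_qp",
    "BootstrapResult",
    "bootstrap_stability",
    "detect_signatures",
    "detection_probability_curve",
]


def _signature_array(sigs: SignatureSet, labels) -> np.ndarray:
    if list(labels) != list(sigs.components):
        raise ValueError("component labels of catalog and signatures differ")
    W = sigs.matrix.to_numpy(dtype=float)
    if (W.sum(axis=0) == 0).any():
        bad = [n for n, s in zip(sigs.names, W.sum(axis=0)) if s == 0]
        raise ValueError(f"all-zero signature column(s): {bad}")
    return W


def fit_exposures_qp(
    catalog_row: pd.Series, sigs: SignatureSet
) -> tuple[pd.Series, pd.Series]:
    """Fit one sample's exposures by NNLS.

    Returns (absolute, relative) exposures; relative is the absolute
    vector scaled to unit sum (all zeros when the fit is zero).
    """
    W = _signature_array(sigs, catalog_row.index)
    v = catalog_row.to_numpy(dtype=float)
    x, _ = nnls(W, v)
    absolute = pd.Series(x, index=sigs.names)
    total = absolute.sum()
    relative = absolute / total if total > 0 else absolute * 0.0
    return absolute, relative


@dataclass
class BootstrapResult:
    """Original + bootstrap exposures and per-signature stability measures."""

    original_absolute: pd.Series
    original_relative: pd.Series
    draws_relative: pd.DataFrame  # n_boot x k
    rmse: pd.Series
    p_value: pd.Series
    n_boot: int
    seed: int


def bootstrap_stability(
    catalog_row: pd.Series,
    sigs: SignatureSet,
    n_boot: int = 1000,
    exposure_cutoff: float = 0.01,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap a sample's catalog and refit to measure exposure stability.

    Each bootstrap catalog is a multinomial redraw of the sample's n events
    at the observed component probabilities v/n, refit by NNLS.
    RMSE_s = sqrt(mean_b (rel_b,s - rel_orig,s)^2); the presence p-value of
    signature s is the fraction of draws with relative exposure <=
    ``exposure_cutoff``.
    """
    v = catalog_row.to_numpy(dtype=float)
    n = v.sum()
    if n <= 0:
        raise ValueError("catalog row has zero total count")
    W = _signature_array(sigs, catalog_row.index)
    orig_abs, orig_rel = fit_exposures_qp(catalog_row, sigs)

    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(round(n)), v / n, size=n_boot).astype(float)
    rel = np.zeros((n_boot, len(sigs.names)))
    for b in range(n_boot):
        x, _ = nnls(W, draws[b])
        total = x.sum()
        rel[b] = x / total if total > 0 else 0.0

    diffs = rel - orig_rel.to_numpy()[None, :]
    rmse = pd.Series(np.sqrt((diffs**2).mean(axis=0)), index=sigs.names)
    p_value = pd.Series((rel <= exposure_cutoff).mean(axis=0), index=sigs.names)
    return BootstrapResult(
        original_absolute=orig_abs,
        original_relative=orig_rel,
        draws_relative=pd.DataFrame(rel, columns=sigs.names),
        rmse=rmse,
        p_value=p_value,
        n_boot=n_boot,
        seed=seed,
    )


def _support_table(
    catalog: pd.DataFrame,
    sigs: SignatureSet,
    n_boot: int,
    exposure_cutoff: float,
    p_cutoff: float,
    seed: int,
) -> pd.DataFrame:
    """Per-tumor boolean support: bootstrap p-value below cutoff."""
    streams = np.random.SeedSequence(seed).spawn(len(catalog))
    rows = {}
    for (sample, row), stream in zip(catalog.iterrows(), streams):
        boot = bootstrap_stability(
            row, sigs, n_boot=n_boot, exposure_cutoff=exposure_cutoff,
            seed=int(stream.generate_state(1)[0] % (2**31)),
        )
        rows[sample] = boot.p_value < p_cutoff
    return pd.DataFrame(rows).T


def detect_signatures(
    catalog: pd.DataFrame,
    sigs: SignatureSet,
    exposure_cutoff: float = 0.01,
    p_cutoff: float = 0.05,
    min_tumors: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Cohort-level signature detection.

    A tumor supports a signature when its bootstrap presence p-value is
    below ``p_cutoff`` (its relative exposure credibly exceeds
    ``exposure_cutoff``); a signature is detected when more than
    ``min_tumors`` tumors support it.

    Returns (detected signature names, per-tumor boolean support table).
    """
    if len(catalog) == 0:
        raise ValueError("empty cohort")
    support = _support_table(catalog, sigs, n_boot, exposure_cutoff, p_cutoff, seed)
    counts = support.sum(axis=0)
    detected = [name for name in sigs.names if counts[name] > min_tumors]
    return detected, support


def detection_probability_curve(
    catalog: pd.DataFrame,
    sigs: SignatureSet,
    fractions,
    reps: int = 1000,
    min_tumors: int = 10,
    exposure_cutoff: float = 0.01,
    p_cutoff: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Probability of detecting all signatures vs cohort sampling fraction.

    Per-tumor bootstrap support is computed once for the full cohort; each
    repetition then subsamples tumors without replacement and applies the
    cohort detection rule, so the curve isolates the effect of cohort size.
    """
    fractions = list(fractions)
    n = len(catalog)
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"sampling fraction {f} outside (0, 1]")
        if int(np.floor(f * n)) < 1:
            raise ValueError(f"fraction {f} selects no tumors from cohort of {n}")
    support = _support_table(catalog, sigs, n_boot, exposure_cutoff, p_cutoff, seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    probs = {}
    support_arr = support.to_numpy()
    k = len(sigs.names)
    for f in fractions:
        size = int(np.floor(f * n))
        hits = 0
        for _ in range(reps):
            idx = rng.choice(n, size=size, replace=False)
            counts = support_arr[idx].sum(axis=0)
            if (counts > min_tumors).sum() == k:
                hits += 1
        probs[f] = hits / reps
    return pd.Series(probs, name="detection_probability")
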
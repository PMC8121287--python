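"""De novo signature discovery by non-negative matrix factorization.

The catalog (samples x components) is factorized as V ~ W H with V the
transposed catalog (components x samples), W >= 0 the signature profiles
(components x k) and H >= 0 the exposures (k x samples). The solver is the
classic multiplicative-update scheme under generalized Kullback-Leibler
divergence with random uniform restarts; the factorization rank k is
surveyed via the cophenetic correlation coefficient of the run-averaged
consensus matrix. Absolute exposures follow from scaling each signature
column to unit sum and pushing the scale into the exposure rows, so a
sample's absolute exposures sum to its (reconstructed) total event count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from .tally import ComponentScheme

__all__ = [
    "SignatureSet",
    "NMFRun",
    "RankSurveyResult",
    "kl_nmf",
    "run_nmf",
    "survey_ranks",
    "extract_signatures",
    "normalize_profile_matrix",
    "cosine_similarity_matrix",
    "consensus_cluster_samples",
]

_EPS = 1e-9


@dataclass
class SignatureSet:
    """Component x signature profile matrix with optional feature annotation."""

    matrix: pd.DataFrame
    features: pd.Series | None = None  # component label -> feature name

    @property
    def components(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass
class NMFRun:
    """Best factorization of one multi-restart NMF call."""

    W: pd.DataFrame
    H: pd.DataFrame
    objectives: list[float]
    consensus: pd.DataFrame
    best_run: int
    history: list[float] = field(default_factory=list)


@dataclass
class RankSurveyResult:
    """Cophenetic / reconstruction-error survey over candidate ranks."""

    table: pd.DataFrame  # columns: rank, cophenetic, reconstruction_error
    consensus: dict[int, pd.DataFrame]
    n_runs: int
    seed: int
    suggested_rank: int


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    div = np.sum(WH) - np.sum(V)
    div += np.sum(V[mask] * np.log(V[mask] / WH[mask]))
    return float(div)


def kl_nmf(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    check_every: int = 10,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One KL multiplicative-update run from a random uniform start.

    Returns (W, H, objective history). The KL objective is non-increasing
    across updates; iteration stops when its relative change over
    ``check_every`` iterations drops below ``tol``.
    """
    m, n = V.shape
    W = rng.uniform(_EPS, 1.0, size=(m, k))
    H = rng.uniform(_EPS, 1.0, size=(k, n))
    history = [_kl_divergence(V, W @ H)]
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if it % check_every == 0 or it == max_iter:
            obj = _kl_divergence(V, W @ H)
            history.append(obj)
            prev = history[-2]
            if abs(prev - obj) <= tol * max(abs(prev), _EPS):
                break
    return W, H, history


def _check_catalog(catalog: pd.DataFrame, k: int) -> np.ndarray:
    V = catalog.to_numpy(dtype=float).T  # components x samples
    if (V < 0).any():
        raise ValueError("catalog contains negative counts")
    zero_rows = catalog.index[catalog.sum(axis=1) == 0].tolist()
    if zero_rows:
        raise ValueError(f"catalog has all-zero sample row(s): {zero_rows}")
    if not 2 <= k < min(catalog.shape):
        raise ValueError(
            f"rank {k} out of range [2, {min(catalog.shape) - 1}] "
            f"for catalog of shape {catalog.shape}"
        )
    return V


def run_nmf(
    catalog: pd.DataFrame,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> NMFRun:
    """Multi-restart KL-NMF; returns the best run plus the consensus matrix.

    The consensus matrix averages, over restarts, the sample connectivity
    matrix (1 when two samples load most on the same signature).
    """
    V = _check_catalog(catalog, k)
    n = V.shape[1]
    streams = np.random.SeedSequence(seed).spawn(n_runs)

    best = None
    objectives: list[float] = []
    consensus = np.zeros((n, n))
    for run, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        W, H, history = kl_nmf(V, k, rng, max_iter=max_iter, tol=tol)
        objectives.append(history[-1])
        membership = H.argmax(axis=0)
        consensus += membership[:, None] == membership[None, :]
        if best is None or history[-1] < best[2][-1]:
            best = (W, H, history, run)
    consensus /= n_runs

    W, H, history, best_run = best
    samples = catalog.index
    sig_names = [f"Sig{i + 1}" for i in range(k)]
    return NMFRun(
        W=pd.DataFrame(W, index=catalog.columns, columns=sig_names),
        H=pd.DataFrame(H, index=sig_names, columns=samples),
        objectives=objectives,
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        best_run=best_run,
        history=history,
    )


def cophenetic_coefficient(consensus: pd.DataFrame) -> float:
    """Correlation between consensus dissimilarity and its average-linkage
    cophenetic distances; 1.0 for a degenerate (perfectly stable) consensus."""
    D = 1.0 - consensus.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    Z = average(d)
    coph = cophenet(Z)
    if np.std(d) == 0 or np.std(coph) == 0:
        return 1.0
    return float(np.corrcoef(d, coph)[0, 1])


def survey_ranks(
    catalog: pd.DataFrame,
    ranks,
    n_runs: int = 50,
    seed: int = 0,
    stability_margin: float = 0.01,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> RankSurveyResult:
    """Survey candidate factorization ranks.

    For each rank the cophenetic correlation coefficient of the consensus
    matrix and the best-run reconstruction error (KL) are reported. The
    suggested rank is the largest rank whose cophenetic coefficient exceeds
    the next surveyed rank's by ``stability_margin`` — advisory only; rank
    choice ultimately rests on stability and interpretability together.
    """
    ranks = sorted(set(int(r) for r in ranks))
    rows = []
    consensus = {}
    for k in ranks:
        res = run_nmf(catalog, k, n_runs=n_runs, seed=seed, max_iter=max_iter, tol=tol)
        rows.append(
            {
                "rank": k,
                "cophenetic": cophenetic_coefficient(res.consensus),
                "reconstruction_error": min(res.objectives),
            }
        )
        consensus[k] = res.consensus
    table = pd.DataFrame(rows)

    suggested = int(table.loc[table["cophenetic"].idxmax(), "rank"])
    for i in range(len(table) - 2, -1, -1):
        if table["cophenetic"].iloc[i] - table["cophenetic"].iloc[i + 1] > stability_margin:
            suggested = int(table["rank"].iloc[i])
            break
    return RankSurveyResult(
        table=table, consensus=consensus, n_runs=n_runs, seed=seed,
        suggested_rank=suggested,
    )


def _ss_order_key(W: pd.DataFrame, features: pd.Series) -> list[int]:
    """Signature order: ascending weighted-median segment-size bin.

    Mirrors ranking signatures by the median length of their copy-number
    segments; ties fall back to the weighted mean bin, then column order.
    """
    ss_rows = features[features == "SS"].index
    keys = []
    for j, name in enumerate(W.columns):
        w = W.loc[ss_rows, name].to_numpy(dtype=float)
        total = w.sum()
        if total <= 0:
            keys.append((np.inf, np.inf, j))
            continue
        p = w / total
        cum = np.cumsum(p)
        median_bin = int(np.searchsorted(cum, 0.5))
        mean_bin = float(np.arange(len(p)) @ p)
        keys.append((median_bin, mean_bin, j))
    return sorted(range(len(keys)), key=lambda j: keys[j])


def extract_signatures(
    catalog: pd.DataFrame,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    scheme: ComponentScheme | None = None,
    prefix: str = "Sig",
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> tuple[SignatureSet, pd.DataFrame, pd.DataFrame, NMFRun]:
    """Extract k signatures and per-sample exposures from a catalog.

    Returns (signatures, relative exposures, absolute exposures, nmf run).
    Signature columns sum to 1; the column scale is folded into the
    exposures, so absolute exposures approximate each sample's event count
    attributable to each signature. Signatures are ordered by ascending
    median segment-size mass when a scheme with an SS feature is given,
    else by descending total exposure.
    """
    res = run_nmf(catalog, k, n_runs=n_runs, seed=seed, max_iter=max_iter, tol=tol)
    W = res.W.to_numpy()
    H = res.H.to_numpy()

    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]  # W@H unchanged

    features = scheme.feature_of() if scheme is not None else None
    W_df = pd.DataFrame(W, index=res.W.index, columns=res.W.columns)
    if features is not None and (features == "SS").any():
        order = _ss_order_key(W_df, features)
    else:
        order = list(np.argsort(-H.sum(axis=1), kind="stable"))
    W = W[:, order]
    H = H[order, :]

    names = [f"{prefix}{i + 1}" for i in range(k)]
    sigs = SignatureSet(
        matrix=pd.DataFrame(W, index=catalog.columns, columns=names),
        features=features,
    )
    absolute = pd.DataFrame(H.T, index=catalog.index, columns=names)
    totals = absolute.sum(axis=1)
    relative = absolute.div(totals.where(totals > 0, 1.0), axis=0)
    return sigs, relative, absolute, res


def normalize_profile_matrix(sigs: SignatureSet, mode: str) -> SignatureSet:
    """Normalize signature profiles for display/comparison.

    ``within-feature-row``: each feature block of each signature is scaled
    to unit sum (all-zero blocks stay zero). ``whole-signature``: each
    signature column is scaled to unit sum.
    """
    W = sigs.matrix.copy().astype(float)
    if mode == "whole-signature":
        sums = W.sum(axis=0)
        W = W.div(sums.where(sums > 0, 1.0), axis=1)
    elif mode == "within-feature-row":
        if sigs.features is None:
            raise ValueError("within-feature normalization needs feature annotation")
        for feature in sigs.features.unique():
            rows = sigs.features[sigs.features == feature].index
            block = W.loc[rows]
            sums = block.sum(axis=0)
            W.loc[rows] = block.div(sums.where(sums > 0, 1.0), axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SignatureSet(matrix=W, features=sigs.features)


def cosine_similarity_matrix(A, B) -> pd.DataFrame:
    """Pairwise cosine similarity between two signature sets.

    Requires identical component labels in identical order — comparing
    catalogs with different component definitions is exactly the failure
    mode fixed components exist to prevent. Zero vectors get similarity 0.
    """
    Am = A.matrix if isinstance(A, SignatureSet) else pd.DataFrame(A)
    Bm = B.matrix if isinstance(B, SignatureSet) else pd.DataFrame(B)
    if list(Am.index) != list(Bm.index):
        raise ValueError("component labels differ; signature sets are not comparable")
    a = Am.to_numpy(dtype=float)
    b = Bm.to_numpy(dtype=float)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    sim = a.T @ b
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, sim / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame(sim, index=Am.columns, columns=Bm.columns)


def consensus_cluster_samples(
    consensus: pd.DataFrame, k: int, relative_exposures: pd.DataFrame
) -> tuple[pd.Series, dict[int, str]]:
    """Cluster samples on the consensus matrix and annotate groups.

    Average-linkage hierarchical clustering of 1 - consensus cut at k
    groups; each group is labelled with the signature of highest mean
    relative exposure among its members (ties -> lower signature index).
    """
    n = len(consensus)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    D = 1.0 - consensus.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    labels = fcluster(Z, t=k, criterion="maxclust")
    groups = pd.Series(labels, index=consensus.index, name="group")

    enriched = {}
    rel = relative_exposures.loc[consensus.index]
    for g in sorted(set(labels)):
        means = rel[groups == g].mean(axis=0)
        enriched[int(g)] = means.index[int(np.argmax(means.to_numpy()))]
    return groups, enriched
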
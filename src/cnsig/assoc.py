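"""Association testing between signature exposures and sample covariates.

Continuous (and ordinal) covariates are tested by Pearson correlation;
binary covariates split samples into two groups compared by a two-sided
Mann-Whitney U test, with the difference of group means reported as the
effect. All p-values from one call are adjusted together by
Benjamini-Hochberg false discovery rate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["associate_exposures"]

# exact U distribution is feasible and preferable at small combined n without ties
_EXACT_N_MAX = 20


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _mannwhitney(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    n = len(x0) + len(x1)
    has_ties = len(np.unique(np.concatenate([x0, x1]))) < n
    method = "exact" if (n <= _EXACT_N_MAX and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x1, x0, alternative="two-sided", method=method)
    effect = float(np.mean(x1) - np.mean(x0))
    return effect, float(res.pvalue)


def associate_exposures(
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    kinds: dict[str, str],
) -> pd.DataFrame:
    """Test every signature against every covariate.

    Parameters
    ----------
    exposures
        Samples x signatures exposure matrix (relative or absolute).
    covariates
        Samples x covariates table; missing values dropped pairwise.
    kinds
        covariate name -> ``continuous`` or ``binary``. Binary covariates
        must take exactly two non-missing values; the effect reported is
        mean(group 1) - mean(group 0) with groups in sorted value order.

    Returns
    -------
    DataFrame with columns signature, covariate, kind, effect, p_value,
    fdr, n_used. Rows with too few observations (or an empty group) carry
    NA effect/p and are excluded from the FDR adjustment.
    """
    shared = exposures.index.intersection(covariates.index)
    if len(shared) == 0:
        raise ValueError("no shared sample identifiers")
    unknown = set(kinds.values()) - {"continuous", "binary"}
    if unknown:
        raise ValueError(f"unknown covariate kind(s): {sorted(unknown)}")

    rows = []
    for cov, kind in kinds.items():
        if cov not in covariates.columns:
            raise ValueError(f"covariate {cov!r} not in table")
        cvals = covariates.loc[shared, cov]
        for sig in exposures.columns:
            evals = exposures.loc[shared, sig]
            mask = cvals.notna() & evals.notna()
            x = evals[mask].to_numpy(dtype=float)
            c = cvals[mask]
            n_used = int(mask.sum())
            effect = p = np.nan
            if kind == "continuous":
                if n_used >= 3 and np.std(x) > 0 and np.std(c.to_numpy(float)) > 0:
                    effect, p = _pearson(x, c.to_numpy(dtype=float))
                else:
                    warnings.warn(f"{sig} vs {cov}: too few usable pairs, emitting NA")
            else:
                levels = sorted(pd.unique(c))
                if len(levels) != 2:
                    warnings.warn(f"{sig} vs {cov}: not exactly two groups, emitting NA")
                else:
                    x0 = x[(c == levels[0]).to_numpy()]
                    x1 = x[(c == levels[1]).to_numpy()]
                    if len(x0) == 0 or len(x1) == 0 or n_used < 3:
                        warnings.warn(f"{sig} vs {cov}: empty group, emitting NA")
                    else:
                        effect, p = _mannwhitney(x0, x1)
            rows.append(
                {
                    "signature": sig,
                    "covariate": cov,
                    "kind": kind,
                    "effect": effect,
                    "p_value": p,
                    "n_used": n_used,
                }
            )
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    ok = table["p_value"].notna()
    if ok.any():
        table.loc[ok, "fdr"] = multipletests(table.loc[ok, "p_value"], method="fdr_bh")[1]
    return table
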
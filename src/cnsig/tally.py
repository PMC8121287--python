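"""Fixed component classification and catalog-matrix construction.

The copy-number catalog uses a fixed, ordered 80-component scheme over the
8 features (BP10MB:7, BPArm:11, CN:10, CNCP:7, OsCN:5, SS:13, NC50:4,
BoChr:23). Because the components are fixed, catalogs and signatures from
different cohorts share a coordinate system and can be compared by cosine
similarity — the key practical advantage over mixture-model components
whose meaning changes with the dataset.

Substitution catalogs use the standard 96 trinucleotide-context classes
(6 pyrimidine-referenced substitution types x 16 flanking-base contexts)
in COSMIC lexicographic order.

Catalogs are plain DataFrames: rows = samples, columns = component labels
in scheme order, values = nonnegative integer counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, compute_features
from .genome import GenomeBuild
from .profiles import CNProfile

__all__ = [
    "ComponentScheme",
    "default_scheme",
    "classify_observation",
    "tally_cn_catalog",
    "tally_sbs_catalog",
    "sbs96_labels",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentScheme:
    """Ordered component bins: (feature, label, lower, upper, kind).

    ``kind`` is ``discrete`` (value == lower == upper) or ``range``
    (lower < value <= upper, with +/-inf allowed). Within each feature the
    bins are mutually exclusive and jointly exhaustive over feasible values.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"feature", "label", "lower", "upper", "kind"}
        if not required <= set(self.table.columns):
            raise ValueError(f"scheme table needs columns {sorted(required)}")
        if self.table["label"].duplicated().any():
            raise ValueError("duplicate component labels in scheme")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    @property
    def features(self) -> list[str]:
        return list(dict.fromkeys(self.table["feature"]))

    def feature_of(self) -> pd.Series:
        """component label -> feature name."""
        return self.table.set_index("label")["feature"]

    def components_for(self, feature: str) -> pd.DataFrame:
        return self.table[self.table["feature"] == feature]


def default_scheme() -> ComponentScheme:
    """The packaged default 80-component copy-number scheme."""
    ref = resources.files("cnsig.data").joinpath("cn_components_80.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    table["lower"] = table["lower"].astype(float)
    table["upper"] = table["upper"].astype(float)
    return ComponentScheme(table=table)


def classify_observation(feature: str, value: float, scheme: ComponentScheme) -> str:
    """Label of the unique component of ``feature`` containing ``value``."""
    sub = scheme.components_for(feature)
    if sub.empty:
        raise ValueError(f"feature {feature!r} not in scheme")
    for row in sub.itertuples(index=False):
        if row.kind == "discrete":
            if value == row.lower:
                return row.label
        elif row.lower < value <= row.upper:
            return row.label
    raise ValueError(f"value {value} of feature {feature} matches no component")


def _feature_bin_indices(
    sub: pd.DataFrame, values: np.ndarray
) -> np.ndarray:
    """Vectorized component index (within feature block) per observation."""
    idx = np.full(len(values), -1, dtype=int)
    for j, row in enumerate(sub.itertuples(index=False)):
        if row.kind == "discrete":
            mask = values == row.lower
        else:
            mask = (values > row.lower) & (values <= row.upper)
        conflict = mask & (idx >= 0)
        if conflict.any():
            raise ValueError(f"overlapping components for feature {row.feature}")
        idx[mask] = j
    if (idx < 0).any():
        bad = values[idx < 0][0]
        feature = sub["feature"].iloc[0]
        raise ValueError(f"value {bad} of feature {feature} matches no component")
    return idx


def tally_cn_catalog(
    profiles,
    build: GenomeBuild,
    scheme: ComponentScheme | None = None,
    baseline: int = 2,
) -> pd.DataFrame:
    """Tally feature observations of each profile into the component catalog.

    Returns a samples x components count DataFrame with columns in scheme
    order. Every observation of every feature contributes +1 to exactly
    one component.
    """
    if scheme is None:
        scheme = default_scheme()
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")

    counts = np.zeros((len(profiles), len(scheme)), dtype=int)
    offsets = {}
    pos = 0
    for feature in scheme.features:
        block = scheme.components_for(feature)
        offsets[feature] = (pos, block)
        pos += len(block)

    samples = []
    for i, prof in enumerate(profiles):
        obs = compute_features(prof, build, baseline=baseline)
        samples.append(prof.sample)
        for feature in scheme.features:
            start, block = offsets[feature]
            values = np.asarray(obs[feature], dtype=float)
            if values.size == 0:
                continue
            idx = _feature_bin_indices(block, values)
            np.add.at(counts[i], start + idx, 1)
        if counts[i].sum() == 0:
            logger.warning("sample %s: empty catalog row", prof.sample)
    return pd.DataFrame(counts, index=pd.Index(samples, name="sample"), columns=scheme.labels)


# --- SBS-96 ----------------------------------------------------------------

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def sbs96_labels() -> list[str]:
    """The 96 context labels in COSMIC lexicographic order (C>A block first)."""
    return [
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five in _BASES
        for three in _BASES
    ]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "sample",
    "Chromosome": "chromosome",
    "Start_Position": "position",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
}


def tally_sbs_catalog(mutations: pd.DataFrame, reference) -> pd.DataFrame:
    """Tally single-base substitutions into the 96-class catalog.

    Parameters
    ----------
    mutations
        Table with columns sample, chromosome, position (1-based), ref, alt
        (MAF-style column names are also accepted). Only single-base
        substitutions are tallied; other rows are skipped with a warning.
    reference
        Mapping chromosome -> sequence supporting slicing (a
        ``pyfaidx.Fasta`` or a dict of strings).

    Substitutions are referred to by the pyrimidine of the mutated
    Watson-Crick pair: purine-reference records are reverse-complemented
    (base and flanks) before classification.
    """
    table = mutations.rename(columns=_MAF_COLUMNS)
    required = ["sample", "chromosome", "position", "ref", "alt"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"mutation table missing column(s) {missing}")

    labels = sbs96_labels()
    col_index = {lab: j for j, lab in enumerate(labels)}
    samples = list(dict.fromkeys(table["sample"]))
    row_index = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), 96), dtype=int)

    for rec in table.itertuples(index=False):
        ref_base = str(rec.ref).upper()
        alt_base = str(rec.alt).upper()
        if len(ref_base) != 1 or len(alt_base) != 1 or ref_base == alt_base:
            logger.warning("skipping non-SBS record at %s:%s", rec.chromosome, rec.position)
            continue
        pos = int(rec.position)
        context = str(reference[rec.chromosome][pos - 2 : pos + 1]).upper()
        if len(context) != 3:
            raise ValueError(f"cannot fetch trinucleotide context at {rec.chromosome}:{pos}")
        if context[1] != ref_base:
            raise ValueError(
                f"reference mismatch at {rec.chromosome}:{pos}: "
                f"table says {ref_base}, sequence has {context[1]}"
            )
        if any(b not in _BASES for b in context) or alt_base not in _BASES:
            logger.warning("skipping record with ambiguous base at %s:%s", rec.chromosome, pos)
            continue
        if ref_base in "AG":  # purine reference: flip to pyrimidine strand
            context = _revcomp(context)
            ref_base = _revcomp(rec.ref.upper())
            alt_base = _revcomp(alt_base)
        label = f"{context[0]}[{ref_base}>{alt_base}]{context[2]}"
        counts[row_index[rec.sample], col_index[label]] += 1

    return pd.DataFrame(counts, index=pd.Index(samples, name="sample"), columns=labels)
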
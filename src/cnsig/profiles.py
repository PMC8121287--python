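"""Segmented absolute copy-number profiles: containers, readers, writers.

A profile is one sample's partition of the genome into segments with
integer total copy number (diploid baseline 2). Coordinates are 1-based
inclusive throughout (seg-file convention). Adjacent same-chromosome
segments with equal copy number are merged at normalization time so that
every junction between retained segments is a true copy-number breakpoint;
gaps between consecutive segments are permitted and do not themselves
create breakpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBuild

__all__ = [
    "CNProfile",
    "read_segments",
    "write_segments",
    "normalize_profile",
]

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["chromosome", "start", "end", "cn"]

# column maps for upstream caller dialects -> generic names
_DIALECTS = {
    "generic": {"sample": "sample", "chromosome": "chromosome", "start": "start",
                "end": "end", "segVal": "cn"},
    "sequenza": {"chromosome": "chromosome", "start.pos": "start",
                 "end.pos": "end", "CNt": "cn"},
    "facets": {"chrom": "chromosome", "start": "start", "end": "end",
               "tcn.em": "cn"},
}


@dataclass
class CNProfile:
    """One sample's segments as a DataFrame (chromosome, start, end, cn).

    Rows are expected in chromosome-then-start order after
    :func:`normalize_profile`; ``cn`` is a nonnegative integer.
    """

    sample: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SEGMENT_COLUMNS if c not in self.segments.columns]
        if missing:
            raise ValueError(f"profile {self.sample}: missing columns {missing}")
        self.segments = self.segments[SEGMENT_COLUMNS].reset_index(drop=True)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.segments["chromosome"]))

    def by_chromosome(self):
        """Yield (chromosome, sub-frame) in stored order."""
        for chrom in self.chromosomes():
            yield chrom, self.segments[self.segments["chromosome"] == chrom]

    def cn_sequence(self, chrom: str) -> np.ndarray:
        sub = self.segments[self.segments["chromosome"] == chrom]
        return sub["cn"].to_numpy()

    def validate(self, build: GenomeBuild) -> None:
        for chrom, sub in self.by_chromosome():
            if chrom not in build:
                raise ValueError(
                    f"profile {self.sample}: chromosome {chrom!r} not in build {build.name}"
                )
            if (sub["end"] > build.lengths[chrom]).any():
                raise ValueError(
                    f"profile {self.sample}: segment beyond {chrom} end in build {build.name}"
                )


def _round_half_up(values: pd.Series) -> pd.Series:
    return np.floor(values.astype(float) + 0.5).astype(int)


def _normalize_chrom_names(chroms: pd.Series) -> pd.Series:
    s = chroms.astype(str).str.replace("^chr", "", regex=True)
    s = s.replace({"23": "X"})
    return "chr" + s


_TALLIED = {f"chr{i}" for i in range(1, 23)} | {"chrX"}


def read_segments(source, format: str = "generic", sample: str | None = None) -> list[CNProfile]:
    """Read segmented absolute copy-number profiles from a table or path.

    Parameters
    ----------
    source
        Path to a TSV, or a DataFrame already in the declared dialect.
    format
        ``generic`` (columns sample, chromosome, start, end, segVal),
        ``sequenza`` (chromosome, start.pos, end.pos, CNt) or ``facets``
        (chrom, start, end, tcn.em). The caller dialects carry no sample
        column; ``sample`` (or the file stem) names the single profile.
    sample
        Sample identifier used when the table has no sample column.

    Returns
    -------
    list of :class:`CNProfile`, one per sample, normalized (sorted, merged).

    Notes
    -----
    Chromosome names are accepted with or without the ``chr`` prefix;
    non-integer copy numbers are rounded half-up; chrY, chrM and unplaced
    contigs are dropped with a logged count.
    """
    if format not in _DIALECTS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_DIALECTS)}")
    colmap = _DIALECTS[format]

    if isinstance(source, (str, Path)):
        table = pd.read_csv(source, sep="\t")
        if sample is None:
            sample = Path(source).stem
    else:
        table = source.copy()

    missing = [c for c in colmap if c not in table.columns and colmap[c] != "sample"]
    if missing:
        raise ValueError(f"missing required column(s) {missing} for format {format!r}")
    table = table.rename(columns=colmap)
    if "sample" not in table.columns:
        if sample is None:
            raise ValueError(f"format {format!r} carries no sample column; pass sample=")
        table["sample"] = sample

    table["chromosome"] = _normalize_chrom_names(table["chromosome"])
    n_before = len(table)
    table = table[table["chromosome"].isin(_TALLIED)]
    dropped = n_before - len(table)
    if dropped:
        logger.info("dropped %d segment(s) on chrY/unplaced contigs", dropped)

    if (table["cn"].astype(float) < 0).any():
        bad = table[table["cn"].astype(float) < 0].iloc[0]
        raise ValueError(
            f"negative copy number in row (sample={bad['sample']}, "
            f"{bad['chromosome']}:{bad['start']}-{bad['end']}, cn={bad['cn']})"
        )
    table["cn"] = _round_half_up(table["cn"])
    table["start"] = table["start"].astype(int)
    table["end"] = table["end"].astype(int)

    profiles = []
    for name, sub in table.groupby("sample", sort=True):
        prof = CNProfile(sample=str(name), segments=sub[SEGMENT_COLUMNS])
        profiles.append(normalize_profile(prof))
    return profiles


def write_segments(profiles, path) -> None:
    """Write profiles as a generic seg TSV (sample, chromosome, start, end, segVal)."""
    frames = []
    for prof in profiles:
        sub = prof.segments.copy()
        sub.insert(0, "sample", prof.sample)
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"cn": "segVal"})
    out.to_csv(path, sep="\t", index=False)


def _chrom_sort_key(chrom: str) -> int:
    body = chrom.removeprefix("chr")
    return 23 if body == "X" else int(body)


def normalize_profile(profile: CNProfile) -> CNProfile:
    """Sort segments and merge adjacent equal-cn runs per chromosome.

    Overlapping segments are an input error. Idempotent; the total covered
    bp is preserved (merging only joins touching or gapped neighbours —
    a merged segment spans from the first start to the last end of its run).
    """
    seg = profile.segments.copy()
    if len(seg) == 0:
        raise ValueError(f"profile {profile.sample}: no segments")
    seg["_order"] = seg["chromosome"].map(_chrom_sort_key)
    seg = seg.sort_values(["_order", "start"], kind="mergesort").drop(columns="_order")

    merged_rows = []
    for chrom in dict.fromkeys(seg["chromosome"]):
        sub = seg[seg["chromosome"] == chrom]
        prev = None
        for row in sub.itertuples(index=False):
            if row.start > row.end:
                raise ValueError(
                    f"profile {profile.sample}: segment {chrom}:{row.start}-{row.end} has start > end"
                )
            if prev is not None and row.start <= prev["end"]:
                raise ValueError(
                    f"profile {profile.sample}: overlapping segments "
                    f"{chrom}:{prev['start']}-{prev['end']} and {chrom}:{row.start}-{row.end}"
                )
            if prev is not None and row.cn == prev["cn"]:
                prev["end"] = row.end
            else:
                if prev is not None:
                    merged_rows.append(prev)
                prev = {"chromosome": chrom, "start": row.start, "end": row.end, "cn": row.cn}
        if prev is not None:
            merged_rows.append(prev)

    return CNProfile(sample=profile.sample, segments=pd.DataFrame(merged_rows))
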
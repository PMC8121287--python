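"""Genome-build resources: chromosome lengths and arm boundaries.

A build tallies exactly the 23 chromosomes 1-22 and X (index 23 in the
per-chromosome burden feature); Y is never tallied. Builds are shipped as
packaged TSVs with columns ``chromosome``, ``length``, ``p_end`` where
``p_end`` is the last base of the p arm (the q arm starts at ``p_end + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = ["GenomeBuild", "load_genome_build", "available_builds"]

_BUILD_FILES = {
    "hg38": "genome_hg38.tsv",
    "hg19": "genome_hg19.tsv",
    "toy": "genome_toy.tsv",
}


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome lengths plus p/q arm boundaries (1-based, bp)."""

    name: str
    chromosomes: tuple[str, ...]
    lengths: dict[str, int] = field(repr=False)
    p_end: dict[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            length = self.lengths[chrom]
            pe = self.p_end[chrom]
            if length <= 0:
                raise ValueError(f"{chrom}: non-positive length {length}")
            if not 1 <= pe < length:
                raise ValueError(
                    f"{chrom}: arm boundary {pe} outside [1, {length})"
                )

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def chrom_index(self, chrom: str) -> int:
        """1-based tally index of a chromosome (chr1..chr22 -> 1..22, chrX -> 23)."""
        return self.chromosomes.index(chrom) + 1

    def arms(self, chrom: str) -> tuple[tuple[int, int], tuple[int, int]]:
        """(p, q) arm intervals as 1-based inclusive (start, end) pairs."""
        pe = self.p_end[chrom]
        return (1, pe), (pe + 1, self.lengths[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


def available_builds() -> list[str]:
    return sorted(_BUILD_FILES)


def load_genome_build(name: str) -> GenomeBuild:
    """Load a packaged genome build by name.

    Parameters
    ----------
    name
        One of ``hg38``, ``hg19`` or ``toy`` (a 2-chromosome 50 Mb build
        used throughout the worked examples and tests).
    """
    if name not in _BUILD_FILES:
        raise ValueError(
            f"unknown genome build {name!r}; available: {', '.join(available_builds())}"
        )
    ref = resources.files("cnsig.data").joinpath(_BUILD_FILES[name])
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return GenomeBuild(
        name=name,
        chromosomes=tuple(table["chromosome"]),
        lengths=dict(zip(table["chromosome"], table["length"].astype(int))),
        p_end=dict(zip(table["chromosome"], table["p_end"].astype(int))),
    )
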
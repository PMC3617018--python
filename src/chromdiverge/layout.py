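"""Genome layout: the coordinate universe for binning and permutation.

A :class:`GenomeLayout` records chromosome names and lengths for one species,
optionally with a centromere coordinate and an acrocentric flag per
chromosome.  Every module that bins signal, shuffles labels within
chromosomes, or rotates intervals around a circularised chromosome takes its
coordinates from here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 100_000


class InvalidParameterError(ValueError):
    """Raised when an operation receives parameters outside its domain."""


class CoordinateError(ValueError):
    """Raised when a record refers to coordinates outside the layout."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    centromere_bp: int | None = None
    acrocentric: bool = False

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise InvalidParameterError(
                f"chromosome {self.name!r}: length_bp must be positive, got {self.length_bp}"
            )
        if self.centromere_bp is not None and not (0 < self.centromere_bp < self.length_bp):
            raise InvalidParameterError(
                f"chromosome {self.name!r}: centromere_bp must lie strictly inside "
                f"(0, {self.length_bp}), got {self.centromere_bp}"
            )


@dataclass
class GenomeLayout:
    """Ordered chromosomes of one species."""

    species_tag: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidParameterError(f"duplicate chromosome names in layout: {names}")

    def __iter__(self):
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    def chrom(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise CoordinateError(f"unknown chromosome {name!r} for species {self.species_tag!r}")

    def n_bins(self, bin_size: int = DEFAULT_BIN_SIZE) -> int:
        """Number of whole bins across the genome (terminal remnants dropped)."""
        return int(sum(c.length_bp // bin_size for c in self.chromosomes))

    def bin_table(self, bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
        """All whole bins as a tidy frame (chrom, start, end), 0-based half-open.

        Chromosome remnants shorter than ``bin_size`` are not binned: the
        analysis works on fixed-width windows and a short terminal window
        would distort per-window means.
        """
        rows = []
        for c in self.chromosomes:
            n = c.length_bp // bin_size
            starts = np.arange(n, dtype=np.int64) * bin_size
            rows.append(
                pd.DataFrame(
                    {"chrom": c.name, "start": starts, "end": starts + bin_size}
                )
            )
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(rows, ignore_index=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.name for c in self.chromosomes],
                "length": [c.length_bp for c in self.chromosomes],
                "centromere": [
                    -1 if c.centromere_bp is None else c.centromere_bp
                    for c in self.chromosomes
                ],
                "acrocentric": [int(c.acrocentric) for c in self.chromosomes],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, species_tag: str) -> "GenomeLayout":
        chroms = [
            Chromosome(
                name=str(r.chrom),
                length_bp=int(r.length),
                centromere_bp=None if int(r.centromere) < 0 else int(r.centromere),
                acrocentric=bool(int(r.acrocentric)),
            )
            for r in frame.itertuples()
        ]
        return cls(species_tag=species_tag, chromosomes=chroms)
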
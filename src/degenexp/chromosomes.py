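"""Chromosome tables: per-chromosome lengths and the supergene interval.

The chromosome table is the denominator of every enrichment expectation in
this package.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChromosomeTable", "fire_ant_table"]

# Published summary figures for the placed (superscaffolded) fire-ant optical
# chromosomes: 16 chromosomes totalling 350.94 Mb, with the social chromosome
# (chr 16) spanning 29.61 Mb and the supergene occupying 7.7-28.6 Mb of it.
_TOTAL_BP = 350_940_000
_SOCIAL_BP = 29_610_000
_SUPERGENE_INTERVAL = (7_700_000, 28_600_000)


@dataclass(frozen=True)
class ChromosomeTable:
    """Per-chromosome lengths plus the single supergene-bearing chromosome.

    Parameters
    ----------
    names
        Chromosome identifiers, one per chromosome.
    lengths
        Chromosome lengths in bp; all positive.
    social
        Name of the chromosome carrying the supergene.
    supergene_interval
        ``[start, end)`` of the supergene on the social chromosome, in bp.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    social: str
    supergene_interval: tuple[int, int]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.social not in self.names:
            raise ValueError(f"social chromosome {self.social!r} not in table")
        s, e = self.supergene_interval
        social_len = self.lengths[self.names.index(self.social)]
        if not (0 <= s < e <= social_len):
            raise ValueError("supergene interval outside social chromosome")
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.names)}
        )

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    def length_of(self, name: str) -> int:
        return self.lengths[self._index[name]]

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @property
    def social_length(self) -> int:
        return self.length_of(self.social)

    @property
    def supergene_length(self) -> int:
        s, e = self.supergene_interval
        return e - s

    def social_share(self) -> float:
        """Fraction of the placed genome on the social chromosome."""
        return self.social_length / self.total_length

    def lengths_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chromosome": self.names, "length": self.lengths})
        df["is_social"] = df["chromosome"] == self.social
        s, e = self.supergene_interval
        df["supergene_start"] = np.where(df["is_social"], s, pd.NA)
        df["supergene_end"] = np.where(df["is_social"], e, pd.NA)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChromosomeTable":
        social_rows = df[df["is_social"].astype(bool)]
        if len(social_rows) != 1:
            raise ValueError("exactly one social chromosome required")
        row = social_rows.iloc[0]
        return cls(
            names=tuple(df["chromosome"].astype(str)),
            lengths=tuple(int(x) for x in df["length"]),
            social=str(row["chromosome"]),
            supergene_interval=(int(row["supergene_start"]), int(row["supergene_end"])),
        )

    def scaled(self, factor: float) -> "ChromosomeTable":
        """Return a table with every coordinate multiplied by ``factor``."""
        s, e = self.supergene_interval
        return ChromosomeTable(
            names=self.names,
            lengths=tuple(max(1, int(round(l * factor))) for l in self.lengths),
            social=self.social,
            supergene_interval=(int(round(s * factor)), int(round(e * factor))),
        )


def fire_ant_table() -> ChromosomeTable:
    """16-chromosome table emulating the placed fire-ant optical chromosomes.

    The social chromosome (chr16) is 29.61 Mb of a 350.94 Mb placed genome
    (8.4%), with the supergene at 7.7-28.6 Mb.  Lengths of chromosomes 1-15
    are a plausible decreasing series fixed so the totals match.
    """
    rest = _TOTAL_BP - _SOCIAL_BP
    base = np.linspace(30.8e6, 12.0e6, 15)
    base = np.round(base * rest / base.sum()).astype(int)
    base[-1] += rest - int(base.sum())  # force the exact total
    names = tuple(f"chr{i}" for i in range(1, 17))
    lengths = tuple(int(x) for x in base) + (_SOCIAL_BP,)
    return ChromosomeTable(
        names=names,
        lengths=lengths,
        social="chr16",
        supergene_interval=_SUPERGENE_INTERVAL,
    )
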
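"""Genome coordinates and the ordered marker map.

Coordinates are 1-based bp positions on the ten maize chromosomes; default
chromosome lengths are those of the B73 RefGen_v3 assembly, so chromosome 1
runs to 301,476,924 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

#: B73 RefGen_v3 chromosome lengths (bp), chromosomes 1-10.
B73V3_CHROM_LENGTHS: dict[int, int] = {
    1: 301_476_924,
    2: 237_917_468,
    3: 232_245_527,
    4: 242_062_272,
    5: 217_959_525,
    6: 169_407_836,
    7: 176_826_311,
    8: 175_377_686,
    9: 157_038_028,
    10: 149_632_204,
}

#: Default genetic-map rate, cM per Mb.  There is no published genetic map for
#: this cross; 0.7 cM/Mb gives a ~1,500 cM genome, typical for maize.
DEFAULT_CM_PER_MB = 0.7


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker loci over a multi-chromosome genome.

    Parameters
    ----------
    table : DataFrame with integer columns ``chrom`` and ``pos`` (1-based bp),
        sorted by (chrom, pos), positions strictly increasing within a
        chromosome.
    chrom_lengths : mapping chromosome -> length in bp.
    cm_per_mb : mapping chromosome -> genetic-map rate (cM/Mb).
    """

    table: pd.DataFrame
    chrom_lengths: dict[int, int] = field(
        default_factory=lambda: dict(B73V3_CHROM_LENGTHS)
    )
    cm_per_mb: dict[int, float] = field(
        default_factory=lambda: {c: DEFAULT_CM_PER_MB for c in B73V3_CHROM_LENGTHS}
    )

    def __post_init__(self) -> None:
        tab = self.table
        if not {"chrom", "pos"}.issubset(tab.columns):
            raise InvalidInputError("marker table needs 'chrom' and 'pos' columns")
        for length in self.chrom_lengths.values():
            if length <= 0:
                raise InvalidConfigError("chromosome lengths must be positive")
        if len(tab) and (tab["pos"] < 1).any():
            raise InvalidInputError("marker positions must be >= 1")
        for chrom, grp in tab.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise InvalidInputError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
            if chrom not in self.chrom_lengths:
                raise InvalidInputError(f"chromosome {chrom} has no length")
            if pos[-1] > self.chrom_lengths[chrom]:
                raise InvalidInputError(
                    f"marker beyond end of chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def genetic_positions(self, chrom: int, bp: np.ndarray) -> np.ndarray:
        """Map bp positions on one chromosome to cM under the linear rate."""
        return np.asarray(bp, dtype=float) * self.cm_per_mb[chrom] / 1e6

    def genetic_length(self, chrom: int) -> float:
        """Genetic length of a chromosome in cM."""
        return self.chrom_lengths[chrom] * self.cm_per_mb[chrom] / 1e6
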
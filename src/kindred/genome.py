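"""Genetic map: physical and genetic coordinates of the analysed sites.

The map carries, for every site, a chromosome label, a physical position in
base pairs and a genetic position in centimorgans.  It is the common
coordinate system for block-bootstrap resampling (blocks are cut by physical
position) and for IBD arithmetic (segment lengths and the genome-length
denominator are genetic distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap"]


@dataclass
class GeneticMap:
    """Per-site coordinates on a multi-chromosome genome.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per site.  Sites of one chromosome must be
        contiguous and sorted by physical position.
    pos_bp : array of int
        Physical position (bp), strictly increasing within a chromosome.
    pos_cm : array of float
        Genetic position (cM), nondecreasing within a chromosome.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray
    _chrom_order: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if not (len(self.chrom) == len(self.pos_bp) == len(self.pos_cm)):
            raise ValueError("chrom, pos_bp and pos_cm must have equal length")
        if len(self.chrom) == 0:
            raise ValueError("empty genetic map")
        # preserve first-appearance chromosome order
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        self._chrom_order = list(seen)
        for c in self._chrom_order:
            m = self.chrom == c
            bp = self.pos_bp[m]
            cm = self.pos_cm[m]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"physical positions not strictly increasing on {c}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"genetic positions decrease on {c}")
        if self.total_cm <= 0:
            raise ValueError("total map length must be positive")

    # -- constructors ------------------------------------------------------

    @classmethod
    def regular(
        cls,
        n_sites: int,
        n_chrom: int = 4,
        chrom_length_bp: int = 100_000_000,
        cm_per_mb: float = 1.0,
    ) -> "GeneticMap":
        """Evenly spaced sites on equal-length chromosomes with a uniform
        recombination rate (default 1 cM/Mb)."""
        if n_sites < n_chrom:
            raise ValueError("need at least one site per chromosome")
        per = np.full(n_chrom, n_sites // n_chrom)
        per[: n_sites % n_chrom] += 1
        chroms, bps = [], []
        for i, n in enumerate(per):
            # spacing keeps sites strictly inside (0, L]
            step = chrom_length_bp // (n + 1)
            pos = (np.arange(1, n + 1) * step).astype(np.int64)
            chroms.append(np.full(n, f"chr{i + 1}", dtype=object))
            bps.append(pos)
        bp = np.concatenate(bps)
        return cls(
            chrom=np.concatenate(chroms),
            pos_bp=bp,
            pos_cm=bp * 1e-6 * cm_per_mb,
        )

    # -- properties --------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> list:
        return list(self._chrom_order)

    def chrom_mask(self, c) -> np.ndarray:
        return self.chrom == c

    def chrom_cm_length(self, c) -> float:
        """Genetic length of a chromosome, anchored at 0 cM."""
        return float(self.pos_cm[self.chrom == c].max())

    @property
    def total_cm(self) -> float:
        return float(sum(self.pos_cm[self.chrom == c].max() for c in self._chrom_order))

    # -- block partition for the bootstrap ---------------------------------

    def block_indices(self, block_bp: int = 10_000_000) -> list[np.ndarray]:
        """Partition sites into contiguous nonoverlapping physical blocks.

        Each chromosome is cut into ``block_bp`` windows starting at 0; the
        final short window is kept as its own block.  Returns one index
        array per nonempty block.
        """
        if block_bp <= 0:
            raise ValueError("block_bp must be positive")
        out: list[np.ndarray] = []
        idx = np.arange(self.n_sites)
        for c in self._chrom_order:
            m = self.chrom == c
            bins = self.pos_bp[m] // block_bp
            sub = idx[m]
            for b in np.unique(bins):
                out.append(sub[bins == b])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos_bp, "cm": self.pos_cm}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos_bp=df["pos"].to_numpy(),
            pos_cm=df["cm"].to_numpy(),
        )
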
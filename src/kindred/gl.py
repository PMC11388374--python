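"""Genotype-likelihood matrices and reference allele-frequency panels.

Low-coverage ancient samples are represented not by hard genotype calls but
by three normalized likelihoods per site — P(reads | g) for g = 0, 1, 2
copies of the derived allele.  Files use the beagle genotype-likelihood text
layout (``marker alleleA alleleB`` then three columns per individual),
either with linear likelihoods or with phred-scaled values
(likelihood ∝ 10^(−PL/10)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneticMap

__all__ = ["GLMatrix", "ReferencePanel", "read_beagle", "write_beagle"]

MISSING_GL = np.array([1 / 3, 1 / 3, 1 / 3])
FREQ_CLAMP = 1e-5


def _normalize_rows(gl: np.ndarray) -> np.ndarray:
    s = gl.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("genotype likelihood triple sums to zero")
    return gl / s


@dataclass
class GLMatrix:
    """Normalized genotype likelihoods for a cohort.

    Attributes
    ----------
    ids : list of str
    gmap : GeneticMap
        Site coordinates, shared with the reference panel after intersection.
    gl : ndarray, shape (n_individuals, n_sites, 3)
        Rows sum to 1; sites with no data hold the uniform triple.
    missing : bool ndarray, shape (n_individuals, n_sites)
    """

    ids: list
    gmap: GeneticMap
    gl: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, s = len(self.ids), self.gmap.n_sites
        if self.gl.shape != (n, s, 3):
            raise ValueError(f"gl shape {self.gl.shape} != ({n}, {s}, 3)")
        if self.missing.shape != (n, s):
            raise ValueError("missing mask shape mismatch")
        sums = self.gl.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("genotype likelihood triples must sum to 1")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return self.gmap.n_sites

    def individual(self, iid) -> tuple[np.ndarray, np.ndarray]:
        """(S, 3) likelihoods and missing mask for one individual."""
        i = self.ids.index(iid)
        return self.gl[i], self.missing[i]

    def subset_sites(self, idx: np.ndarray) -> "GLMatrix":
        sub = GeneticMap(self.gmap.chrom[idx], self.gmap.pos_bp[idx], self.gmap.pos_cm[idx])
        return GLMatrix(list(self.ids), sub, self.gl[:, idx], self.missing[:, idx])


@dataclass
class ReferencePanel:
    """Derived-allele frequencies for K reference populations.

    Frequencies are clamped into [1e-5, 1 − 1e-5] so that fixed sites cannot
    produce infinite log-likelihood terms.
    """

    populations: list
    gmap: GeneticMap
    freqs: np.ndarray  # (n_sites, K)

    def __post_init__(self) -> None:
        self.freqs = np.clip(np.asarray(self.freqs, dtype=float), FREQ_CLAMP, 1 - FREQ_CLAMP)
        if self.freqs.shape != (self.gmap.n_sites, len(self.populations)):
            raise ValueError("frequency matrix shape mismatch")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def population_index(self, name: str) -> int:
        try:
            return self.populations.index(name)
        except ValueError:
            raise KeyError(f"unknown population {name!r}") from None

    def pooled(self, names) -> np.ndarray:
        """Mean frequency over named populations (used for kinship)."""
        cols = [self.population_index(n) for n in names]
        return self.freqs[:, cols].mean(axis=1)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        df = self.gmap.to_frame()
        for j, p in enumerate(self.populations):
            df[p] = self.freqs[:, j]
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", comment="#")
        pops = [c for c in df.columns if c not in ("chrom", "pos", "cm")]
        gmap = GeneticMap.from_frame(df)
        return cls(pops, gmap, df[pops].to_numpy())


def intersect_sites(gl: GLMatrix, panel: ReferencePanel) -> tuple[GLMatrix, ReferencePanel]:
    """Align a GL matrix and a panel on their shared (chrom, pos) sites."""
    a = pd.MultiIndex.from_arrays([gl.gmap.chrom, gl.gmap.pos_bp])
    b = pd.MultiIndex.from_arrays([panel.gmap.chrom, panel.gmap.pos_bp])
    common = a.intersection(b, sort=False)
    if len(common) == 0:
        raise ValueError("no shared sites between GL matrix and panel")
    ia = a.get_indexer(common)
    ib = b.get_indexer(common)
    sub_gl = gl.subset_sites(np.sort(ia))
    order = np.argsort(ia)
    panel_sub = ReferencePanel(
        list(panel.populations),
        sub_gl.gmap,
        panel.freqs[ib[order]],
    )
    return sub_gl, panel_sub


# ---------------------------------------------------------------------------
# beagle-style text IO


def write_beagle(
    glmat: GLMatrix,
    path,
    dialect: str = "linear",
    header_lines: list[str] | None = None,
) -> None:
    """Write a beagle genotype-likelihood text file.

    ``dialect='phred'`` writes PL-style values −10·log10(L/L_max) rounded to
    3 decimals; ``'linear'`` writes the normalized likelihoods themselves.
    Markers are encoded ``chrom_pos``.
    """
    if dialect not in ("linear", "phred"):
        raise ValueError(f"unknown dialect {dialect!r}")
    n, s = glmat.n_individuals, glmat.n_sites
    markers = [f"{c}_{p}" for c, p in zip(glmat.gmap.chrom, glmat.gmap.pos_bp)]
    cols = ["marker", "allele1", "allele2"]
    for iid in glmat.ids:
        cols += [str(iid)] * 3
    vals = glmat.gl  # (n, s, 3)
    if dialect == "phred":
        mx = vals.max(axis=2, keepdims=True)
        out = -10.0 * np.log10(np.maximum(vals / mx, 1e-300))
    else:
        out = vals
    flat = out.transpose(1, 0, 2).reshape(s, 3 * n)
    buf = io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    buf.write("\t".join(cols) + "\n")
    for r in range(s):
        row = [markers[r], "0", "1"] + [f"{x:.6g}" for x in flat[r]]
        buf.write("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_beagle(path, dialect: str = "linear", cm_per_mb: float = 1.0) -> GLMatrix:
    """Read a beagle genotype-likelihood text file.

    Markers must be ``chrom_pos``; genetic positions are reconstructed at
    ``cm_per_mb`` (uniform map) unless a sidecar map is applied afterwards.
    Malformed rows raise with their line number.
    """
    if dialect not in ("linear", "phred"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 6 or (len(header) - 3) % 3 != 0:
        raise ValueError(f"{path}: header does not contain id triples")
    ids = header[3::3]
    n = len(ids)
    chroms, bps, glrows = [], [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 3 + 3 * n:
            raise ValueError(
                f"{path}: line {lineno}: expected {3 + 3 * n} columns, got {len(parts)}"
            )
        marker = parts[0]
        try:
            chrom, pos = marker.rsplit("_", 1)
            bps.append(int(pos))
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: bad marker {marker!r}") from None
        chroms.append(chrom)
        try:
            glrows.append([float(x) for x in parts[3:]])
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric likelihood") from None
    raw = np.asarray(glrows).reshape(len(bps), n, 3).transpose(1, 0, 2)
    if dialect == "phred":
        raw = 10.0 ** (-raw / 10.0)
    gl = _normalize_rows(raw)
    # uniform triples mark missing sites
    missing = np.all(np.abs(gl - 1 / 3) < 1e-6, axis=2)
    bp = np.asarray(bps, dtype=np.int64)
    gmap = GeneticMap(np.asarray(chroms, dtype=object), bp, bp * 1e-6 * cm_per_mb)
    return GLMatrix(list(ids), gmap, gl, missing)
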
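"""Strontium mobility classification, collagen QC and dietary contrasts.

Mobility: tooth-enamel ⁸⁷Sr/⁸⁶Sr reflects the geology where an individual
grew up.  Two nested local baselines are derived from the human values
themselves — a strict "local center" (mean ± 2 SD of nonadults, who must
have formed enamel locally) nested in a wider local range (mean ± 2 SD of
all humans, cross-checked against environmental samples).  Individuals are
classed local_center / wider_local / nonlocal accordingly.

Diet: bone-collagen δ13C and δ15N are compared between groups with a
two-sided permutation test on the difference of means, after a standard
collagen-preservation screen (%C > 13, %N > 4.8, atomic C/N in [2.9, 3.6]).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import permutation_test

__all__ = [
    "LocalityRanges",
    "derive_locality_ranges",
    "classify_locality",
    "collagen_qc",
    "qc_table",
    "diet_group_compare",
]

# atomic masses for the weight% -> atomic C/N conversion
_MASS_C = 12.011
_MASS_N = 14.007

QC_MIN_PCT_C = 13.0
QC_MIN_PCT_N = 4.8
QC_CN_RANGE = (2.9, 3.6)


@dataclass
class LocalityRanges:
    """Nested local Sr intervals: strict center inside the wider range."""

    center: tuple
    wider: tuple
    n_nonadults: int = 0
    n_humans: int = 0
    n_environmental: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.wider
        if lo > hi:
            raise ValueError("wider interval inverted")
        # center clipped into wider
        clo, chi = self.center
        self.center = (max(clo, lo), min(chi, hi))


def derive_locality_ranges(humans: pd.DataFrame, environmental=None) -> LocalityRanges:
    """Two-tier local Sr baseline from human (and environmental) values.

    center = mean ± 2·SD of nonadult human ratios; wider = mean ± 2·SD of
    all human ratios.  Environmental values act as a consistency check: a
    warning flag is recorded if any falls outside the wider range.  With
    fewer than 2 nonadults the center falls back to the wider range
    (flagged).
    """
    sr = humans["sr_ratio"].dropna()
    if len(sr) < 2:
        raise ValueError("need at least 2 human Sr values")
    is_nonadult = humans.loc[sr.index, "age_class"] == "nonadult"
    nonadult = sr[is_nonadult]
    flags: list = []
    mean_all, sd_all = sr.mean(), sr.std(ddof=1)
    wider = (mean_all - 2 * sd_all, mean_all + 2 * sd_all)
    if len(nonadult) >= 2:
        m, s = nonadult.mean(), nonadult.std(ddof=1)
        center = (m - 2 * s, m + 2 * s)
    else:
        center = wider
        flags.append("insufficient nonadults: center set to wider range")
    n_env = 0
    if environmental is not None:
        env = np.asarray(
            environmental["sr_ratio"] if isinstance(environmental, pd.DataFrame) else environmental,
            dtype=float,
        )
        n_env = len(env)
        outside = (env < wider[0]) | (env > wider[1])
        if outside.any():
            msg = f"{int(outside.sum())} environmental value(s) outside the wider human range"
            flags.append(msg)
            _warnings.warn(msg, stacklevel=2)
    return LocalityRanges(
        center=center, wider=wider, n_nonadults=int(is_nonadult.sum()),
        n_humans=len(sr), n_environmental=n_env, flags=flags,
    )


def classify_locality(sr_ratio, ranges: LocalityRanges) -> str:
    """local_center / wider_local / nonlocal / unknown for one Sr value."""
    if sr_ratio is None or (isinstance(sr_ratio, float) and np.isnan(sr_ratio)):
        return "unknown"
    if ranges.center[0] <= sr_ratio <= ranges.center[1]:
        return "local_center"
    if ranges.wider[0] <= sr_ratio <= ranges.wider[1]:
        return "wider_local"
    return "nonlocal"


def collagen_qc(pct_c: float, pct_n: float) -> tuple[bool, list]:
    """Collagen-preservation screen; returns (passed, failed criteria).

    Atomic C/N = (%C/12.011)/(%N/14.007); acceptance needs %C > 13,
    %N > 4.8 and C/N within [2.9, 3.6] (inclusive).
    """
    reasons = []
    if pct_c is None or pct_n is None or np.isnan(pct_c) or np.isnan(pct_n):
        return False, ["missing measurement"]
    if pct_n == 0:
        return False, ["undefined ratio"]
    if pct_c <= QC_MIN_PCT_C:
        reasons.append("carbon")
    if pct_n <= QC_MIN_PCT_N:
        reasons.append("nitrogen")
    cn = (pct_c / _MASS_C) / (pct_n / _MASS_N)
    if not (QC_CN_RANGE[0] <= cn <= QC_CN_RANGE[1]):
        reasons.append("ratio")
    return len(reasons) == 0, reasons


def atomic_cn(pct_c: float, pct_n: float) -> float:
    return (pct_c / _MASS_C) / (pct_n / _MASS_N)


def qc_table(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the collagen screen to a record table.

    Adds ``cn_atomic``, ``qc_pass`` and ``qc_reasons`` columns; idempotent.
    """
    out = records.copy()
    res = [collagen_qc(c, n) for c, n in zip(out["pctC"], out["pctN"])]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cn_atomic"] = (out["pctC"] / _MASS_C) / (out["pctN"] / _MASS_N)
    out["qc_pass"] = [r[0] for r in res]
    out["qc_reasons"] = [";".join(r[1]) for r in res]
    return out


def diet_group_compare(
    records: pd.DataFrame,
    grouping,
    isotope_field: str = "d13C",
    B: int = 10_000,
    seed=None,
) -> dict:
    """Permutation contrast of a dietary isotope between two groups.

    ``grouping`` is a boolean Series/array aligned with ``records`` (True =
    focal group).  Records failing collagen QC must be excluded upstream;
    if a ``qc_pass`` column is present it is honoured here.  When either
    group has fewer than 2 members the means are reported but the p-value
    withheld.
    """
    df = records
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"]]
    grouping = np.asarray(grouping, dtype=bool)
    if len(grouping) != len(records):
        raise ValueError("grouping length mismatch")
    grouping = grouping[records.index.isin(df.index)] if len(df) != len(records) else grouping
    vals = df[isotope_field].to_numpy(dtype=float)
    in_g, out_g = vals[grouping], vals[~grouping]
    if len(in_g) == 0 or len(out_g) == 0:
        raise ValueError("both groups must be nonempty")
    out = {
        "field": isotope_field,
        "n_group": int(len(in_g)),
        "n_rest": int(len(out_g)),
        "mean_group": float(in_g.mean()),
        "mean_rest": float(out_g.mean()),
        "difference": float(in_g.mean() - out_g.mean()),
        "n_permutations": B,
        "pvalue": None,
    }
    if len(in_g) >= 2 and len(out_g) >= 2:
        labels = np.where(grouping, "group", "rest")
        res = permutation_test(vals, labels, B=B, seed=seed)
        out["pvalue"] = res.pvalue
    return out
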
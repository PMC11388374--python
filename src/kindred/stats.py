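"""Shared inferential statistics: permutation tests and Cramér's V.

These back the community-level comparisons — ancestry differences between a
pedigree and the rest of the cohort, dietary isotope contrasts between
groups, and the association between grave-good classes and pedigree
membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

__all__ = ["PermutationTestResult", "permutation_test", "cramers_v"]


@dataclass
class PermutationTestResult:
    """Two-sided permutation test on a difference of group means.

    p = (1 + #{|T_perm| >= |T_obs|}) / (B + 1); ties count as exceedances,
    so p is never 0 and equals 1 on constant data.
    """

    observed: float
    n_permutations: int
    pvalue: float
    seed: object = None
    n_a: int = 0
    n_b: int = 0
    mean_a: float = np.nan
    mean_b: float = np.nan


def permutation_test(values, labels, B: int = 10_000, seed=None,
                     group_order=None) -> PermutationTestResult:
    """Permutation test for a difference in means between two groups.

    Parameters
    ----------
    values : 1-d array of measurements
    labels : 1-d array with exactly two distinct values; the statistic is
        mean(first group) − mean(second group), groups ordered by first
        appearance unless ``group_order`` names them explicitly.
    B : number of label permutations (>= 1)
    group_order : optional pair of labels fixing which group comes first;
        exchanging the two entries negates the observed statistic and (for
        equal group sizes under a fixed seed) leaves the p-value unchanged.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-d arrays")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {len(uniq)}")
    if group_order is not None:
        if set(group_order) != set(uniq):
            raise ValueError("group_order must name the two labels present")
        uniq = list(group_order)
    if B < 1:
        raise ValueError("B must be >= 1")
    mask = labels == uniq[0]
    n_a = int(mask.sum())
    n = len(values)
    if n_a == 0 or n_a == n:
        raise ValueError("one group is empty")
    obs = values[mask].mean() - values[~mask].mean()

    rng = np.random.default_rng(seed)
    # vectorized label shuffles: argsort of random keys gives uniform permutations
    keys = rng.random((B, n))
    order = np.argsort(keys, axis=1)
    perm_vals = values[order]
    t_a = perm_vals[:, :n_a].mean(axis=1)
    t_b = perm_vals[:, n_a:].mean(axis=1)
    t = t_a - t_b
    exceed = np.sum(np.abs(t) >= np.abs(obs) - 1e-12)
    p = (1 + exceed) / (B + 1)
    return PermutationTestResult(
        observed=float(obs),
        n_permutations=B,
        pvalue=float(p),
        seed=seed,
        n_a=n_a,
        n_b=n - n_a,
        mean_a=float(values[mask].mean()),
        mean_b=float(values[~mask].mean()),
    )


def cramers_v(table) -> float:
    """Cramér's V for an r×c contingency table.

    V = sqrt(χ² / (n · (min(r, c) − 1))) with the Pearson χ² statistic and
    no continuity correction.  For 2×2 tables V equals |φ|.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("table must hold nonnegative counts with positive total")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an all-zero row or column")
    chi2 = chi2_contingency(t, correction=False).statistic
    n = t.sum()
    k = min(t.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))
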
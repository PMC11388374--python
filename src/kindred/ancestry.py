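"""Supervised admixture from genotype likelihoods.

Model
-----
For one target individual, the reference panel supplies derived-allele
frequencies f_k(s) for K fixed populations.  Under admixture proportions q
(on the simplex), the individual's derived-allele probability at site s is
h(s) = Σ_k q_k f_k(s), genotypes are Binomial(2, h(s)), and the observed
data enter through normalized genotype likelihoods GL(s, g):

    ℓ(q) = Σ_s log Σ_g GL(s, g) · Binom(g; 2, h(s)).

ℓ is maximized by EM: each of the two allele copies at a site is allocated
to population k with probability q_k f_k / h for a derived copy or
q_k (1 − f_k) / (1 − h) for an ancestral copy (weighted by the genotype
posterior), and q is updated to the mean allocation.  The fit is restarted
from independent Dirichlet(1) draws and the best run kept, because the
likelihood can be multimodal when panel populations are weakly
differentiated.

Uncertainty comes from a simple nonoverlapping block bootstrap: chromosomes
are cut into fixed-size physical blocks (default 10 Mb), blocks are
resampled with replacement, and q is re-estimated per replicate.  Weakly
differentiated population pairs swap ancestry between replicates, inflating
per-component intervals; pooling such a pair narrows them — both effects
are exposed via :meth:`BootstrapResult.pool`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gl import GLMatrix, ReferencePanel

__all__ = [
    "AdmixtureModel",
    "AdmixtureResults",
    "BootstrapResult",
    "admixture_loglik",
    "estimate_admixture",
    "block_bootstrap",
    "pool_components",
    "congruence_correlation",
]

_SIMPLEX_TOL = 1e-6


def _check_simplex(q: np.ndarray, tol: float = _SIMPLEX_TOL) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q < -tol) or abs(q.sum() - 1.0) > tol:
        raise ValueError("q must lie on the probability simplex")
    return np.clip(q, 0.0, None) / np.clip(q, 0.0, None).sum()


def admixture_loglik(q, gl: np.ndarray, freqs: np.ndarray) -> float:
    """Mixture log-likelihood ℓ(q) over all supplied sites.

    Missing sites carrying the uniform triple contribute the constant
    log(1/3) each, so they never move the optimum.
    """
    q = _check_simplex(q)
    gl = np.asarray(gl, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if gl.shape[0] != freqs.shape[0] or freqs.shape[1] != len(q):
        raise ValueError("site/population dimension mismatch")
    h = freqs @ q
    pg = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h**2], axis=1)
    return float(np.log((gl * pg).sum(axis=1)).sum())


def _em_step(q, gl, freqs):
    """One EM update; returns (q_next, loglik at the input q).

    The log-likelihood is nondecreasing under this map (EM property).
    """
    S = freqs.shape[0]
    h = freqs @ q
    p0 = (1 - h) ** 2
    p1 = 2 * h * (1 - h)
    p2 = h**2
    w0 = gl[:, 0] * p0
    w1 = gl[:, 1] * p1
    w2 = gl[:, 2] * p2
    tot = w0 + w1 + w2
    ll = float(np.log(tot).sum())
    # expected derived copies per site under the genotype posterior
    ed = (w1 + 2 * w2) / tot
    A = (q[None, :] * freqs) / h[:, None]               # derived-copy allocation
    Bm = (q[None, :] * (1 - freqs)) / (1 - h)[:, None]  # ancestral-copy allocation
    qn = (ed @ A + (2 - ed) @ Bm) / (2 * S)
    qn = np.clip(qn, 1e-12, None)
    return qn / qn.sum(), ll


def _em(gl, freqs, q0, tol=1e-6, maxiter=2000):
    """SQUAREM-accelerated EM from q0; returns (q, loglik, converged, n_iter).

    Each cycle takes two plain EM steps, extrapolates along the observed
    step direction and stabilizes the extrapolation with one further EM
    step; whenever the extrapolated point lowers the likelihood the plain
    double step is kept instead, so the likelihood never decreases.  The
    loop stops when a full cycle improves the log-likelihood by < ``tol``.
    """
    q = np.asarray(q0, dtype=float)
    ll_prev = -np.inf
    converged = False
    it = 0
    while it < maxiter:
        q1, ll_q = _em_step(q, gl, freqs)
        q2, ll_q1 = _em_step(q1, gl, freqs)
        it += 2
        r = q1 - q
        v = (q2 - q1) - r
        vv = float(v @ v)
        if vv > 1e-30:
            alpha = -np.sqrt(float(r @ r) / vv)
            qe = q - 2 * alpha * r + alpha * alpha * v
            qe = np.clip(qe, 1e-12, None)
            qe /= qe.sum()
            qn, ll_qe = _em_step(qe, gl, freqs)
            it += 1
            q = qn if ll_qe >= ll_q1 else q2
        else:
            q = q2
        if ll_q - ll_prev < tol and it > 3:
            converged = True
            ll_prev = ll_q
            break
        ll_prev = ll_q
    # final likelihood at the returned point
    h = freqs @ q
    pg = np.stack([(1 - h) ** 2, 2 * h * (1 - h), h**2], axis=1)
    ll = float(np.log((gl * pg).sum(axis=1)).sum())
    return q, max(ll, ll_prev), converged, it


@dataclass
class AncestryEstimate:
    q: np.ndarray
    loglik: float
    n_restarts: int
    converged: bool
    n_sites: int


def estimate_admixture(
    gl: np.ndarray,
    freqs: np.ndarray,
    restarts: int = 50,
    seed=None,
    tol: float = 1e-6,
    maxiter: int = 2000,
    missing: np.ndarray | None = None,
    init: np.ndarray | None = None,
) -> AncestryEstimate:
    """Best-of-restarts EM estimate of admixture proportions.

    Restarts are initialized from Dirichlet(1, ..., 1) draws; when ``init``
    is given it is used as the first (warm) start and the remaining
    ``restarts − 1`` are random.
    """
    gl = np.asarray(gl, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if missing is not None:
        keep = ~np.asarray(missing, dtype=bool)
        gl = gl[keep]
        freqs = freqs[keep]
    if gl.shape[0] == 0:
        raise ValueError("no informative sites")
    K = freqs.shape[1]
    rng = np.random.default_rng(seed)
    best = None
    inits = []
    if init is not None:
        inits.append(_check_simplex(init))
    while len(inits) < restarts:
        inits.append(rng.dirichlet(np.ones(K)))
    for q0 in inits:
        q, ll, conv, _ = _em(gl, freqs, q0, tol=tol, maxiter=maxiter)
        if best is None or ll > best[1]:
            best = (q, ll, conv)
    q, ll, conv = best
    return AncestryEstimate(q=q, loglik=ll, n_restarts=restarts, converged=conv, n_sites=gl.shape[0])


# ---------------------------------------------------------------------------
# Model / Results interface


class AdmixtureModel:
    """Supervised admixture model for one individual against a fixed panel.

    Parameters
    ----------
    gl : (S, 3) normalized genotype likelihoods
    panel : ReferencePanel aligned to the same S sites
    missing : optional (S,) bool mask of no-data sites

    Examples
    --------
    >>> model = AdmixtureModel.from_matrix(glmat, panel, "IND_3")  # doctest: +SKIP
    >>> res = model.fit(restarts=50, seed=1)                       # doctest: +SKIP
    >>> res.q, res.llf                                             # doctest: +SKIP
    """

    def __init__(self, gl, panel: ReferencePanel, missing=None, individual: str | None = None):
        self.gl = np.asarray(gl, dtype=float)
        self.panel = panel
        if self.gl.shape != (panel.gmap.n_sites, 3):
            raise ValueError("gl must be (n_sites, 3) aligned with the panel")
        self.missing = (
            np.zeros(panel.gmap.n_sites, dtype=bool)
            if missing is None
            else np.asarray(missing, dtype=bool)
        )
        self.individual = individual

    @classmethod
    def from_matrix(cls, glmat: GLMatrix, panel: ReferencePanel, individual) -> "AdmixtureModel":
        gl, missing = glmat.individual(individual)
        return cls(gl, panel, missing=missing, individual=individual)

    def loglike(self, q) -> float:
        return admixture_loglik(q, self.gl, self.panel.freqs)

    def fit(self, restarts: int = 50, seed=None, tol: float = 1e-6, maxiter: int = 2000,
            init=None) -> "AdmixtureResults":
        est = estimate_admixture(
            self.gl, self.panel.freqs, restarts=restarts, seed=seed,
            tol=tol, maxiter=maxiter, missing=self.missing, init=init,
        )
        return AdmixtureResults(self, est)


@dataclass
class AdmixtureResults:
    """Fitted admixture proportions with likelihood diagnostics."""

    model: AdmixtureModel
    estimate: AncestryEstimate

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.estimate.q, index=self.model.panel.populations, name="q")

    q = params

    @property
    def llf(self) -> float:
        return self.estimate.loglik

    @property
    def nobs(self) -> int:
        return self.estimate.n_sites

    @property
    def converged(self) -> bool:
        return self.estimate.converged

    def bootstrap(self, B: int = 100, block_bp: int = 10_000_000, seed=None,
                  restarts: int = 5) -> "BootstrapResult":
        return block_bootstrap(
            self.model.gl, self.model.panel, block_bp=block_bp, B=B, seed=seed,
            missing=self.model.missing, point_estimate=self.estimate.q,
            restarts=restarts,
        )

    def summary(self) -> str:
        lines = [
            "Supervised admixture (genotype-likelihood EM)",
            "=" * 45,
            f"individual:        {self.model.individual or '-'}",
            f"informative sites: {self.nobs}",
            f"log-likelihood:    {self.llf:.3f}",
            f"restarts:          {self.estimate.n_restarts}",
            f"converged:         {self.converged}",
            "-" * 45,
            f"{'population':<15}{'proportion':>12}",
        ]
        for pop, val in self.params.items():
            lines.append(f"{pop:<15}{val:>12.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of the admixture vector (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.params.plot.bar(ax=ax)
        ax.set_ylabel("ancestry proportion")
        ax.set_ylim(0, 1)
        return ax


# ---------------------------------------------------------------------------
# block bootstrap


@dataclass
class BootstrapResult:
    """Replicate admixture vectors from the block bootstrap.

    ``replicates`` is (B, K); per-component SD and 2.5/97.5 percentile
    intervals summarize it.
    """

    populations: list
    replicates: np.ndarray
    seed: object = None
    block_bp: int = 10_000_000

    @property
    def sd(self) -> pd.Series:
        return pd.Series(self.replicates.std(axis=0, ddof=1), index=self.populations, name="sd")

    @property
    def ci(self) -> pd.DataFrame:
        lo, hi = np.percentile(self.replicates, [2.5, 97.5], axis=0)
        return pd.DataFrame({"low": lo, "high": hi}, index=self.populations)

    def pool(self, pairs) -> pd.DataFrame:
        """Pooled estimates for named population pairs.

        The pooled replicate value is the sum of the two member components
        within each replicate, so its SD reflects their (negative)
        covariance — the mechanism by which pooling two easily confused
        ancestries narrows the interval.
        """
        return pool_components(self, pairs)


def block_bootstrap(
    gl,
    panel: ReferencePanel,
    block_bp: int = 10_000_000,
    B: int = 100,
    seed=None,
    missing=None,
    point_estimate=None,
    restarts: int = 5,
    tol: float = 1e-6,
    maxiter: int = 2000,
) -> BootstrapResult:
    """Nonoverlapping physical-block bootstrap of the admixture estimate.

    Chromosomes are partitioned into contiguous ``block_bp`` windows (the
    final short window is retained); each replicate draws the same number of
    blocks with replacement from the pooled list, concatenates their sites
    and re-runs the EM.  Replicate fits use ``restarts`` starts, the first
    warm-started at ``point_estimate`` when given.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    gl = np.asarray(gl, dtype=float)
    blocks = panel.gmap.block_indices(block_bp)
    if len(blocks) < 2:
        raise ValueError("fewer than 2 blocks; shrink block_bp or add sites")
    if missing is None:
        missing = np.zeros(gl.shape[0], dtype=bool)
    if point_estimate is None:
        point_estimate = estimate_admixture(
            gl, panel.freqs, restarts=max(restarts, 5), seed=seed, missing=missing
        ).q
    rng = np.random.default_rng(seed)
    nb = len(blocks)
    reps = np.empty((B, panel.n_populations))
    for b in range(B):
        chosen = rng.integers(0, nb, size=nb)
        idx = np.concatenate([blocks[c] for c in chosen])
        est = estimate_admixture(
            gl[idx], panel.freqs[idx], restarts=restarts,
            seed=rng.integers(2**31 - 1), missing=missing[idx],
            init=point_estimate, tol=tol, maxiter=maxiter,
        )
        reps[b] = est.q
    return BootstrapResult(list(panel.populations), reps, seed=seed, block_bp=block_bp)


def pool_components(result: BootstrapResult, pairs) -> pd.DataFrame:
    """Sum named component pairs within each bootstrap replicate.

    Returns one row per pair with the pooled point estimate (mean over
    replicates), SD and percentile interval.
    """
    rows = []
    for a, b in pairs:
        ia = result.populations.index(a) if a in result.populations else None
        ib = result.populations.index(b) if b in result.populations else None
        if ia is None or ib is None:
            missing = a if ia is None else b
            raise KeyError(f"unknown population {missing!r}")
        pooled = result.replicates[:, ia] + result.replicates[:, ib]
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        rows.append(
            {
                "pair": f"{a}+{b}",
                "estimate": pooled.mean(),
                "sd": pooled.std(ddof=1),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("pair")


def congruence_correlation(estimates_a: pd.DataFrame, estimates_b: pd.DataFrame, component) -> float:
    """Pearson correlation of a (possibly pooled) component across individuals.

    ``component`` may be one column name or a list of names, in which case
    the named columns are summed before correlating (e.g. a northern
    component defined as the sum of two panel populations).  Both frames are
    indexed by individual id; they must cover the same individuals.
    """
    comps = [component] if isinstance(component, str) else list(component)
    a = estimates_a[comps].sum(axis=1)
    b = estimates_b[comps].sum(axis=1)
    if set(a.index) != set(b.index):
        raise ValueError("estimate sets cover different individuals")
    b = b.reindex(a.index)
    if len(a) < 3:
        raise ValueError("need at least 3 individuals")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a component vector")
    return float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
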
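"""Pairwise relatedness from genotype likelihoods and pedigree assembly.

The pair model estimates (k0, k1, k2) — the probabilities that two
individuals share 0, 1 or 2 alleles identical by descent at a random
autosomal locus — by maximum likelihood directly on genotype likelihoods,
so no hard genotype calls are needed at low coverage:

    L(k) = Π_s Σ_{gi,gj} GL_i(s,gi) · GL_j(s,gj) · Σ_m k_m · P(gi,gj | m, f_s)

with the standard Hardy–Weinberg conditional genotype-pair tables for
m = 0, 1, 2 shared alleles.  The kinship summary is π̂ = k1/2 + k2, which
halves with each degree of relatedness (0.25 for parent–offspring and
siblings, 0.125 second degree, ...).

Downstream, calls are filtered on the number of co-covered SNPs, binned
into degrees at the power-of-two π̂ thresholds, reconciled against
independent estimators, and assembled into pedigrees as connected
components over edges of degree <= 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "PairwiseRelatedness",
    "ConsensusRelationship",
    "PedigreeGraph",
    "PairKinshipModel",
    "KinshipResults",
    "estimate_relatedness",
    "filter_by_overlap",
    "classify_degree",
    "reconcile",
    "assemble_pedigrees",
    "DEGREE_LEVEL",
]

logger = logging.getLogger(__name__)

# Degree bins on the kinship-coefficient scale φ = k1/4 + k2/2 = π̂/2
# (KING convention): geometric midpoints between the expected values
# 0.5 (duplicate), 0.25 (1st), 0.125 (2nd), 0.0625 (3rd), i.e. 2^-(d+1.5).
_PHI_CUTS = {
    "duplicate": 2 ** -1.5,       # 0.3536
    "first": 2 ** -2.5,           # 0.1768
    "second": 2 ** -3.5,          # 0.0884
    "third": 2 ** -4.5,           # 0.0442
}
_PO_K0_CUT = 0.1

DEGREE_LEVEL = {
    "duplicate": 0,
    "parent-offspring": 1,
    "sibling": 1,
    "first": 1,
    "second": 2,
    "third": 3,
    "unrelated": 4,
}


@dataclass
class PairwiseRelatedness:
    id1: str
    id2: str
    k0: float
    k1: float
    k2: float
    n_snps: int
    estimator: str = "ml_gl"

    def __post_init__(self) -> None:
        k = np.array([self.k0, self.k1, self.k2])
        if np.any(k < -1e-9) or abs(k.sum() - 1.0) > 1e-6:
            raise ValueError("(k0, k1, k2) must lie on the simplex")

    @property
    def pi_hat(self) -> float:
        return self.k1 / 2 + self.k2

    @property
    def kinship_coefficient(self) -> float:
        """φ = k1/4 + k2/2; halves per degree (0.25 for 1st degree)."""
        return self.k1 / 4 + self.k2 / 2

    @property
    def pair(self) -> tuple:
        return tuple(sorted((self.id1, self.id2)))


# ---------------------------------------------------------------------------
# pair likelihood


def _pair_site_likelihoods(gl_i, gl_j, f):
    """Per-site likelihood A_m(s) of the GL pair given m shared alleles.

    Returns a (3, S) array; evaluating L(k) is then a dot product with k.
    """
    p = np.asarray(f, dtype=float)
    r = 1 - p
    g0 = np.stack([r**2, 2 * p * r, p**2], axis=1)  # HW genotype probs
    li = np.asarray(gl_i, dtype=float)
    lj = np.asarray(gl_j, dtype=float)
    ei = (li * g0).sum(axis=1)
    ej = (lj * g0).sum(axis=1)
    a0 = ei * ej
    a2 = (li * lj * g0).sum(axis=1)
    # one shared allele: P(gi, gj | 1) table expanded
    a1 = (
        li[:, 0] * lj[:, 0] * r**3
        + (li[:, 0] * lj[:, 1] + li[:, 1] * lj[:, 0]) * r**2 * p
        + li[:, 1] * lj[:, 1] * p * r
        + (li[:, 1] * lj[:, 2] + li[:, 2] * lj[:, 1]) * p**2 * r
        + li[:, 2] * lj[:, 2] * p**3
    )
    return np.stack([a0, a1, a2])


def _grid_simplex(step: float) -> np.ndarray:
    ks = []
    n = int(round(1 / step))
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k0 = i * step
            k2 = j * step
            ks.append((k0, 1 - k0 - k2, k2))
    return np.asarray(ks)


def _loglik_many(A: np.ndarray, ks: np.ndarray, chunk: int = 64) -> np.ndarray:
    out = np.empty(len(ks))
    for lo in range(0, len(ks), chunk):
        sub = ks[lo : lo + chunk]
        mix = sub @ A  # (m, S)
        out[lo : lo + chunk] = np.log(np.maximum(mix, 1e-300)).sum(axis=1)
    return out


def estimate_relatedness(
    gl_i,
    gl_j,
    freqs,
    missing_i=None,
    missing_j=None,
    id1: str = "A",
    id2: str = "B",
    grid_step: float = 0.02,
    refine: bool = True,
) -> PairwiseRelatedness:
    """ML estimate of (k0, k1, k2) for one pair.

    Sites where either individual is missing are dropped; the co-covered
    count is reported for the downstream overlap filter.  The optimum is
    located by a coarse simplex grid (``grid_step``) and refined with SLSQP.
    """
    gl_i = np.asarray(gl_i, dtype=float)
    gl_j = np.asarray(gl_j, dtype=float)
    f = np.asarray(freqs, dtype=float)
    keep = np.ones(len(f), dtype=bool)
    if missing_i is not None:
        keep &= ~np.asarray(missing_i, dtype=bool)
    if missing_j is not None:
        keep &= ~np.asarray(missing_j, dtype=bool)
    if not keep.any():
        raise ValueError(f"pair ({id1}, {id2}): no co-covered sites")
    A = _pair_site_likelihoods(gl_i[keep], gl_j[keep], f[keep])
    n_snps = int(keep.sum())

    ks = _grid_simplex(grid_step)
    lls = _loglik_many(A, ks)
    best = ks[int(np.argmax(lls))]
    if refine:
        def neg(k):
            mix = k @ A
            return -np.log(np.maximum(mix, 1e-300)).sum()

        res = minimize(
            neg,
            best,
            method="SLSQP",
            bounds=[(0, 1)] * 3,
            constraints=[{"type": "eq", "fun": lambda k: k.sum() - 1}],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if res.success and -res.fun >= lls.max() - 1e-9:
            best = np.clip(res.x, 0, None)
            best /= best.sum()
    return PairwiseRelatedness(id1, id2, float(best[0]), float(best[1]), float(best[2]), n_snps)


class PairKinshipModel:
    """Relatedness model for one pair of individuals (Model/fit interface)."""

    def __init__(self, gl_i, gl_j, freqs, missing_i=None, missing_j=None,
                 ids=("A", "B")):
        self.gl_i, self.gl_j, self.freqs = gl_i, gl_j, freqs
        self.missing_i, self.missing_j = missing_i, missing_j
        self.ids = tuple(ids)

    @classmethod
    def from_matrix(cls, glmat, freqs, id1, id2) -> "PairKinshipModel":
        gi, mi = glmat.individual(id1)
        gj, mj = glmat.individual(id2)
        return cls(gi, gj, freqs, mi, mj, ids=(id1, id2))

    def fit(self, grid_step: float = 0.02, refine: bool = True) -> "KinshipResults":
        rel = estimate_relatedness(
            self.gl_i, self.gl_j, self.freqs, self.missing_i, self.missing_j,
            id1=self.ids[0], id2=self.ids[1], grid_step=grid_step, refine=refine,
        )
        return KinshipResults(self, rel)


@dataclass
class KinshipResults:
    model: PairKinshipModel
    relatedness: PairwiseRelatedness

    @property
    def params(self) -> pd.Series:
        r = self.relatedness
        return pd.Series({"k0": r.k0, "k1": r.k1, "k2": r.k2, "pi_hat": r.pi_hat})

    @property
    def degree(self) -> str:
        return classify_degree(self.relatedness)

    def summary(self) -> str:
        r = self.relatedness
        return "\n".join(
            [
                "Pairwise relatedness (genotype-likelihood ML)",
                "=" * 45,
                f"pair:            {r.id1} - {r.id2}",
                f"co-covered SNPs: {r.n_snps}",
                f"k0, k1, k2:      {r.k0:.4f}, {r.k1:.4f}, {r.k2:.4f}",
                f"pi_hat:          {r.pi_hat:.4f}",
                f"degree class:    {self.degree}",
            ]
        )


# ---------------------------------------------------------------------------
# filtering, classification, reconciliation


def filter_by_overlap(pairs, min_snps: int = 10_000):
    """Drop pairs with fewer than ``min_snps`` co-covered SNPs.

    Pairs with exactly the threshold are retained; removals are logged.
    """
    kept, removed = [], []
    for p in pairs:
        (kept if p.n_snps >= min_snps else removed).append(p)
    for p in removed:
        logger.info(
            "overlap filter: dropping pair (%s, %s) with %d shared SNPs (< %d)",
            p.id1, p.id2, p.n_snps, min_snps,
        )
    return kept


def classify_degree(rel: PairwiseRelatedness) -> str:
    """Bin the kinship coefficient at the power-of-two thresholds.

    φ = k1/4 + k2/2 is compared against the geometric midpoints of the
    expected per-degree values (duplicate 0.5, 1st 0.25, 2nd 0.125, 3rd
    0.0625); 1st-degree calls split into parent–offspring (k0 < 0.1,
    tolerating low-coverage noise around the expected k0 = 0) vs sibling.
    """
    phi = rel.kinship_coefficient
    if phi > _PHI_CUTS["duplicate"]:
        return "duplicate"
    if phi > _PHI_CUTS["first"]:
        return "parent-offspring" if rel.k0 < _PO_K0_CUT else "sibling"
    if phi > _PHI_CUTS["second"]:
        return "second"
    if phi > _PHI_CUTS["third"]:
        return "third"
    return "unrelated"


@dataclass
class ConsensusRelationship:
    pair: tuple
    degree: str
    level: int
    supporting: list = field(default_factory=list)
    discordant: bool = False
    single_source: bool = False


def reconcile(pair, primary_degree: str, secondary_degrees: dict) -> ConsensusRelationship:
    """Merge the likelihood-based call with independent estimator calls.

    The primary call is accepted without a flag when at least half of the
    available secondary estimators agree on the degree — exactly for
    1st-degree calls, within one level for 2nd/3rd.  Otherwise the primary
    call is kept but flagged discordant.  With no secondary estimator the
    call is flagged single-source.
    """
    pair = tuple(sorted(pair))
    level = DEGREE_LEVEL[primary_degree]
    if not secondary_degrees:
        return ConsensusRelationship(pair, primary_degree, level, single_source=True)
    tolerance = 0 if level <= 1 else 1
    agree = [
        name
        for name, deg in secondary_degrees.items()
        if abs(DEGREE_LEVEL[deg] - level) <= tolerance
    ]
    discordant = len(agree) < len(secondary_degrees) / 2
    return ConsensusRelationship(pair, primary_degree, level, supporting=agree,
                                 discordant=discordant)


# ---------------------------------------------------------------------------
# pedigree assembly


@dataclass
class PedigreeGraph:
    """Typed relationship graph; components of close kin form pedigrees.

    ``graph`` holds one edge per pair of degree <= 3; ``po_dag`` orients
    parent–offspring edges older → younger where age classes allow.
    Components are sorted largest first; ``generation_depth[i]`` is
    1 + the longest directed parent–offspring path inside component i.
    """

    graph: nx.Graph
    po_dag: nx.DiGraph
    components: list
    generation_depth: list
    po_span: list = field(default_factory=list)
    distant: list = field(default_factory=list)  # (id, id) pairs beyond 3rd degree
    warnings: list = field(default_factory=list)

    def component_of(self, iid):
        for i, comp in enumerate(self.components):
            if iid in comp:
                return i
        return None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": range(len(self.components)),
                "size": [len(c) for c in self.components],
                "generation_depth": self.generation_depth,
                "po_span": self.po_span,
            }
        )


def _longest_po_chain(edges, nodes) -> int:
    """Nodes on the longest simple path through parent-offspring edges,
    ignoring orientation (exhaustive DFS; pedigree components are small)."""
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        if u in adj and v in adj:
            adj[u].add(v)
            adj[v].add(u)
    best = 1 if nodes else 0

    def dfs(node, seen):
        nonlocal best
        best = max(best, len(seen))
        for nxt in adj[node]:
            if nxt not in seen:
                dfs(nxt, seen | {nxt})

    for n in nodes:
        if adj[n]:
            dfs(n, {n})
    return best


def assemble_pedigrees(consensus, metadata: pd.DataFrame | None = None) -> PedigreeGraph:
    """Build pedigrees from consensus relationships.

    ``consensus`` is an iterable of ConsensusRelationship; ``metadata`` may
    provide ``id``, ``age_class`` (adult/nonadult/unknown) used to orient
    parent–offspring edges (adult → nonadult).  Individuals connected only
    by >3rd-degree evidence are listed under ``distant`` instead of being
    merged into components.
    """
    age = {}
    if metadata is not None:
        age = dict(zip(metadata["id"], metadata.get("age_class", "unknown")))
    g = nx.Graph()
    dag = nx.DiGraph()
    distant = []
    warnings: list = []
    for rel in sorted(consensus, key=lambda r: r.pair):
        a, b = rel.pair
        if rel.level > 3:
            distant.append(rel.pair)
            continue
        g.add_edge(a, b, degree=rel.degree, level=rel.level,
                   discordant=rel.discordant)
        if rel.degree == "parent-offspring":
            ca, cb = age.get(a, "unknown"), age.get(b, "unknown")
            if ca == "adult" and cb == "nonadult":
                dag.add_edge(a, b)
            elif ca == "nonadult" and cb == "adult":
                dag.add_edge(b, a)
            # same or unknown age classes: left unoriented
    if not nx.is_directed_acyclic_graph(dag):
        cycles = list(nx.simple_cycles(dag))
        warnings.append(f"orientation contradiction in parent-offspring edges: {cycles}")
        for cyc in cycles:
            for u, v in zip(cyc, cyc[1:] + cyc[:1]):
                if dag.has_edge(u, v):
                    dag.remove_edge(u, v)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    po_edges = [
        (u, v) for u, v, d in g.edges(data=True) if d["degree"] == "parent-offspring"
    ]
    depths, spans = [], []
    for comp in comps:
        sub = dag.subgraph(comp)
        depths.append(1 + (nx.dag_longest_path_length(sub) if sub.number_of_nodes() else 0))
        spans.append(_longest_po_chain(po_edges, comp))
    return PedigreeGraph(
        graph=g, po_dag=dag, components=[set(c) for c in comps],
        generation_depth=depths, po_span=spans, distant=distant, warnings=warnings,
    )
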
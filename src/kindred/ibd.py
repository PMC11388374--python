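"""IBD-sharing networks from pairwise segment tables.

Segments shorter than a length threshold (default 12 cM, strict) are
discarded; each surviving pair gets an adjusted π̂ edge — the summed segment
length divided by the genetic length of the genome — with known sibling
pairs forced to 0.5 (segment callers on unphased low-coverage data cannot
separate IBD2 from IBD1, so sibling sharing is systematically undercounted).
Edge weights are then min–max rescaled to [0, 1] and isolated individuals
drop out of the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "filter_segments",
    "pair_pihat",
    "pihat_table",
    "build_network",
    "network_summary",
    "read_segments",
    "write_segments",
]

#: sex-averaged autosomal genetic map length, cM
DEFAULT_GENOME_CM = 3540.0

SEGMENT_COLUMNS = ["id1", "id2", "chrom", "start_cm", "end_cm", "length_cm"]


def _validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    for col in SEGMENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"segment table missing column {col!r}")
    if len(df):
        if np.any(df.length_cm.to_numpy() <= 0):
            raise ValueError("segment lengths must be positive")
        if np.any(
            np.abs((df.end_cm - df.start_cm - df.length_cm).to_numpy()) > 1e-6
        ):
            raise ValueError("length must equal end - start")
        if np.any(df.id1.to_numpy() == df.id2.to_numpy()):
            raise ValueError("segment ids must be distinct")
    return df


def filter_segments(segments: pd.DataFrame, min_cm: float = 12.0) -> pd.DataFrame:
    """Keep segments strictly longer than ``min_cm``."""
    segments = _validate_segments(segments)
    return segments[segments.length_cm > min_cm].reset_index(drop=True)


def pair_pihat(
    segments_for_pair: pd.DataFrame,
    genome_total_cm: float = DEFAULT_GENOME_CM,
    known_sibling: bool = False,
) -> float:
    """Adjusted π̂ for one pair: Σ lengths / genome length, siblings 0.5."""
    if genome_total_cm <= 0:
        raise ValueError("genome_total_cm must be positive")
    if known_sibling:
        return 0.5
    pairs = set(zip(segments_for_pair.id1, segments_for_pair.id2))
    if len(pairs) > 1:
        raise ValueError(f"segments for multiple pairs mixed in: {sorted(pairs)}")
    return float(segments_for_pair.length_cm.sum() / genome_total_cm)


def pihat_table(
    segments: pd.DataFrame,
    genome_total_cm: float = DEFAULT_GENOME_CM,
    siblings=(),
) -> pd.DataFrame:
    """Adjusted π̂ per pair over a (filtered) segment table.

    ``siblings`` is a collection of known sibling id pairs whose π̂ is set
    to 0.5 regardless of the called segment sum.  Pairs with no surviving
    segments get no row (hence no edge downstream).
    """
    segments = _validate_segments(segments)
    sib = {tuple(sorted(p)) for p in siblings}
    if len(segments) == 0:
        rows = []
    else:
        key = segments.apply(lambda r: tuple(sorted((r.id1, r.id2))), axis=1)
        sums = segments.groupby(key).length_cm.sum()
        rows = [
            {
                "id1": p[0],
                "id2": p[1],
                "raw_pihat": 0.5 if p in sib else s / genome_total_cm,
            }
            for p, s in sums.items()
        ]
    return pd.DataFrame(rows, columns=["id1", "id2", "raw_pihat"])


def build_network(pair_pihats: pd.DataFrame, annotations: pd.DataFrame | None = None) -> nx.Graph:
    """Weighted undirected IBD network.

    Raw π̂ weights are min–max rescaled to [0, 1]; if all weights coincide
    (including the single-edge case) every edge gets weight 1.  Only
    individuals with at least one edge appear.  ``annotations`` (indexed or
    keyed by ``id``) attach as node attributes.
    """
    if len(pair_pihats) == 0:
        raise ValueError("no edges: empty pair table")
    raw = pair_pihats.raw_pihat.to_numpy(dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        weight = (raw - lo) / (hi - lo)
    else:
        weight = np.ones_like(raw)
    g = nx.Graph()
    for (_, row), w, r in zip(pair_pihats.iterrows(), weight, raw):
        if row.id1 == row.id2:
            raise ValueError("self-edge in pair table")
        g.add_edge(row.id1, row.id2, raw_pihat=float(r), weight=float(w))
    if annotations is not None:
        ann = annotations.set_index("id") if "id" in annotations.columns else annotations
        for node in g.nodes:
            if node in ann.index:
                g.nodes[node].update(ann.loc[node].to_dict())
    return g


def network_summary(net: nx.Graph) -> dict:
    """Node count, edge count and average degree (2E/N, undirected)."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    return {
        "nodes": n,
        "edges": e,
        "average_degree": (2 * e / n) if n else 0.0,
    }


def write_segments(segments: pd.DataFrame, path, header_lines=None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        _validate_segments(segments)[SEGMENT_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    return _validate_segments(pd.read_csv(path, sep="\t", comment="#"))
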
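"""End-to-end synthetic-to-report workflow.

Stages run in order — simulate → ancestry → kinship → ibd-net → isotope →
mortuary → report — with every stage reading its inputs from, and writing
its outputs to, the run directory, so a run is restartable per stage from
the on-disk intermediates.  All outputs are plain text (beagle GL, TSV/CSV,
JSON) and carry a header with the package version, the seed and a hash of
the configuration; a rerun with an identical configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import AdmixtureModel
from .genome import GeneticMap
from .gl import GLMatrix, ReferencePanel, read_beagle, write_beagle
from .ibd import build_network, filter_segments, network_summary, pihat_table, read_segments, write_segments
from .isotope import classify_locality, derive_locality_ranges, diet_group_compare, qc_table
from .kinship import (
    DEGREE_LEVEL,
    assemble_pedigrees,
    classify_degree,
    estimate_relatedness,
    filter_by_overlap,
    reconcile,
)
from .simulate import (
    IsotopeParams,
    PedigreeSpec,
    branching_pedigree,
    emit_genotype_likelihoods,
    simulate_grave_goods,
    simulate_isotopes,
    simulate_pedigree_genotypes,
    simulate_reference_panel,
)
from .stats import cramers_v, permutation_test

logger = logging.getLogger(__name__)

STAGES = ["simulate", "ancestry", "kinship", "ibd-net", "isotope", "mortuary", "report"]


@dataclass
class PipelineConfig:
    """Thresholds and sizes for one synthetic community run.

    Defaults follow the analysis conventions this pipeline reproduces:
    10,000 minimum shared SNPs for kinship calls, a strict 12 cM IBD
    length floor, 10 Mb bootstrap blocks and 50 EM restarts.
    """

    seed: int = 0
    outdir: str = "kindred_run"
    n_populations: int = 4
    n_sites: int = 20_000
    fst: float = 0.1
    n_chrom: int = 6
    chrom_length_bp: int = 100_000_000
    depth: float = 1.4
    base_error: float = 0.005
    n_unrelated: int = 21
    restarts: int = 50
    bootstrap_reps: int = 20
    bootstrap_restarts: int = 2
    block_bp: int = 10_000_000
    min_snps: int = 10_000
    min_cm: float = 12.0
    genome_cm: float | None = None  # default: simulated map length
    permutations: int = 10_000
    grid_step: float = 0.02

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Flat ``key: value`` text config; keyword overrides win."""
        vals: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key: value'")
            key, val = (x.strip() for x in line.split(":", 1))
            vals[key] = val
        cfg = cls()
        for key, val in vals.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            typ = type(cur) if cur is not None else float
            setattr(cfg, key, typ(val) if typ is not bool else val.lower() == "true")
        for key, val in overrides.items():
            if val is not None:
                setattr(cfg, key, val)
        return cfg

    def config_hash(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_lines(self) -> list:
        return [
            f"kindred v{__version__}",
            f"seed={self.seed}",
            f"config={self.config_hash()}",
        ]


def _rng(cfg: PipelineConfig, stage: int):
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, sep=",") -> None:
    with open(path, "w") as fh:
        for line in cfg.header_lines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False, float_format="%.10g")


def _np_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(obj, path: Path, cfg: PipelineConfig) -> None:
    payload = {"meta": {"version": __version__, "seed": cfg.seed, "config": cfg.config_hash()}}
    payload.update(obj)
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=_np_default) + "\n"
    )


# ---------------------------------------------------------------------------
# cohort layout


def default_cohort(cfg: PipelineConfig) -> tuple[PedigreeSpec, dict]:
    """The standard synthetic community.

    A five-generation 'founding family' with predominantly one ancestry,
    a small second family of contrasting ancestry, and a set of unrelated
    individuals with mixed ancestry vectors.  Returns the pedigree spec and
    a metadata dict (elite ids, age classes, sexes, locality, diet groups).
    """
    K = cfg.n_populations
    rng = _rng(cfg, 99)
    q_elite = np.full(K, 0.05)
    q_elite[0] = 1 - 0.05 * (K - 1)
    q_south = np.full(K, 0.05)
    q_south[1] = 1 - 0.05 * (K - 1)

    elite = branching_pedigree(q_elite, n_generations=5)
    founders = dict(elite.founders)
    children = list(elite.children)
    # contrasting small family: two parents, two children
    founders["B_F"] = q_south
    founders["B_M"] = q_south
    children.append(("B_C1", "B_F", "B_M"))
    children.append(("B_C2", "B_F", "B_M"))
    # unrelated singletons with mixed ancestry
    for i in range(cfg.n_unrelated):
        founders[f"U{i + 1:02d}"] = rng.dirichlet(np.ones(K))
    spec = PedigreeSpec(founders=founders, children=children)

    elite_ids = set(elite.members)
    members = spec.members
    age = {
        m: ("nonadult" if m.startswith("G5_") or m == "B_C2" else "adult") for m in members
    }
    sex = {m: ("M" if i % 2 == 0 else "F") for i, m in enumerate(sorted(members))}
    nonlocal_ids = {"G1_A", "G1_B", "G2_S"}
    meta = {
        "elite_ids": elite_ids,
        "age_class": age,
        "sex": sex,
        "nonlocal_ids": nonlocal_ids,
        "diet_group": {m: ("elite" if m in elite_ids else "rest") for m in members},
    }
    return spec, meta


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gmap = GeneticMap.regular(
        cfg.n_sites, n_chrom=cfg.n_chrom, chrom_length_bp=cfg.chrom_length_bp
    )
    panel = simulate_reference_panel(cfg.n_populations, cfg.n_sites, cfg.fst,
                                     seed=_rng(cfg, 1), gmap=gmap)
    spec, meta = default_cohort(cfg)
    haps, truth = simulate_pedigree_genotypes(panel, spec, seed=_rng(cfg, 2))
    glmat = emit_genotype_likelihoods(haps, gmap, cfg.depth, cfg.base_error, seed=_rng(cfg, 3))

    members = spec.members
    member_df = pd.DataFrame(
        {
            "id": members,
            "age_class": [meta["age_class"][m] for m in members],
            "sex": [meta["sex"][m] for m in members],
            "diet_group": [meta["diet_group"][m] for m in members],
            "local": [m not in meta["nonlocal_ids"] for m in members],
        }
    )
    iso_params = IsotopeParams(diet_offsets={"elite": (1.2, 0.5)}, qc_fail_fraction=0.1)
    iso_records, iso_truth = simulate_isotopes(member_df, iso_params, seed=_rng(cfg, 4))
    goods = simulate_grave_goods(members, meta["elite_ids"], seed=_rng(cfg, 5))

    write_beagle(glmat, out / "gl.beagle", header_lines=cfg.header_lines())
    panel.to_tsv(out / "panel.tsv", header_lines=cfg.header_lines())
    segs = truth.ibd_segments.copy()
    write_segments(
        segs[["id1", "id2", "chrom", "start_cm", "end_cm", "length_cm"]],
        out / "segments.tsv", header_lines=cfg.header_lines(),
    )
    _write_csv(iso_records, out / "isotopes.csv", cfg)
    _write_csv(member_df.merge(goods[["id", "weapons", "belt_set"]], on="id"),
               out / "metadata.csv", cfg)
    truth_json = {
        "total_cm": truth.total_cm,
        "admixture": {m: list(np.round(truth.admixture[m], 10)) for m in members},
        "elite_ids": sorted(meta["elite_ids"]),
        "nonlocal_ids": sorted(meta["nonlocal_ids"]),
        "k_coefficients": {f"{a}|{b}": list(np.round(v, 10)) for (a, b), v in truth.k_coefficients.items()},
        "true_degree": {
            f"{a}|{b}": spec.relationship_degree(a, b)
            for (a, b) in truth.k_coefficients
            if spec.relationship_degree(a, b) is not None
        },
        "isotope_truth": iso_truth.to_dict(orient="list"),
    }
    _write_json(truth_json, out / "truth.json", cfg)


def _load_inputs(cfg: PipelineConfig):
    out = Path(cfg.outdir)
    glmat = read_beagle(out / "gl.beagle")
    panel = ReferencePanel.from_tsv(out / "panel.tsv")
    return glmat, panel


def stage_ancestry(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    glmat, panel = _load_inputs(cfg)
    rows, boot_rows = [], []
    for i, iid in enumerate(glmat.ids):
        model = AdmixtureModel.from_matrix(glmat, panel, iid)
        res = model.fit(restarts=cfg.restarts, seed=np.random.SeedSequence([cfg.seed, 10, i]))
        row = {"id": iid, **{p: res.params[p] for p in panel.populations},
               "loglik": res.llf, "n_sites": res.nobs}
        rows.append(row)
        if cfg.bootstrap_reps >= 2:
            boot = res.bootstrap(B=cfg.bootstrap_reps, block_bp=cfg.block_bp,
                                 seed=np.random.SeedSequence([cfg.seed, 11, i]),
                                 restarts=cfg.bootstrap_restarts)
            ci = boot.ci
            for p in panel.populations:
                boot_rows.append({
                    "id": iid, "component": p, "sd": boot.sd[p],
                    "ci_low": ci.loc[p, "low"], "ci_high": ci.loc[p, "high"],
                })
    _write_csv(pd.DataFrame(rows), out / "ancestry.tsv", cfg, sep="\t")
    if boot_rows:
        _write_csv(pd.DataFrame(boot_rows), out / "bootstrap.tsv", cfg, sep="\t")


def stage_kinship(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    glmat, panel = _load_inputs(cfg)
    freqs = panel.freqs.mean(axis=1)  # pooled panel frequencies
    segments = read_segments(out / "segments.tsv")
    total_cm = cfg.genome_cm or float(glmat.gmap.total_cm)

    # secondary estimator: degree bins from IBD-segment sharing
    surviving = filter_segments(segments, cfg.min_cm)
    ibd_pi = pihat_table(surviving, total_cm)
    ibd_degree = {
        tuple(sorted((r.id1, r.id2))): _degree_from_sharing(r.raw_pihat)
        for r in ibd_pi.itertuples()
    }

    ids = glmat.ids
    rels = []
    for i in range(len(ids)):
        gi, mi = glmat.individual(ids[i])
        for j in range(i + 1, len(ids)):
            gj, mj = glmat.individual(ids[j])
            rels.append(
                estimate_relatedness(gi, gj, freqs, mi, mj, id1=ids[i], id2=ids[j],
                                     grid_step=cfg.grid_step)
            )
    kept = filter_by_overlap(rels, min_snps=cfg.min_snps)
    consensus = []
    pair_rows = []
    for rel in kept:
        degree = classify_degree(rel)
        secondary = {}
        sec = ibd_degree.get(rel.pair)
        if sec is not None:
            secondary["ibd"] = sec
        cons = reconcile(rel.pair, degree, secondary)
        consensus.append(cons)
        pair_rows.append({
            "id1": rel.pair[0], "id2": rel.pair[1],
            "k0": rel.k0, "k1": rel.k1, "k2": rel.k2,
            "pi_hat": rel.pi_hat, "n_snps": rel.n_snps, "degree": degree,
            "discordant": cons.discordant, "single_source": cons.single_source,
        })
    meta = pd.read_csv(out / "metadata.csv", comment="#")
    ped = assemble_pedigrees(consensus, meta)
    _write_csv(pd.DataFrame(pair_rows), out / "pairs.tsv", cfg, sep="\t")
    edges = pd.DataFrame(
        [
            {"id1": u, "id2": v, "degree": d["degree"], "discordant": d["discordant"]}
            for u, v, d in sorted(ped.graph.edges(data=True))
        ]
    )
    _write_csv(edges, out / "pedigree_edges.csv", cfg)
    _write_csv(ped.summary_frame().assign(
        members=["|".join(sorted(c)) for c in ped.components]
    ), out / "components.csv", cfg)


def _degree_from_sharing(share: float) -> str:
    """Degree bin from the genome fraction covered by IBD segments.

    Segment callers on unphased data merge IBD1/IBD2, so the sharing
    fraction expects ~1.0 for parent-offspring, 0.75 siblings, 0.5 second
    degree, 0.25 third; cuts at the geometric midpoints.
    """
    if share > (0.75 * 0.5) ** 0.5:     # 0.612
        return "first"
    if share > (0.5 * 0.25) ** 0.5:     # 0.354
        return "second"
    if share > (0.25 * 0.125) ** 0.5:   # 0.177
        return "third"
    return "unrelated"


def stage_ibd_net(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    segments = read_segments(out / "segments.tsv")
    glmat = read_beagle(out / "gl.beagle")
    total_cm = cfg.genome_cm or float(glmat.gmap.total_cm)
    surviving = filter_segments(segments, cfg.min_cm)
    siblings = set()
    pairs_path = out / "pairs.tsv"
    if pairs_path.exists():
        pairs = pd.read_csv(pairs_path, sep="\t", comment="#")
        siblings = {
            tuple(sorted((r.id1, r.id2)))
            for r in pairs.itertuples()
            if r.degree == "sibling"
        }
    pihats = pihat_table(surviving, total_cm, siblings=siblings)
    if len(pihats) == 0:
        _write_json({"network": {"nodes": 0, "edges": 0, "average_degree": 0.0}},
                    out / "network.json", cfg)
        _write_csv(pd.DataFrame(columns=["id1", "id2", "raw_pihat", "weight"]),
                   out / "ibd_edges.csv", cfg)
        return
    net = build_network(pihats)
    summary = network_summary(net)
    edge_rows = [
        {"id1": min(u, v), "id2": max(u, v), "raw_pihat": d["raw_pihat"], "weight": d["weight"]}
        for u, v, d in net.edges(data=True)
    ]
    edge_df = pd.DataFrame(sorted(edge_rows, key=lambda r: (r["id1"], r["id2"])))
    node_df = pd.DataFrame(
        [{"id": n, "degree": int(net.degree(n))} for n in net.nodes]
    ).sort_values("id", ignore_index=True)
    _write_csv(edge_df, out / "ibd_edges.csv", cfg)
    _write_csv(node_df, out / "ibd_nodes.csv", cfg)
    _write_json({"network": summary}, out / "network.json", cfg)


def stage_isotope(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    records = pd.read_csv(out / "isotopes.csv", comment="#")
    ranges = derive_locality_ranges(records)
    records = qc_table(records)
    records["locality"] = [classify_locality(v, ranges) for v in records["sr_ratio"]]
    comp_path = out / "components.csv"
    groups: set = set()
    if comp_path.exists():
        comps = pd.read_csv(comp_path, comment="#")
        if len(comps):
            groups = set(comps.iloc[0]["members"].split("|"))
    in_group = records["id"].isin(groups).to_numpy()
    comparison = None
    qc_ok = records["qc_pass"].to_numpy()
    if in_group[qc_ok].sum() >= 2 and (~in_group[qc_ok]).sum() >= 2:
        comparison = diet_group_compare(
            records, in_group, "d13C", B=cfg.permutations,
            seed=np.random.SeedSequence([cfg.seed, 40]),
        )
    _write_csv(records, out / "locality.csv", cfg)
    _write_json(
        {
            "ranges": {
                "center": list(ranges.center), "wider": list(ranges.wider),
                "n_nonadults": ranges.n_nonadults, "n_humans": ranges.n_humans,
                "flags": ranges.flags,
            },
            "diet_comparison": comparison,
        },
        out / "diet.json", cfg,
    )


def stage_mortuary(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    meta = pd.read_csv(out / "metadata.csv", comment="#")
    comps = pd.read_csv(out / "components.csv", comment="#")
    group = set(comps.iloc[0]["members"].split("|")) if len(comps) else set()
    in_group = meta["id"].isin(group)
    results = {}
    for artifact in ("weapons", "belt_set"):
        has = meta[artifact].astype(bool)
        table = np.array(
            [
                [int((in_group & has).sum()), int((in_group & ~has).sum())],
                [int((~in_group & has).sum()), int((~in_group & ~has).sum())],
            ]
        )
        try:
            v = cramers_v(table)
        except ValueError:
            v = None
        results[artifact] = {"table": table.tolist(), "cramers_v": v}
    _write_json({"mortuary": results}, out / "mortuary.json", cfg)


def stage_report(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    ancestry = pd.read_csv(out / "ancestry.tsv", sep="\t", comment="#")
    comps = pd.read_csv(out / "components.csv", comment="#")
    network = json.loads((out / "network.json").read_text())
    diet = json.loads((out / "diet.json").read_text())
    mortuary = json.loads((out / "mortuary.json").read_text())
    locality = pd.read_csv(out / "locality.csv", comment="#")
    boot_path = out / "bootstrap.tsv"
    intervals: dict = {}
    if boot_path.exists():
        boot = pd.read_csv(boot_path, sep="\t", comment="#")
        for r in boot.to_dict(orient="records"):
            intervals.setdefault(r["id"], {})[r["component"]] = {
                "sd": r["sd"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
            }
    report = {
        "ancestry": {
            r["id"]: {
                **{k: r[k] for k in ancestry.columns if k != "id"},
                "intervals": intervals.get(r["id"], {}),
            }
            for r in ancestry.to_dict(orient="records")
        },
        "pedigrees": comps.to_dict(orient="records"),
        "ibd_network": network["network"],
        "locality_classes": dict(zip(locality["id"], locality["locality"])),
        "collagen_qc": dict(zip(locality["id"], locality["qc_pass"].astype(bool).tolist())),
        "diet_comparison": diet["diet_comparison"],
        "sr_ranges": diet["ranges"],
        "mortuary": mortuary["mortuary"],
    }
    _write_json(report, out / "report.json", cfg)
    return json.loads((out / "report.json").read_text())


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "ancestry": stage_ancestry,
    "kinship": stage_kinship,
    "ibd-net": stage_ibd_net,
    "isotope": stage_isotope,
    "mortuary": stage_mortuary,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the named stages in order (all by default); returns the report.

    A failing stage aborts the run with the stage name in the exception.
    """
    stages = list(stages or STAGES)
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    report = None
    for name in STAGES:
        if name not in stages:
            continue
        logger.info("pipeline stage: %s", name)
        try:
            result = _STAGE_FUNCS[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "report":
            report = result
    return report if report is not None else {}
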
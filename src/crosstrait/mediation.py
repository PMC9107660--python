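"""Mediation pipeline: orchestrates the full analysis and applies the
joint-significance rule over the MR estimates.

The causal ordering is fixed: X (birthweight) -> M1 (age at menarche)
-> M2 (age at menopause) -> Y (breast cancer).  Edge assignments:

* X -> M1: univariable IVW;
* X -> M2 and M1 -> M2: multivariable IVW with both upstream traits;
* M1 -> Y and M2 -> Y: multivariable IVW adjusting for all upstream
  traits;
* X -> Y: univariable IVW (total effect).

A path exerts mediation iff every constituent edge is individually
significant at alpha — the joint-significance rule, deliberately without
multiple-testing correction across edges.  No formal indirect-effect
estimator (product/difference, Sobel) is computed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import ldsc as _ldsc
from . import mr as _mr
from . import pleiotropy as _pleio
from .genes import gene_tests, genomic_control
from .ldref import LDReference, load_ld_reference
from .simulate import (ChainConfig, ChainData, SimulationConfig,
                       plant_pleiotropic_genes, simulate_bw_instrument_panel,
                       simulate_causal_chain, simulate_fetal_maternal,
                       simulate_ld_reference, simulate_paired_sumstats)
from .sumstats import (GeneAnnotation, SumStats, exclude_mhc, harmonize_pair,
                       qc_sumstats, read_gene_annotation, read_sumstats)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class Edge:
    source: str
    target: str
    beta: float
    se: float
    pval: float
    adjusted_for: list[str] = field(default_factory=list)
    significant: bool = False
    method: str = "IVW"


@dataclass
class MediationPath:
    nodes: list[str]
    verdict: bool | None  # None = undetermined (missing edge estimate)


@dataclass
class MediationGraph:
    nodes: list[str]
    edges: list[Edge]
    paths: list[MediationPath] = field(default_factory=list)

    def edge(self, source: str, target: str) -> Edge | None:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        return None

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "edges": [dataclasses.asdict(e) for e in self.edges],
            "paths": [{"nodes": p.nodes, "verdict": p.verdict}
                      for p in self.paths],
        }


def joint_significance(edges: list[Edge | None], alpha: float = 0.05,
                       ) -> bool | None:
    """Mediation verdict for a path: True iff every edge p-value is below
    ``alpha``; None (undetermined) when an edge estimate is missing."""
    for e in edges:
        if e is None or not np.isfinite(e.pval):
            return None
    return all(e.pval < alpha for e in edges)


# ----------------------------------------------------------------------
# chain MR analysis
# ----------------------------------------------------------------------

def _edge_from_estimate(est: _mr.MREstimate, source: str, target: str,
                        alpha: float, adjusted_for=None) -> Edge:
    return Edge(source=source, target=target, beta=est.beta, se=est.se,
                pval=est.pval, adjusted_for=list(adjusted_for or []),
                significant=bool(est.pval < alpha), method=est.method)


def chain_mediation_analysis(x: SumStats, m1: SumStats, m2: SumStats,
                             y: SumStats, alpha: float = 0.05,
                             bw_p_thresh: float = _mr.BW_P_THRESHOLD,
                             p_thresh: float = _mr.CLUMP_P,
                             ld: LDReference | None = None,
                             clump_r2: float = _mr.CLUMP_R2,
                             sensitivity: bool = True,
                             seed: int = 0,
                             ) -> tuple[MediationGraph, pd.DataFrame]:
    """Run the MR edge suite over the four chain traits and assemble the
    mediation graph.

    Instruments per exposure are genome-wide-significant SNPs for that
    exposure (birthweight uses its dedicated threshold), LD-clumped when a
    reference is supplied.  Returns the graph and a tidy table of all MR
    estimates (primary edges plus sensitivity analyses).
    """

    def select(s: SumStats, thresh: float) -> list[str]:
        if ld is not None:
            return _mr.clump_instruments(s, ld, p_thresh=thresh,
                                         r2_thresh=clump_r2)
        d = s.data[s.data["pval"] <= thresh]
        return list(d.sort_values(["pval", "rsid"], kind="stable")["rsid"])

    inst_x = select(x, bw_p_thresh)
    inst_m1 = select(m1, p_thresh)
    inst_m2 = select(m2, p_thresh)
    if len(inst_x) < 3 or len(inst_m1) < 3 or len(inst_m2) < 3:
        raise PipelineError(
            f"too few instruments (X={len(inst_x)}, M1={len(inst_m1)}, "
            f"M2={len(inst_m2)})")

    names = {"x": x.trait_label, "m1": m1.trait_label,
             "m2": m2.trait_label, "y": y.trait_label}
    rows = []
    edges: list[Edge] = []

    def record(est, source, target, adjusted=()):
        rows.append({"exposure": source, "outcome": target,
                     "method": est.method, "beta": est.beta, "se": est.se,
                     "pval": est.pval, "n_instruments": est.n_instruments,
                     "adjusted_for": ",".join(adjusted), **{
                         k: v for k, v in est.extras.items()
                         if np.isscalar(v)}})

    # univariable edges: X -> M1 and X -> Y (total effect)
    for target_s, target_key in ((m1, "m1"), (y, "y")):
        inst = _mr.make_instrument_set(x, target_s, inst_x)
        est = _mr.ivw(inst)
        edges.append(_edge_from_estimate(est, names["x"], names[target_key],
                                         alpha))
        record(est, names["x"], names[target_key])
        if sensitivity and inst.n_instruments >= 4:
            for fn in (_mr.mr_egger, _mr.max_likelihood):
                sens = fn(inst)
                record(sens, names["x"], names[target_key])
            wm = _mr.weighted_median(inst, seed=seed)
            record(wm, names["x"], names[target_key])
            presso = _mr.mr_presso(inst, seed=seed)
            rec = presso.corrected
            record(_mr.MREstimate(
                method="PRESSO_corrected", beta=rec.beta, se=rec.se,
                pval=rec.pval, n_instruments=rec.n_instruments,
                extras={"global_p": presso.global_p,
                        "n_outliers": len(presso.outlier_rsids)}),
                names["x"], names[target_key])

    # MVMR of M2 on (X, M1)
    mv = _mr.make_mv_instrument_set([x, m1], m2,
                                    sorted(set(inst_x) | set(inst_m1)))
    for est in _mr.mvmr_ivw(mv):
        src = est.exposure
        adj = est.extras.get("adjusted_for", [])
        edges.append(_edge_from_estimate(est, src, names["m2"], alpha, adj))
        record(est, src, names["m2"], adj)

    # MVMR of Y on (X, M1, M2)
    mv3 = _mr.make_mv_instrument_set(
        [x, m1, m2], y, sorted(set(inst_x) | set(inst_m1) | set(inst_m2)))
    for est in _mr.mvmr_ivw(mv3):
        if est.exposure == names["x"]:
            continue  # the X -> Y edge reported is the univariable total
        adj = est.extras.get("adjusted_for", [])
        edges.append(_edge_from_estimate(est, est.exposure, names["y"],
                                         alpha, adj))
        record(est, est.exposure, names["y"], adj)

    graph = MediationGraph(nodes=[names[k] for k in ("x", "m1", "m2", "y")],
                           edges=edges)
    e_xm1 = graph.edge(names["x"], names["m1"])
    e_m1m2 = graph.edge(names["m1"], names["m2"])
    e_m2y = graph.edge(names["m2"], names["y"])
    e_xm2 = graph.edge(names["x"], names["m2"])
    e_m1y = graph.edge(names["m1"], names["y"])
    graph.paths = [
        MediationPath([names["x"], names["m1"], names["m2"], names["y"]],
                      joint_significance([e_xm1, e_m1m2, e_m2y], alpha)),
        MediationPath([names["x"], names["m1"], names["y"]],
                      joint_significance([e_xm1, e_m1y], alpha)),
        MediationPath([names["x"], names["m2"], names["y"]],
                      joint_significance([e_xm2, e_m2y], alpha)),
    ]
    return graph, pd.DataFrame(rows)


def render_effect_graph(g: MediationGraph, dot_path=None, fig_path=None,
                        ) -> str:
    """Serialize the effect graph: solid edges are significant, dashed are
    not.  Returns the DOT text; optionally writes it and a matplotlib
    rendering."""
    lines = ["digraph mediation {", "  rankdir=LR;"]
    for n in g.nodes:
        lines.append(f'  "{n}";')
    for e in g.edges:
        style = "solid" if e.significant else "dashed"
        label = f"b={e.beta:.3f}, P={e.pval:.3g}"
        if e.adjusted_for:
            label += " (adj)"
        lines.append(f'  "{e.source}" -> "{e.target}" '
                     f'[style={style}, label="{label}"];')
    lines.append("}")
    dot = "\n".join(lines)
    if dot_path is not None:
        with open(dot_path, "w") as fh:
            fh.write(dot + "\n")
    if fig_path is not None:
        _render_matplotlib(g, fig_path)
    return dot


def _render_matplotlib(g: MediationGraph, fig_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(g.nodes)
    xs = np.linspace(0, 1, k)
    ys = [0.1 if i % 2 else 0.9 for i in range(k)]
    pos = {n: (xs[i], ys[i]) for i, n in enumerate(g.nodes)}
    fig, ax = plt.subplots(figsize=(8, 4))
    for n, (px, py) in pos.items():
        ax.annotate(n, (px, py), ha="center", va="center",
                    bbox=dict(boxstyle="round", fc="lightsteelblue"))
    for e in g.edges:
        if e.source not in pos or e.target not in pos:
            continue
        p0, p1 = np.array(pos[e.source]), np.array(pos[e.target])
        d = p1 - p0
        p0s = p0 + 0.12 * d
        p1s = p1 - 0.12 * d
        ax.annotate(
            "", xy=p1s, xytext=p0s,
            arrowprops=dict(arrowstyle="->",
                            linestyle="-" if e.significant else "--",
                            color="black" if e.significant else "gray"))
        mid = (p0s + p1s) / 2
        ax.text(mid[0], mid[1] + 0.03, f"{e.beta:.3f} (P={e.pval:.2g})",
                fontsize=7, ha="center")
    ax.set_axis_off()
    fig.savefig(fig_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis.

    When a stage's input files are not supplied, synthetic data with the
    module defaults are generated (seeded), so the pipeline is exercisable
    without external data.
    """

    out_dir: str = "crosstrait_out"
    seed: int = 0
    alpha: float = 0.05
    fdr: float = 0.05
    bw_p_thresh: float = _mr.BW_P_THRESHOLD
    p_thresh: float = _mr.CLUMP_P
    run_ldsc: bool = True
    run_genes: bool = True
    run_mr: bool = True
    exclude_mhc_region: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    chain: ChainConfig = field(default_factory=ChainConfig)
    #: genetic correlation used for the synthetic maternal-vs-outcome pair
    rg_maternal: float = -0.25
    n_genes: int = 200
    snps_per_gene: int = 10
    frac_shared_genes: float = 0.05
    #: optional file inputs: keys fetal, maternal, outcome, menarche,
    #: menopause (canonical sumstats dialect), ld_dir, genes_bed, snp_map
    files: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        chain = ChainConfig(**raw.pop("chain", {}))
        return cls(sim=sim, chain=chain, **raw)


def _window_gene_annotation(ld: LDReference, n_genes: int,
                            snps_per_gene: int) -> list[GeneAnnotation]:
    """Genes as consecutive same-chromosome SNP windows of the LD panel."""
    tab = ld.snp_table()
    genes = []
    gid = 0
    for chrom, grp in tab.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        for i in range(0, len(grp) - snps_per_gene + 1, snps_per_gene):
            if gid >= n_genes:
                return genes
            sub = grp.iloc[i:i + snps_per_gene]
            gid += 1
            genes.append(GeneAnnotation(
                gene_id=f"G{gid:04d}", chrom=int(chrom),
                start=int(sub["pos"].min()), end=int(sub["pos"].max()),
                snp_ids=list(sub["rsid"])))
    return genes


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Execute QC -> harmonization -> LDSC -> gene tests -> pleiotropy ->
    MR suite -> mediation, writing one table per stage plus a JSON summary
    and the effect-graph files to ``cfg.out_dir``.  Returns the summary
    dict.  Any stage failure raises a stage-named :class:`PipelineError`
    (partial outputs are preserved on disk)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    rngs = {name: np.random.default_rng(s) for name, s in zip(
        ("ldsc_f", "ldsc_m", "genes_f", "genes_m", "chain", "panel"),
        root.spawn(6))}
    summary: dict = {"seed": cfg.seed, "alpha": cfg.alpha, "fdr": cfg.fdr}

    ld = None
    if "ld_dir" in cfg.files:
        ld = load_ld_reference(cfg.files["ld_dir"])
    elif cfg.run_ldsc or cfg.run_genes:
        ld = simulate_ld_reference(cfg.sim.m_snps, cfg.sim.n_blocks,
                                   cfg.sim.block_rho)

    # ---------------- LDSC stage ----------------
    if cfg.run_ldsc:
        try:
            ell = _ldsc.compute_ld_scores(ld)
            pairs = {}
            if {"fetal", "outcome"} <= set(cfg.files):
                pairs["fetal"] = (read_sumstats(cfg.files["fetal"]),
                                  read_sumstats(cfg.files["outcome"]))
            else:
                pairs["fetal"] = simulate_paired_sumstats(
                    ld, cfg.sim, rngs["ldsc_f"])
            if {"maternal", "outcome"} <= set(cfg.files):
                pairs["maternal"] = (read_sumstats(cfg.files["maternal"]),
                                     read_sumstats(cfg.files["outcome"]))
            else:
                mcfg = dataclasses.replace(cfg.sim, rg_true=cfg.rg_maternal)
                pairs["maternal"] = simulate_paired_sumstats(
                    ld, mcfg, rngs["ldsc_m"])
            fits, by_chrom = [], []
            for key, (s1, s2) in pairs.items():
                s1, _ = qc_sumstats(s1)
                s2, _ = qc_sumstats(s2)
                if cfg.exclude_mhc_region:
                    s1, s2 = exclude_mhc(s1), exclude_mhc(s2)
                s1h, s2h = harmonize_pair(s1, s2)
                fit = _ldsc.ldsc_rg(s1h, s2h, ell)
                fits.append({"pair": key, **dataclasses.asdict(fit)})
                bc = _ldsc.ldsc_rg_by_chromosome(s1h, s2h, ell)
                bc.insert(0, "pair", key)
                by_chrom.append(bc)
            pd.DataFrame(fits).to_csv(
                os.path.join(cfg.out_dir, "ldsc.tsv"), sep="\t", index=False)
            pd.concat(by_chrom).to_csv(
                os.path.join(cfg.out_dir, "ldsc_by_chrom.tsv"),
                sep="\t", index=False)
            summary["ldsc"] = {f["pair"]: {"rg": f["rg"], "pval": f["pval_rg"]}
                               for f in fits}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"LDSC stage failed: {exc}") from exc

    # ---------------- gene / pleiotropy stage ----------------
    if cfg.run_genes:
        try:
            if "genes_bed" in cfg.files:
                genes = read_gene_annotation(cfg.files["genes_bed"],
                                             cfg.files.get("snp_map"))
            else:
                genes = _window_gene_annotation(ld, cfg.n_genes,
                                                cfg.snps_per_gene)
            pleio_sets = {}
            for key, sign in (("fetal", +1), ("maternal", -1)):
                rng = rngs["genes_f" if key == "fetal" else "genes_m"]
                planted = plant_pleiotropic_genes(
                    genes, cfg.frac_shared_genes, sign, cfg.sim, rng)
                s1, s2 = planted.to_observed_sumstats(
                    ld, cfg.sim.n1, cfg.sim.n2, rng)
                res1 = gene_tests(s1, ld, genes)
                res2 = gene_tests(s2, ld, genes)
                res1, lam1 = genomic_control(res1)
                res2, lam2 = genomic_control(res2)
                tab1 = pd.DataFrame([dataclasses.asdict(r) for r in res1])
                tab2 = pd.DataFrame([dataclasses.asdict(r) for r in res2])
                tab1.to_csv(os.path.join(
                    cfg.out_dir, f"genes_{key}.tsv"), sep="\t", index=False)
                tab2.to_csv(os.path.join(
                    cfg.out_dir, f"genes_outcome_{key}.tsv"),
                    sep="\t", index=False)
                scan, comp = _pleio.pleiotropy_scan(
                    tab1[["gene_id", "pval_gc"]].rename(
                        columns={"pval_gc": "pval"}),
                    tab2[["gene_id", "pval_gc"]].rename(
                        columns={"pval_gc": "pval"}),
                    fdr=cfg.fdr)
                gmap = {g.gene_id: g for g in genes}
                results = []
                s1h, s2h = harmonize_pair(s1, s2)
                for _, row in scan[scan["significant"]].iterrows():
                    r, nloc = _pleio.gene_effect_correlation(
                        s1h, s2h, gmap[row["gene_id"]])
                    results.append(_pleio.PleiotropyResult(
                        gene_id=row["gene_id"], p1=row["p1"], p2=row["p2"],
                        t=row["t"], p_pleio=row["p_pleio"], q=row["q"],
                        effect_corr=r, n_local_snps=nloc))
                scan.to_csv(os.path.join(
                    cfg.out_dir, f"pleiotropy_{key}.tsv"),
                    sep="\t", index=False)
                corrs = [r.effect_corr for r in results
                         if np.isfinite(r.effect_corr)]
                if corrs:
                    _effect_corr_histogram(
                        corrs, key,
                        os.path.join(cfg.out_dir,
                                     f"effect_corr_{key}.png"))
                pleio_sets[key] = results
                summary.setdefault("pleiotropy", {})[key] = {
                    "n_significant": int(scan["significant"].sum()),
                    "lambda_gc": [lam1, lam2],
                    "pi00": comp.pi00,
                }
            cmpres = _pleio.compare_pleiotropic_sets(
                pleio_sets["fetal"], pleio_sets["maternal"])
            summary["pleiotropy"]["shared_genes"] = cmpres.shared_genes
            summary["pleiotropy"]["corr_effect_corr"] = cmpres.corr_effect_corr
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"gene/pleiotropy stage failed: {exc}") from exc

    # ---------------- MR / mediation stage ----------------
    if cfg.run_mr:
        try:
            file_traits = {"fetal", "menarche", "menopause", "outcome"}
            if file_traits <= set(cfg.files):
                x = read_sumstats(cfg.files["fetal"])
                m1 = read_sumstats(cfg.files["menarche"])
                m2 = read_sumstats(cfg.files["menopause"])
                yv = read_sumstats(cfg.files["outcome"],
                                   trait_type="binary")
                chain = ChainData(x=x, m1=m1, m2=m2, y=yv)
            else:
                chain = simulate_causal_chain(cfg.chain, rngs["chain"])
            graph, mr_table = chain_mediation_analysis(
                chain.x, chain.m1, chain.m2, chain.y, alpha=cfg.alpha,
                bw_p_thresh=cfg.bw_p_thresh, p_thresh=cfg.p_thresh,
                ld=None, seed=cfg.seed)
            mr_table.to_csv(os.path.join(cfg.out_dir, "mr_results.tsv"),
                            sep="\t", index=False)
            fetal_p, maternal_p, truth = simulate_bw_instrument_panel(
                rng=rngs["panel"])
            labels = _mr.classify_bw_instruments(
                fetal_p, maternal_p, list(truth.index))
            counts = labels.value_counts().to_dict()
            sets = _mr.instrument_sets_from_labels(labels)
            summary["instrument_classification"] = {
                "counts": counts,
                "n_fetal_set": len(sets["fetal"]),
                "n_maternal_set": len(sets["maternal"]),
            }
            with open(os.path.join(cfg.out_dir, "mediation.json"), "w") as fh:
                json.dump(graph.to_dict(), fh, indent=2)
            render_effect_graph(
                graph, dot_path=os.path.join(cfg.out_dir, "effect_graph.dot"),
                fig_path=os.path.join(cfg.out_dir, "effect_graph.png"))
            summary["mediation"] = {
                "->".join(p.nodes): p.verdict for p in graph.paths}
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"MR/mediation stage failed: {exc}") from exc

    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _effect_corr_histogram(corrs, label, path) -> None:
    """Distribution of local SNP effect-size correlations over the
    significant pleiotropic genes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(corrs, bins=np.linspace(-1, 1, 21), color="steelblue",
            edgecolor="white")
    ax.axvline(0, color="gray", lw=0.8)
    ax.set_xlabel("local effect-size correlation")
    ax.set_ylabel("pleiotropic genes")
    ax.set_title(label)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
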
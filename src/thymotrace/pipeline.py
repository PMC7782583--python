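"""End-to-end orchestration: simulate (or ingest) both conditions, embed,
annotate axes, call coreceptor states, order them along PC1 and pseudotime,
run the differential-expression contrasts and compare conditions.

One global seed fans out deterministically to per-stage child seeds, so an
identical config + seed yields a byte-identical JSON report.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import annotation, coreceptor, embedding, ordering, preprocess, stats, trajectory
from .io import read_counts, read_gene_set, validate_dataset, write_counts
from .simulate import SimulationConfig, generate_dataset, mhcii_ko_config
from .types import CellAnnotation, CountMatrix, GeneSetRef

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    # input: either simulate (default) or read from paths
    simulate: bool = True
    input_wt: Optional[dict] = None  # {"mtx":..., "cells":..., "genes":...}
    input_ko: Optional[dict] = None
    geneset_paths: Optional[dict] = None  # {"activation": path, "lineage": path}
    n_cells_per_subset: int = 50
    n_genes: int = 500
    ko_activation_scale: float = 0.5
    # preprocessing
    min_total: int = 500_000
    max_total: int = 1_500_000
    scale_factor: float = 1e4
    n_hvg: int = 2000
    exclude_genes: tuple[str, ...] = ("Cd4", "Cd8a", "Cd8b1")
    # embedding and annotation
    n_pcs: int = 10
    n_axis_genes: int = 100
    rank_by: str = "spline_p"
    spline_df: int = 4
    # classification and ordering
    tau: int = 1
    n_bins: int = 20
    alpha: float = 0.01
    axis: str = "pc1"  # primary ordering axis: "pc1" or "pseudotime"
    seed: int = 0

    def validate(self) -> None:
        if self.axis not in ("pc1", "pseudotime"):
            raise ValueError("axis must be 'pc1' or 'pseudotime'")
        if self.rank_by not in ("spline_p", "abs_r"):
            raise ValueError("rank_by must be 'spline_p' or 'abs_r'")
        if not self.simulate:
            for name, paths in (("input_wt", self.input_wt), ("input_ko", self.input_ko)):
                if not paths:
                    raise ValueError(f"simulate=False requires {name} paths")
                for key in ("mtx", "cells", "genes"):
                    if key not in paths:
                        raise ValueError(f"{name} is missing the {key!r} path")
                    if not Path(paths[key]).exists():
                        raise FileNotFoundError(f"{name}[{key!r}]: {paths[key]} not found")
            if not self.geneset_paths:
                raise ValueError("simulate=False requires geneset_paths")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_genes" in raw:
            raw["exclude_genes"] = tuple(raw["exclude_genes"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def _analyse_condition(
    cm: CountMatrix,
    ann: CellAnnotation,
    cfg: PipelineConfig,
    genesets: dict[str, GeneSetRef],
    label: str,
) -> dict:
    t0 = time.perf_counter()
    cm_qc = preprocess.qc_filter_cells(cm, cfg.min_total, cfg.max_total)
    keep = np.isin(ann.table["cell_id"], cm_qc.cell_ids)
    ann_qc = ann.subset(keep)
    nm = preprocess.lognormalize(cm_qc, cfg.scale_factor)
    hvg = preprocess.select_hvg(cm_qc, cfg.n_hvg, exclude=cfg.exclude_genes)
    k = min(cfg.n_pcs, min(nm.values.shape[0], len(hvg)) - 1)
    emb = embedding.pca(nm, hvg, k=k)
    activation_markers = genesets["activation"].genes if "activation" in genesets else []
    emb = embedding.orient_axes(emb, ann_qc, nm, activation_markers)
    var_tab = embedding.variance_report(emb)
    axes = annotation.annotate_axes(
        nm,
        emb,
        genesets,
        pcs=(1, 2, 3),
        n_top=cfg.n_axis_genes,
        rank_by=cfg.rank_by,
        df=cfg.spline_df,
        alpha=cfg.alpha,
    )
    calls = coreceptor.call_states(cm_qc, tau=cfg.tau)
    detect = coreceptor.detection_frequencies(cm_qc, ann_qc, tau=cfg.tau)
    inter_mask = coreceptor.pool_intermediates(ann_qc)
    inter_idx = np.flatnonzero(inter_mask)
    states_inter = calls["state"].to_numpy()[inter_idx]

    # ordering along oriented PC1
    pc1_inter = emb.pc(1)[inter_idx]
    order_pc1 = ordering.order_states(
        pc1_inter, states_inter, "pc1", n_bins=cfg.n_bins
    )
    # ordering along principal-curve pseudotime of the intermediates
    n_curve_pcs = min(3, emb.k)
    coords = emb.scores[inter_idx][:, :n_curve_pcs]
    traj = trajectory.principal_curve(coords)
    order_pt = ordering.order_states(
        traj.pseudotime, states_inter, "pseudotime", n_bins=cfg.n_bins
    )

    # centroid distances between intermediate subsets and SP populations
    pheno = ann_qc.phenotype
    states_all = calls["state"].to_numpy()
    groups = {}
    for st in ("CD4_state", "CD8_state"):
        m = inter_mask & (states_all == st)
        if m.any():
            groups[f"inter_{st}"] = m
    for sp in ("CD4_SP", "CD8_SP"):
        m = pheno == sp
        if m.any():
            groups[sp] = m
    pcs_for_dist = (1, 3) if emb.k >= 3 else tuple(range(1, emb.k + 1))
    dist = (
        ordering.centroid_distances(emb, groups, pcs=pcs_for_dist)
        if len(groups) >= 2
        else None
    )

    # DE between CD4_state and CD8_state intermediates
    de = None
    mask_a = inter_mask & (states_all == "CD4_state")
    mask_b = inter_mask & (states_all == "CD8_state")
    if mask_a.sum() >= 3 and mask_b.sum() >= 3:
        de = stats.wilcoxon_de(nm, mask_a, mask_b)

    log.info(
        "condition %s: %d cells -> %d after QC (%.1fs)",
        label, cm.n_cells, cm_qc.n_cells, time.perf_counter() - t0,
    )
    section = {
        "n_cells": cm_qc.n_cells,
        "dataset_report": validate_dataset(cm_qc, ann_qc),
        "variance_table": var_tab.reset_index().to_dict(orient="records"),
        "axis_labels": {pc: axes[pc].label for pc in axes},
        "axis_enrichment_p": {
            pc: {name: axes[pc].enrichments[name].p_value for name in axes[pc].enrichments}
            for pc in axes
        },
        "detection_frequencies": detect.reset_index().to_dict(orient="records"),
        "state_counts": calls["state"].value_counts().to_dict(),
        "intermediate_state_counts": order_pc1.n_per_state,
        "ordering_pc1": _ordering_summary(order_pc1),
        "ordering_pseudotime": _ordering_summary(order_pt),
        "pseudotime_converged": traj.converged,
        "centroid_distances": (
            dist.reset_index().to_dict(orient="records") if dist is not None else None
        ),
        "top_de_genes": (
            de.sort_values("adjusted_p").head(10).reset_index()
            .rename(columns={"index": "gene"}).to_dict(orient="records")
            if de is not None
            else None
        ),
    }
    internals = {
        "cm": cm_qc, "ann": ann_qc, "nm": nm, "emb": emb, "calls": calls,
        "order_pc1": order_pc1, "order_pt": order_pt, "de": de,
    }
    return {"section": section, "internals": internals}


def _ordering_summary(res: ordering.OrderingResult) -> dict:
    out: dict = {"axis": res.axis_name, "n_per_state": res.n_per_state, "ks": {}}
    for key, ks in res.ks.items():
        out["ks"][key] = {
            "D": ks.d, "p": ks.p, "alternative": ks.alternative, "method": ks.method,
        }
    out["peak_bins"] = {
        st: ordering.peak_bin(curve) for st, curve in res.curves.items()
    }
    return out


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage for both conditions and return the report bundle."""
    cfg.validate()
    seeds = _child_seeds(cfg.seed, 2)
    if cfg.simulate:
        sim_wt = SimulationConfig(
            n_cells_per_subset=cfg.n_cells_per_subset,
            n_genes=cfg.n_genes,
            seed=seeds[0],
        )
        sim_ko = mhcii_ko_config(sim_wt, activation_scale=cfg.ko_activation_scale)
        sim_ko = dataclasses.replace(sim_ko, seed=seeds[1])
        cm_wt, ann_wt, truth_wt = generate_dataset(sim_wt)
        cm_ko, ann_ko, truth_ko = generate_dataset(sim_ko)
        genesets = {
            "activation": truth_wt.truth_genesets["activation"],
            "lineage": truth_wt.truth_genesets["lineage"],
        }
    else:
        cm_wt, ann_wt = read_counts(**{k: cfg.input_wt[k2] for k, k2 in
                                       [("mtx_path", "mtx"), ("cells_tsv", "cells"),
                                        ("genes_tsv", "genes")]})
        cm_ko, ann_ko = read_counts(**{k: cfg.input_ko[k2] for k, k2 in
                                       [("mtx_path", "mtx"), ("cells_tsv", "cells"),
                                        ("genes_tsv", "genes")]})
        genesets = {
            name: read_gene_set(path, name)
            for name, path in cfg.geneset_paths.items()
        }
        truth_wt = truth_ko = None

    res_wt = _analyse_condition(cm_wt, ann_wt, cfg, genesets, "WT")
    res_ko = _analyse_condition(cm_ko, ann_ko, cfg, genesets, "MHCII_KO")

    key = "order_pc1" if cfg.axis == "pc1" else "order_pt"
    verdicts = ordering.compare_conditions(
        res_wt["internals"][key], res_ko["internals"][key], alpha=cfg.alpha
    )
    bundle = {
        "config": _jsonify(dataclasses.asdict(cfg)),
        "conditions": {"WT": res_wt["section"], "MHCII_KO": res_ko["section"]},
        "comparison": {
            "axis": cfg.axis,
            "alpha": cfg.alpha,
            "verdicts": {c: _jsonify(v) for c, v in verdicts.items()},
        },
    }
    bundle = _jsonify(bundle)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond, cm, ann in (("WT", cm_wt, ann_wt), ("MHCII_KO", cm_ko, ann_ko)):
            write_counts(
                cm, ann,
                outdir / f"{cond}_counts.mtx",
                outdir / f"{cond}_cells.tsv",
                outdir / f"{cond}_genes.tsv",
            )
        (outdir / "report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True), encoding="utf-8"
        )
        (outdir / "report.md").write_text(render_report(bundle), encoding="utf-8")
        manifest = {
            "files": sorted(p.name for p in outdir.iterdir()),
            "seed": cfg.seed,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
    return bundle


def render_report(bundle: dict) -> str:
    """One-page markdown summary of a report bundle.

    Renders the sections that are present; missing sections are noted
    rather than fatal.
    """
    lines = ["# Thymocyte lineage-choice ordering report", ""]
    comp = bundle.get("comparison")
    if comp:
        lines.append(f"Primary ordering axis: **{comp['axis']}** (alpha={comp['alpha']})")
        for cond, v in sorted(comp["verdicts"].items()):
            lines.append(
                f"- {cond}: **{v['verdict']}** "
                f"(one-sided KS {v['alternative']}: D={v['d']:.3f}, p={v['p']:.3g})"
            )
        lines.append("")
    else:
        lines.append("_comparison section missing_\n")
    for cond, sec in sorted(bundle.get("conditions", {}).items()):
        lines.append(f"## {cond}")
        lines.append(f"Cells after QC: {sec.get('n_cells', 'n/a')}")
        if sec.get("variance_table"):
            lines.append("\n| PC | % of first 5 | % of total |")
            lines.append("|---|---|---|")
            for row in sec["variance_table"]:
                lines.append(
                    f"| {row['pc']} | {row['pct_of_first5']:.2f} | {row['pct_of_total']:.2f} |"
                )
        if sec.get("axis_labels"):
            labels = ", ".join(
                f"PC{pc}: {lab}" for pc, lab in sorted(sec["axis_labels"].items())
            )
            lines.append(f"\nAxis labels: {labels}")
        if sec.get("state_counts"):
            counts = ", ".join(f"{k}={v}" for k, v in sorted(sec["state_counts"].items()))
            lines.append(f"\nCoreceptor state calls: {counts}")
        for axis_key in ("ordering_pc1", "ordering_pseudotime"):
            summ = sec.get(axis_key)
            if summ and summ.get("ks"):
                for name, ks in sorted(summ["ks"].items()):
                    lines.append(
                        f"\n{summ['axis']} KS ({name}): D={ks['D']:.3f}, "
                        f"p={ks['p']:.3g} [{ks['method']}]"
                    )
        if sec.get("top_de_genes"):
            top = ", ".join(r["gene"] for r in sec["top_de_genes"][:5])
            lines.append(f"\nTop DE genes (CD4_state vs CD8_state intermediates): {top}")
        elif sec.get("top_de_genes") is None:
            lines.append("\n_DE section unavailable (too few cells per state)_")
        lines.append("")
    return "\n".join(lines)
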
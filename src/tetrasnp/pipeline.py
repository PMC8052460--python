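"""Config-driven end-to-end pipeline.

Stage order mirrors a marker-based germplasm characterization: filtering ->
diversity -> distance/tree/curation -> structure (K-means/BIC, DAPC, Fst) ->
selection scans -> sweep consensus -> core selection -> pedigree checks.
Curation (duplicate and mislabel removal) always precedes core selection.
Every stage is a thin call into the library modules; the report performs no
arithmetic of its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import coreset, diversity, pedigree, popstructure, selection, simulate
from .io import (
    DosageMatrix,
    diploidize,
    filter_markers,
    five_cluster_frequencies,
    infer_ploidy,
    read_clone_panel,
    read_dosage_matrix,
    read_marker_map,
    write_dosage_csv,
)

log = logging.getLogger("tetrasnp.pipeline")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    outdir: str = "tetrasnp_run"
    seed: int = 0
    # inputs: either paths or a synthetic simulation block
    dosage_csv: str | None = None
    map_csv: str | None = None
    panel_csv: str | None = None
    pedigree_csv: str | None = None
    simulate: dict[str, Any] | None = None
    # stage toggles
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "filter": True,
            "diversity": True,
            "structure": True,
            "scan": True,
            "core": True,
            "pedigree": True,
        }
    )
    # stage parameters
    maf_min: float = 0.05
    max_missing: float = 0.10
    k_max: int = 8
    n_pca: int = 20
    dup_threshold: float = 0.001
    core_fraction: float = 0.20
    core_restarts: int = 10
    sweep_flank: int = 250_000

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class ReportBundle:
    sections: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if hasattr(o, "__dict__"):
                return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
            return str(o)

        return json.dumps(
            {"provenance": self.provenance, "sections": self.sections},
            default=default,
            indent=2,
        )


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = ReportBundle(
        provenance={"config": asdict(cfg), "config_hash": cfg.config_hash(), "seed": cfg.seed}
    )
    rng_seed = cfg.seed

    # ------------------------------------------------------------- inputs
    truth = None
    ped_table = None
    if cfg.simulate is not None:
        sim_cfg = simulate.SimConfig(seed=rng_seed, **cfg.simulate)
        D, panel, mmap, truth = simulate.simulate_structured_population(sim_cfg)
        D, panel, truth = simulate.inject_anomalies(D, panel, sim_cfg, truth)
        write_dosage_csv(D, str(outdir / "dosage.csv"))
        mmap.table.to_csv(outdir / "marker_map.csv", index=False)
        panel.table.to_csv(outdir / "clone_panel.csv", index=False)
    else:
        if cfg.dosage_csv is None:
            raise ValueError("either simulate: or dosage_csv must be configured")
        D = read_dosage_matrix(cfg.dosage_csv)
        mmap = read_marker_map(cfg.map_csv) if cfg.map_csv else None
        panel = read_clone_panel(cfg.panel_csv) if cfg.panel_csv else None
        if cfg.pedigree_csv:
            ped_table = pedigree.PedigreeTable(
                pd.read_csv(cfg.pedigree_csv).rename(
                    columns={"clone_id": "clone", "female_parent": "female", "male_parent": "male"}
                )
            )
    log.info("input: %d clones x %d markers", D.n_clones, D.n_markers)

    # ------------------------------------------------------------- filter
    if cfg.stages.get("filter", True):
        D, frep = filter_markers(D, cfg.maf_min, cfg.max_missing)
        report.sections["filter"] = asdict(frep)
        log.info("filter: retained %d of %d markers", frep.n_retained, frep.n_input)

    # ploidy screen: call every clone from its five-class profile
    ploidy_calls = {}
    for c in D.clone_ids:
        try:
            ploidy_calls[c] = infer_ploidy(five_cluster_frequencies(D, c))
        except ValueError:
            ploidy_calls[c] = "no_calls"
    non_tetra = sorted(c for c, v in ploidy_calls.items() if v != "tetraploid")
    report.sections["ploidy_screen"] = {"non_tetraploid": non_tetra}
    tetra = [c for c in D.clone_ids if ploidy_calls[c] == "tetraploid"]
    D_t = D.subset_clones(tetra) if non_tetra else D

    # ---------------------------------------------------------- diversity
    if cfg.stages.get("diversity", True):
        mstats = diversity.marker_stats(D_t)
        he_mean = float(mstats["He"].mean())
        cstats = diversity.clone_stats(D_t, he_mean)
        summary = diversity.sequence_diversity(diploidize(D_t))
        mstats.to_csv(outdir / "marker_stats.csv", index=False)
        cstats.to_csv(outdir / "clone_stats.csv", index=False)
        report.sections["diversity"] = {
            "he_mean": he_mean,
            "pic_mean": float(mstats["PIC"].mean()),
            "maf_mean": float(mstats["MAF"].mean()),
            "ho_mean": float(cstats["Ho"].mean()),
            "f_mean": float(cstats["F"].mean()),
            "sequence": asdict(summary),
        }

    # ---------------------------------------------------------- structure
    dm = popstructure.nei_distance_matrix(D_t)
    dm.to_frame().to_csv(outdir / "nei_distance.csv")
    Z, newick = popstructure.ward_tree(dm)
    (outdir / "dendrogram.nwk").write_text(newick)
    curation = (
        popstructure.detect_duplicates_and_mislabels(dm, panel, cfg.dup_threshold, tree=Z)
        if panel is not None
        else pd.DataFrame(columns=["clone_id", "flag", "evidence"])
    )
    curation.to_csv(outdir / "curation.csv", index=False)
    report.sections["curation"] = {
        "n_duplicates": int((curation["flag"] == "duplicate").sum()),
        "n_mislabel_candidates": int((curation["flag"] == "mislabel_candidate").sum()),
    }

    if cfg.stages.get("structure", True):
        cl = popstructure.kmeans_bic_scan(D_t, k_max=cfg.k_max, seed=rng_seed)
        dapc = popstructure.dapc_fit(
            D_t, cl.assignments, n_pca=min(cfg.n_pca, D_t.n_clones - cl.selected_k - 1)
        )
        fst = popstructure.pairwise_fst(D_t, cl.assignments)
        fst.to_csv(outdir / "fst.csv", index=False)
        dapc.memberships.to_csv(outdir / "dapc_memberships.csv")
        report.sections["structure"] = {
            "selected_k": cl.selected_k,
            "bic": dict(zip(map(str, cl.k_values), cl.bic)),
            "dapc_variance_fraction": dapc.variance_fraction,
            "n_da": dapc.n_da,
            "fst": fst,
        }

    # --------------------------------------------------------------- scans
    if cfg.stages.get("scan", True):
        if cfg.simulate is None:
            log.warning("scan stage needs phased haplotypes; skipping for file inputs")
        else:
            sim_cfg = simulate.SimConfig(seed=rng_seed, **(cfg.simulate or {}))
            panelA, panelB, sweep_truth = simulate.simulate_sweep_pair(sim_cfg)
            ihs = selection.ihs_scan(panelA)
            xpe = selection.xpehh_scan(panelA, panelB)
            regions = selection.consensus_sweeps([ihs, xpe], flank=cfg.sweep_flank)
            for res, name in ((ihs, "ihs"), (xpe, "xpehh")):
                res.table.to_csv(outdir / f"scan_{name}.csv", index=False)
            pd.DataFrame([asdict(r) for r in regions]).to_csv(
                outdir / "sweep_regions.csv", index=False
            )
            report.sections["scan"] = {
                "n_ihs_sig": int((ihs.table["q"] < 0.01).sum()),
                "n_xpehh_sig": int((xpe.table["q"] < 0.01).sum()),
                "n_regions": len(regions),
                "true_sweep": sweep_truth.sweep_markers,
            }

    # ----------------------------------------------------- curation + core
    if cfg.stages.get("core", True):
        drop = set(curation.loc[curation["flag"] == "duplicate", "clone_id"])
        drop |= set(curation.loc[curation["flag"] == "mislabel_candidate", "clone_id"])
        kept = [c for c in dm.clone_ids if c not in drop]
        dm_cur = popstructure.DistanceMatrix(
            kept,
            dm.to_frame().loc[kept, kept].to_numpy(),
        )
        sel = coreset.select_core(
            dm_cur, cfg.core_fraction, seed=rng_seed, restarts=cfg.core_restarts, panel=panel
        )
        D_cur = D_t.subset_clones([c for c in kept if c in D_t.clone_ids])
        comp = coreset.core_comparison(
            dm_cur, diversity.marker_stats(D_cur), D_cur, sel
        )
        pd.DataFrame({"clone_id": sel.selected}).to_csv(outdir / "core_set.csv", index=False)
        comp.to_csv(outdir / "core_comparison.csv", index=False)
        report.sections["core"] = {
            "n_selected": len(sel.selected),
            "objective_ene": sel.objective,
            "per_class_counts": sel.per_class_counts,
            "comparison": comp,
        }

    # ------------------------------------------------------------ pedigree
    if cfg.stages.get("pedigree", True):
        trios = []
        if cfg.simulate is not None:
            # simulate two pedigreed trios from the generated panel
            sim_cfg = simulate.SimConfig(seed=rng_seed, **(cfg.simulate or {}))
            rows, ids = [], []
            f, m = D_t.clone_ids[0], D_t.clone_ids[1]
            off = simulate.simulate_cross(D_t.row(f), D_t.row(m), 1, seed=rng_seed + 11)[0]
            ids.append("SIM_OFFSPRING")
            rows.append(off)
            Dp = DosageMatrix(
                D_t.clone_ids + ids,
                list(D_t.marker_ids),
                np.vstack([D_t.dosage, np.array(rows)]),
                ploidy=4,
            )
            trios.append(pedigree.trio_conflict(Dp, "SIM_OFFSPRING", f, m))
        elif ped_table is not None:
            genotyped = set(D_t.clone_ids)
            for _, row in ped_table.table.iterrows():
                c, f, m = row["clone"], row["female"], row["male"]
                if c in genotyped and f in genotyped and m in genotyped:
                    trios.append(pedigree.trio_conflict(D_t, c, f, m))
        report.sections["pedigree"] = {"trios": [asdict(t) for t in trios]}
        pd.DataFrame([asdict(t) for t in trios]).to_csv(outdir / "trio_report.csv", index=False)

    (outdir / "report.json").write_text(report.to_json())
    return report
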
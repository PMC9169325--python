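"""End-to-end orchestration: simulate -> map -> infer -> adjacency -> evidence.

Each stage reads only what previous stages wrote (or in-memory results),
writes its outputs plus a manifest (parameters, seed, output checksums) into
the run directory, and the whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import adjacency as adj
from . import ancestral, evidence, mapping
from .phylo import TreeIndex
from .synthetic_data import SimConfig, emit_expression, emit_genes, simulate_history

logger = logging.getLogger(__name__)

STAGES = ("simulate", "map", "infer", "adjacency", "evidence")


@dataclass
class RunConfig:
    tree: str
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulate: dict[str, Any] = field(default_factory=dict)
    map: dict[str, Any] = field(default_factory=dict)
    infer: dict[str, Any] = field(default_factory=dict)
    adjacency: dict[str, Any] = field(default_factory=dict)
    evidence: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tree:
            raise ValueError("config missing required field: tree")
        if not self.outdir:
            raise ValueError("config missing required field: outdir")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "tree" not in raw:
            raise ValueError("config missing required field: tree")
        raw.setdefault("outdir", str(Path(path).with_suffix("")) + "_out")
        raw["stages"] = tuple(raw.get("stages", STAGES))
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "parameters": params,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def derive_loss_profiles(
    matrix: mapping.IntronSiteMatrix,
    history: ancestral.EventHistory,
    tree: TreeIndex,
    species: str,
) -> list[adj.GeneLossProfile]:
    """Per-gene loss layouts for one species from the matrix + event history.

    A gene's ordered site list holds its conserved sites plus the sites this
    species lost; genes without a conserved site are excluded.
    """
    leaf = tree.index_of[species]
    path = set(tree.path_to_root(leaf))
    profiles = []
    meta = matrix.metadata
    for gid, rows in meta.groupby("group_id", sort=True):
        rows = rows.sort_values("aln_column")
        ordinals = []
        r = 0
        pos = 0
        for sid, row in rows.iterrows():
            lost_here = any(
                tree.index_of[b] in path for b in history.site_losses.get(sid, [])
            )
            if row["state"] == "conserved":
                r += 1
                pos += 1
            elif lost_here:
                pos += 1
                ordinals.append(pos)
        if r >= 1:
            profiles.append(
                adj.GeneLossProfile(gene_id=f"{gid}_{species}", r=r, lost_ordinals=tuple(ordinals))
            )
    return profiles


def gene_classes(history, tree: TreeIndex) -> pd.DataFrame:
    """Per (group, species) intron-lost / intron-gained flags from a TrueHistory."""
    flags = history.lost_gene_flags()
    gained: dict[tuple[str, str], bool] = {k: False for k in flags}
    for g in history.groups:
        for s in g.sites:
            if s.gained:
                b = tree.index_of[s.origin]
                for leaf in tree.subtree_leaves(b):
                    if s.leaf_presence.get(tree.labels[leaf]):
                        gained[(g.group_id, tree.labels[leaf])] = True
    rows = [
        {"group_id": gid, "species": sp, "intron_lost": flags[(gid, sp)],
         "intron_gained": gained[(gid, sp)]}
        for gid, sp in sorted(flags)
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages in order; returns the report directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = TreeIndex.from_newick(config.tree)

    sim_params = dict(config.simulate)
    sim_cfg = SimConfig(tree=config.tree, seed=config.seed, **sim_params)
    report: dict[str, Any] = {"seed": config.seed}

    history = data = fpkm = None
    if "simulate" in config.stages:
        history = simulate_history(sim_cfg)
        data = emit_genes(history, sim_cfg)
        fpkm = emit_expression(history, sim_cfg)
        simdir = outdir / "sim"
        data.write(simdir)
        fpkm.to_csv(simdir / "fpkm.tsv", sep="\t", index=False)
        _write_manifest(
            outdir, "simulate", sim_params,
            sorted(p for p in simdir.rglob("*") if p.is_file()),
        )
        report["simulate"] = {
            "groups": len(history.groups),
            "sites": len(history.all_sites()),
            "observable_sites": int(history.leaf_matrix().shape[0]),
        }

    matrix = None
    if "map" in config.stages:
        if data is None:
            raise ValueError("map stage requires simulated data in this run")
        mp = dict(config.map)
        window = mp.get("window", mapping.DEFAULT_WINDOW)
        max_gaps = mp.get("max_gaps", mapping.DEFAULT_MAX_GAPS)
        min_identity = mp.get("min_identity", mapping.DEFAULT_MIN_IDENTITY)
        max_ambiguous = mp.get("max_ambiguous", mapping.DEFAULT_MAX_AMBIGUOUS)
        sites = []
        for gid in sorted(data.alignments):
            aln = data.alignments[gid]
            for site in mapping.map_introns(aln):
                mapping.classify_site(site, aln, window, max_gaps, min_identity)
                sites.append(site)
        matrix = mapping.build_matrix(sites, max_ambiguous, species=tree.leaf_labels)
        matrix.to_tsv(outdir / "matrix.tsv")
        _write_manifest(outdir, "map", mp, [outdir / "matrix.tsv"])
        report["map"] = {
            "sites": matrix.n_sites,
            "conserved": int((matrix.metadata["state"] == "conserved").sum()),
            "discordant": int((matrix.metadata["state"] == "discordant").sum()),
        }

    events = None
    if "infer" in config.stages:
        if matrix is None:
            raise ValueError("infer stage requires the matrix from the map stage")
        inf = dict(config.infer)
        method = inf.get("method", "ml")
        dollo = ancestral.dollo_events(matrix, tree)
        events = dollo
        infer_report: dict[str, Any] = {
            "dollo_losses": dollo.total_losses,
            "dollo_gains": dollo.total_gains,
        }
        if method == "ml":
            root = inf.get("root", "free")
            fit_const = ancestral.fit_rates(
                matrix, tree, "constant",
                max_rounds=inf.get("max_rounds", 1000),
                tol=inf.get("tol", 0.001), seed=config.seed, root=root,
            )
            fit_var = ancestral.fit_rates(
                matrix, tree, "rate_variation",
                max_rounds=inf.get("max_rounds", 1000),
                tol=inf.get("tol", 0.001), seed=config.seed, root=root,
            )
            test = ancestral.lrt(fit_const.loglik, fit_var.loglik)
            chosen = fit_var if test.p_value < 0.05 else fit_const
            events = ancestral.posterior_events(
                matrix, tree, chosen.model,
                threshold=inf.get("posterior_threshold", 0.99),
            )
            infer_report.update(
                {
                    "loglik_constant": fit_const.loglik,
                    "loglik_rate_variation": fit_var.loglik,
                    "lrt_delta": test.delta,
                    "lrt_p": test.p_value,
                    "model": chosen.model.kind,
                    "loss_rate": chosen.model.loss_rate,
                    "gain_rate": chosen.model.gain_rate,
                    "posterior_losses": events.total_losses,
                    "posterior_gains": events.total_gains,
                }
            )
        summary = ancestral.branch_summary(events, tree)
        summary.table.to_csv(outdir / "branch_summary.tsv", sep="\t")
        events.events_frame().to_csv(outdir / "events.tsv", sep="\t", index=False)
        counts = pd.DataFrame(
            [
                {"node": lab, "N": n, "scaled_density": ancestral.scaled_density(n)}
                for lab, n in sorted(events.node_counts.items())
            ]
        )
        counts.to_csv(outdir / "ancestral_counts.tsv", sep="\t", index=False)
        _write_manifest(
            outdir, "infer", inf,
            [outdir / "branch_summary.tsv", outdir / "events.tsv", outdir / "ancestral_counts.tsv"],
        )
        infer_report["wilcoxon_p"] = summary.p_value
        report["infer"] = infer_report

    if "adjacency" in config.stages:
        if events is None or matrix is None:
            raise ValueError("adjacency stage requires inferred events")
        ap = dict(config.adjacency)
        n_res = ap.get("resamples", 100_000)
        rows = []
        for sp in tree.leaf_labels:
            profiles = derive_loss_profiles(matrix, events, tree, sp)
            multi = [p for p in profiles if p.l >= 2]
            observed = sum(p.d for p in profiles)
            losses = sum(p.l for p in profiles)
            if profiles:
                p_exact = adj.exact_tail(profiles)
                p_res = adj.resample_tail(profiles, n_res, seed=config.seed)
            else:
                p_exact = p_res = float("nan")
            rows.append(
                {
                    "species": sp,
                    "losses": losses,
                    "genes_ge2_lost": len(multi),
                    "adjacent_pairs": observed,
                    "p_exact": p_exact,
                    "p_resample": p_res,
                }
            )
        adj_table = pd.DataFrame(rows)
        adj_table.to_csv(outdir / "adjacency.tsv", sep="\t", index=False)
        _write_manifest(outdir, "adjacency", ap, [outdir / "adjacency.tsv"])
        report["adjacency"] = {
            "total_adjacent_pairs": int(adj_table["adjacent_pairs"].sum())
        }

    if "evidence" in config.stages:
        if history is None or fpkm is None:
            raise ValueError("evidence stage requires simulated data in this run")
        classes = gene_classes(history, tree)
        merged = fpkm.merge(classes, on=["group_id", "species"], suffixes=("", "_cls"))
        nonzero = merged[merged["fpkm"] > 0]
        lost = nonzero.loc[nonzero["intron_lost_cls"], "fpkm"]
        cons = nonzero.loc[~nonzero["intron_lost_cls"], "fpkm"]
        ev_report: dict[str, Any] = {}
        if len(lost) >= 2 and len(cons) >= 2:
            cmp = evidence.group_compare(lost, cons)
            ev_report["fpkm"] = {
                "median_lost": cmp.median_a,
                "median_conserved": cmp.median_b,
                "p_value": cmp.p_value,
            }
        n_total = classes.groupby("species").size().iloc[0]
        per_sp = classes.groupby("species")[["intron_lost", "intron_gained"]].sum()
        both = (
            classes[classes["intron_lost"] & classes["intron_gained"]]
            .groupby("species").size()
        )
        co_rows = {}
        for sp in per_sp.index:
            n_lost = int(per_sp.loc[sp, "intron_lost"])
            n_gain = int(per_sp.loc[sp, "intron_gained"])
            n_both = int(both.get(sp, 0))
            if n_lost and n_gain:
                res = evidence.cooccurrence_test(int(n_total), n_lost, n_gain, n_both)
                co_rows[sp] = {
                    "expected_both": res.expected_both,
                    "observed_both": n_both,
                    "p_value": res.p_value,
                }
        ev_report["cooccurrence"] = co_rows
        # splice-signal survey of every emitted intron
        gt_ag = ppt = total = 0
        for sp_structs in data.structures.values():
            for gs in sp_structs.values():
                for rec in gs.introns:
                    feats = evidence.intron_features(rec.sequence)
                    total += 1
                    gt_ag += feats.gt_ag
                    ppt += feats.ppt
        ev_report["splice_signals"] = {
            "introns": total,
            "gt_ag_fraction": gt_ag / total if total else float("nan"),
            "ppt_fraction": ppt / total if total else float("nan"),
        }
        (outdir / "evidence.json").write_text(json.dumps(ev_report, indent=2, sort_keys=True))
        _write_manifest(outdir, "evidence", dict(config.evidence), [outdir / "evidence.json"])
        report["evidence"] = ev_report

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    logger.info("pipeline complete: %s", outdir)
    return outdir
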
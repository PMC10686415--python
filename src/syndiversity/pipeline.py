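"""End-to-end orchestration of the FASS proteomics analysis.

One configuration drives the full chain: synthesize (or ingest) the
feature-level table, median-normalize runs, fit per-protein models per
brain region with controls pooled across cell lines, test sorted-vs-control
and direct type-vs-type contrasts, call synapse-type proteome membership,
build matched-pair log2FC profiles, construct the correlation network, and
compute pair statistics. Every random stage receives a seed derived
deterministically from the master seed, all intermediates are plain TSV,
and a manifest records file hashes for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import conet, membership, pairstats, profiles, quantmodel, synthdata

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Settings of one pipeline run; defaults match the standard cutoffs.

    fold-change gate 1.1, alpha 0.05, testability minimums 6 features /
    12 measurements per condition, soft power 6, edge-weight cutoff 0.3.
    """

    mode: str = "synthetic"  # synthetic | tables
    out_dir: str = "pipeline_out"
    master_seed: int = 0
    # cutoffs
    fc_cutoff: float = 1.1
    alpha: float = 0.05
    min_features: int = 6
    min_measurements: int = 12
    beta: float = 6.0
    weight_cutoff: float = 0.3
    min_module_size: int = 20
    # synthetic-mode sizes
    n_proteins: int = 600
    n_types: int = 15
    n_modules: int = 14
    scenario: dict = field(default_factory=dict)
    # tables-mode paths
    records_path: str | None = None
    runs_path: str | None = None
    traits_path: str | None = None
    complexes_path: str | None = None
    candidate_pairs_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "tables"):
            raise ValueError(f"mode must be synthetic or tables, got {self.mode!r}")
        if self.mode == "tables" and not (self.records_path and self.runs_path):
            raise ValueError("tables mode requires records_path and runs_path")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_cutoff <= 1.0:
            raise ValueError("fc_cutoff must exceed 1")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _seed_for(master: int, stage: str) -> int:
    """Stage seed derived deterministically from the master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def validate_inputs(records_path: str, runs_path: str) -> list[dict]:
    """Schema, uniqueness, annotation, and pairing checks on input tables.

    Returns one dict per violation with a human-readable message and,
    where applicable, offending line numbers (1-based, counting the
    header as line 1).
    """
    violations: list[dict] = []
    rec = pd.read_csv(records_path, sep="\t")
    runs = pd.read_csv(runs_path, sep="\t")
    for col in ("protein", "feature", "run", "intensity"):
        if col not in rec.columns:
            violations.append({"check": "schema", "message": f"records missing column {col!r}"})
    for col in ("run", "animal", "fraction", "region", "cell_type"):
        if col not in runs.columns:
            violations.append({"check": "schema", "message": f"runs missing column {col!r}"})
    if violations:
        return violations

    dup = rec.duplicated(subset=["protein", "feature", "run"], keep=False)
    if dup.any():
        lines = (rec.index[dup] + 2).tolist()
        violations.append(
            {"check": "uniqueness",
             "message": "duplicate (protein, feature, run) records",
             "lines": lines[:50]}
        )
    nonpos = rec["intensity"] <= 0
    if nonpos.any():
        lines = (rec.index[nonpos] + 2).tolist()
        violations.append(
            {"check": "intensity", "message": "non-positive intensities",
             "lines": lines[:50]}
        )
    unknown = ~rec["run"].isin(runs["run"])
    if unknown.any():
        lines = (rec.index[unknown] + 2).tolist()
        violations.append(
            {"check": "annotation",
             "message": "records reference unannotated runs",
             "lines": lines[:50]}
        )
    sorted_runs = runs[runs["fraction"] == "sorted"]
    ctrl_animals = set(runs.loc[runs["fraction"] == "control", "animal"])
    for i, row in sorted_runs.iterrows():
        if row["animal"] not in ctrl_animals:
            violations.append(
                {"check": "pairing",
                 "message": f"unpaired sorted run {row['run']!r}",
                 "lines": [int(i) + 2]}
            )
    return violations


def _region_groups(runs: pd.DataFrame) -> pd.Series:
    """Run -> model group: sorted runs by type, controls pooled per region."""
    labels = np.where(
        runs["fraction"] == "sorted",
        runs["cell_type"] + "_" + runs["region"] + "_sorted",
        runs["region"] + "_control",
    )
    return pd.Series(labels, index=runs["run"].to_numpy())


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis and write the artifact bundle.

    Returns a dict with the in-memory stage products and the manifest.
    Outputs under ``config.out_dir``: inputs/ (feature table, run
    annotation, ground-truth bundle in synthetic mode), calls.tsv,
    results_vs_control.tsv, results_direct.tsv, profiles.tsv +
    profile_meta.tsv, modules.tsv, edges.tsv, module_trait_r.tsv,
    pairs.tsv, report.json, manifest.json.
    """
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    inputs_dir = os.path.join(out, "inputs")
    os.makedirs(inputs_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "master_seed": config.master_seed,
        "config": asdict(config),
        "stages": {},
    }
    counts: dict[str, Any] = {}

    # ---- stage: inputs -------------------------------------------------
    truth = None
    if config.mode == "synthetic":
        t_seed = _seed_for(config.master_seed, "truth")
        s_seed = _seed_for(config.master_seed, "scenario")
        truth = synthdata.generate_ground_truth(
            n_types=config.n_types,
            n_proteins=config.n_proteins,
            n_modules=config.n_modules,
            seed=t_seed,
        )
        scenario = synthdata.SortingScenario(seed=s_seed, **config.scenario)
        table = synthdata.simulate_experiment(truth, scenario)
        synthdata.write_truth_bundle(
            truth, scenario, os.path.join(inputs_dir, "truth"), overwrite=True
        )
        rec_path = os.path.join(inputs_dir, "features.tsv")
        runs_path = os.path.join(inputs_dir, "runs.tsv")
        table.write(rec_path, runs_path)
        # read back so downstream sees exactly the serialized values
        table = synthdata.FeatureTable.read(rec_path, runs_path)
        traits = truth.traits
        complexes = truth.complexes
        candidates = list(truth.negative_pairs)
        rng = np.random.default_rng(_seed_for(config.master_seed, "candidates"))
        prot = truth.proteins.to_numpy()
        extra = rng.choice(len(prot), size=(4 * len(candidates) + 8, 2))
        candidates += [
            (prot[a], prot[b]) for a, b in extra if a != b
        ]
    else:
        rec_path, runs_path = config.records_path, config.runs_path
        table = synthdata.FeatureTable.read(rec_path, runs_path)
        traits = (
            pd.read_csv(config.traits_path, sep="\t", index_col=0)
            if config.traits_path else None
        )
        complexes = None
        if config.complexes_path:
            cdf = pd.read_csv(config.complexes_path, sep="\t")
            complexes = {
                str(cid): list(g["protein"])
                for cid, g in cdf.groupby("complex_id", sort=False)
            }
        candidates = None
        if config.candidate_pairs_path:
            pdf = pd.read_csv(config.candidate_pairs_path, sep="\t")
            candidates = list(zip(pdf.iloc[:, 0], pdf.iloc[:, 1]))

    violations = validate_inputs(rec_path, runs_path)
    if violations:
        raise ValueError(f"input validation failed: {violations[:3]}")
    manifest["stages"]["inputs"] = {
        "files": {p: _sha256(p) for p in (rec_path, runs_path)},
    }

    # ---- stage: normalize + fit ---------------------------------------
    table = quantmodel.normalize_runs(table)
    groups = _region_groups(table.runs)
    runs = table.runs
    fits_by_region: dict[str, dict] = {}
    for region, region_runs in runs.groupby("region", sort=True):
        sub_rec = table.records[table.records["run"].isin(region_runs["run"])]
        sub = synthdata.FeatureTable(records=sub_rec, runs=region_runs)
        fits_by_region[region] = quantmodel.fit_proteins(
            sub, groups,
            min_features=config.min_features,
            min_measurements=config.min_measurements,
        )

    # ---- stage: contrasts ---------------------------------------------
    vs_control: dict[str, list] = {}
    direct: dict[tuple[str, str, str], list] = {}
    for region, fits in sorted(fits_by_region.items()):
        cells = sorted(
            runs.loc[
                (runs["region"] == region) & (runs["fraction"] == "sorted"),
                "cell_type",
            ].unique()
        )
        ctrl_group = f"{region}_control"
        for cell in cells:
            syn_type = f"{cell}_{region}"
            res = quantmodel.compare_many(
                fits,
                {f"{cell}_{region}_sorted": 1.0, ctrl_group: -1.0},
                label=f"{syn_type}_vs_control",
            )
            vs_control[syn_type] = quantmodel.adjust_and_call(
                res, config.fc_cutoff, config.alpha
            )
        for i, ca in enumerate(cells):
            for cb in cells[i + 1:]:
                res = quantmodel.compare_many(
                    fits,
                    {f"{ca}_{region}_sorted": 1.0, f"{cb}_{region}_sorted": -1.0},
                    label=f"{ca}_vs_{cb}_{region}",
                )
                direct[(region, ca, cb)] = quantmodel.adjust_and_call(
                    res, config.fc_cutoff, config.alpha
                )

    res_ctrl_df = quantmodel.results_frame(
        [r for rs in vs_control.values() for r in rs]
    )
    res_direct_df = quantmodel.results_frame(
        [r for rs in direct.values() for r in rs]
    )
    counts["n_types_tested"] = len(vs_control)
    counts["enriched_vs_control"] = int((res_ctrl_df["call"] == "enriched").sum())
    counts["de_enriched_vs_control"] = int(
        (res_ctrl_df["call"] == "de-enriched").sum()
    )

    # ---- stage: membership --------------------------------------------
    def _flip(results: list) -> list:
        out = []
        for r in results:
            flipped = quantmodel.ComparisonResult(
                protein=r.protein, contrast=r.contrast + "_flipped",
                log2fc=-r.log2fc if np.isfinite(r.log2fc) else r.log2fc,
                se=r.se, df=r.df, t=-r.t if np.isfinite(r.t) else r.t,
                p=r.p, p_adj=r.p_adj, call=r.call,
            )
            if r.call == "enriched":
                flipped.call = "de-enriched"
            elif r.call == "de-enriched":
                flipped.call = "enriched"
            out.append(flipped)
        return out

    all_calls: list = []
    for region in sorted(fits_by_region):
        cells = sorted(
            runs.loc[
                (runs["region"] == region) & (runs["fraction"] == "sorted"),
                "cell_type",
            ].unique()
        )
        for cell in cells:
            syn_type = f"{cell}_{region}"
            others = [c for c in cells if c != cell][:2]
            directs = []
            for other in others:
                key = (region, *sorted((cell, other)))
                dres = direct.get((region, key[1], key[2]))
                if dres is None:
                    directs.append(None)
                    continue
                directs.append(dres if key[1] == cell else _flip(dres))
            while len(directs) < 2:
                directs.append(None)
            all_calls.extend(
                membership.call_proteome(
                    vs_control[syn_type], directs[0], directs[1],
                    synapse_type=syn_type,
                )
            )
    calls_df = pd.DataFrame([vars(c) for c in all_calls])
    counts["n_membership_calls"] = len(calls_df)
    counts["n_members"] = int((calls_df["status"] == "enriched").sum())
    counts["n_unique_enriched_proteins"] = int(
        calls_df.loc[calls_df["status"] == "enriched", "protein"].nunique()
    )

    # ---- stage: profiles ----------------------------------------------
    pmat = profiles.build_profile_matrix(table)
    type_avg = pmat.type_averaged()
    counts["n_profile_proteins"] = len(pmat.values)

    # ---- stage: network -----------------------------------------------
    net = None
    edges_df = pd.DataFrame(columns=["source", "target", "weight"])
    modules_df = pd.DataFrame(columns=["protein", "module"])
    if type_avg.values.shape[1] >= 4:
        net_traits = None
        if traits is not None:
            net_traits = traits.reindex(type_avg.values.columns).dropna()
            if len(net_traits) < type_avg.values.shape[1]:
                net_traits = None
        net = conet.build_network(
            type_avg, traits=net_traits, beta=config.beta,
            min_module_size=config.min_module_size,
        )
        edges_df = conet.export_network(
            net.adjacency, config.weight_cutoff, net.modules
        )
        modules_df = net.modules.rename("module").reset_index().rename(
            columns={"index": "protein"}
        )
        counts["n_network_proteins"] = len(net.proteins)
        counts["n_network_filtered_incomplete"] = net.n_filtered_incomplete
        counts["n_modules"] = int((net.modules.max()) if len(net.modules) else 0)
        counts["n_edges"] = len(edges_df)

    # ---- stage: pair statistics ---------------------------------------
    pair_rows = pd.DataFrame(
        columns=["protein_a", "protein_b", "r", "n", "p", "p_adj", "direction"]
    )
    if complexes:
        seed = _seed_for(config.master_seed, "pairstats")
        try:
            cx = pairstats.complex_coregulation(
                type_avg, complexes, seed=seed
            )
            counts["median_complex_r"] = cx["median_complex_r"]
            counts["median_random_r"] = cx["median_random_r"]
            counts["complex_permutation_p"] = cx["p_permutation"]
        except ValueError:
            pass
    if candidates:
        screened, significant = pairstats.screen_negative_pairs(
            type_avg, candidates, alpha=config.alpha
        )
        pair_rows = pd.DataFrame([vars(s) for s in screened])
        counts["n_pairs_screened"] = len(screened)
        counts["n_significant_negative_pairs"] = len(significant)

    # ---- write outputs -------------------------------------------------
    def _write(df: pd.DataFrame, name: str, index: bool = False) -> str:
        path = os.path.join(out, name)
        df.to_csv(path, sep="\t", index=index)
        return path

    files = [
        _write(res_ctrl_df, "results_vs_control.tsv"),
        _write(res_direct_df, "results_direct.tsv"),
        _write(calls_df, "calls.tsv"),
        _write(pmat.values, "profiles.tsv", index=True),
        _write(pmat.columns_meta, "profile_meta.tsv"),
        _write(modules_df, "modules.tsv"),
        _write(edges_df, "edges.tsv"),
        _write(pair_rows, "pairs.tsv"),
    ]
    if net is not None and net.module_trait_r is not None:
        files.append(_write(net.module_trait_r, "module_trait_r.tsv", index=True))
        files.append(_write(net.module_trait_p, "module_trait_p.tsv", index=True))
    report_path = os.path.join(out, "report.json")
    with open(report_path, "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    files.append(report_path)
    manifest["stages"]["outputs"] = {"files": {p: _sha256(p) for p in files}}
    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "config": config,
        "truth": truth,
        "table": table,
        "vs_control": vs_control,
        "direct": direct,
        "calls": calls_df,
        "profile_matrix": pmat,
        "type_averaged": type_avg,
        "network": net,
        "report": counts,
        "manifest": manifest,
    }
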
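"""Recovery and calibration benchmarks on synthetic experiments.

Each function simulates a controlled experiment with the ``synthdata``
generator, runs the corresponding analysis stage, and measures how well
known planted structure is recovered: false-call calibration under the
null, sensitivity to planted fold changes, module and trait recovery by
the correlation network, membership-call recovery, complex-pair
separation, and stereological diameter recovery. The pytest suite and the
standalone acceptance script both drive these harnesses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import conet, membership, pairstats, profiles, quantmodel, spheresim
from .pipeline import _region_groups
from .synthdata import (
    ComplexSpec,
    FeatureTable,
    PairSpec,
    SortingScenario,
    generate_ground_truth,
    simulate_experiment,
)

__all__ = [
    "null_enrichment_calibration",
    "enrichment_power",
    "module_trait_recovery",
    "membership_recovery",
    "complex_pair_separation",
    "negative_pair_screen_recovery",
    "sphere_diameter_recovery",
]


def _no_structure(**kw):
    kw.setdefault("pair_spec", PairSpec(n_pairs=0))
    kw.setdefault("complex_spec", ComplexSpec(n_complexes=0))
    return generate_ground_truth(**kw)


def _sorted_vs_control(table: FeatureTable, fc_cutoff=1.1, alpha=0.05):
    """Fit per region and test every type against its pooled region control."""
    groups = _region_groups(table.runs)
    results = {}
    for region, rr in table.runs.groupby("region", sort=True):
        sub = FeatureTable(
            records=table.records[table.records["run"].isin(rr["run"])],
            runs=rr,
        )
        fits = quantmodel.fit_proteins(sub, groups)
        for cell in sorted(rr.loc[rr["fraction"] == "sorted",
                                  "cell_type"].unique()):
            res = quantmodel.compare_many(
                fits, {f"{cell}_{region}_sorted": 1.0,
                       f"{region}_control": -1.0},
                label=f"{cell}_{region}_vs_control",
            )
            results[f"{cell}_{region}"] = quantmodel.adjust_and_call(
                res, fc_cutoff, alpha
            )
    return results


def null_enrichment_calibration(
    n_datasets: int = 20,
    n_proteins: int = 1000,
    n_types: int = 10,
    n_animals: int = 5,
    seed: int = 0,
) -> dict:
    """False-call fraction among tested, FC-passing proteins under the null.

    Flat latent abundances and zero sort purity make sorted and control
    runs draws from the same distribution; every enrichment or
    de-enrichment call is false. Each dataset contributes one
    sorted-vs-control contrast per synapse type.
    """
    log_cut = np.log2(quantmodel.DEFAULT_FC_CUTOFF)
    n_false = n_passing = n_contrasts = 0
    for d in range(n_datasets):
        truth = _no_structure(
            n_types=n_types, n_proteins=n_proteins, n_modules=0,
            profile_sd=0.0, seed=seed * 100_003 + d,
        )
        scenario = SortingScenario(
            seed=seed * 90_007 + d, n_animals=n_animals, purity=0.0,
            features_per_protein_mean=6.0,
        )
        table = quantmodel.normalize_runs(simulate_experiment(truth, scenario))
        for res in _sorted_vs_control(table).values():
            n_contrasts += 1
            for r in res:
                if np.isfinite(r.p) and abs(r.log2fc) > log_cut:
                    n_passing += 1
                    if r.call in ("enriched", "de-enriched"):
                        n_false += 1
    rate = n_false / n_passing if n_passing else 0.0
    return {
        "false_call_rate": rate,
        "n_false": n_false,
        "n_fc_passing": n_passing,
        "n_contrasts": n_contrasts,
        "bound": 0.05 + 3 * np.sqrt(0.05 * 0.95 / max(n_passing, 1)),
    }


def enrichment_power(
    n_proteins: int = 1000,
    n_planted: int = 200,
    effect_log2: float = 1.0,
    n_animals: int = 5,
    seed: int = 0,
) -> dict:
    """Sensitivity for planted fold changes (default 2-fold, CV 20%).

    Proteins are planted with ``effect_log2`` extra abundance in one
    synapse type; a pure sort against a low-prevalence precursor leaves
    the planted contrast at the nominal effect size.
    """
    truth = _no_structure(
        n_types=3, n_proteins=n_proteins, n_modules=0, profile_sd=0.0,
        seed=seed * 100_003 + 17,
    )
    target = truth.type_labels[0]
    planted = truth.proteins[:n_planted]
    truth.true_abundance.loc[planted, target] += effect_log2
    scenario = SortingScenario(
        seed=seed * 90_007 + 17, n_animals=n_animals, purity=1.0,
        prevalence=0.005, features_per_protein_mean=6.0, fixed_features=True,
        replicate_cv=0.2,
    )
    table = quantmodel.normalize_runs(simulate_experiment(truth, scenario))
    res = _sorted_vs_control(table)[target]
    called = {r.protein for r in res if r.call == "enriched"}
    sensitivity = len(called & set(planted)) / n_planted
    return {"sensitivity": sensitivity, "n_planted": n_planted,
            "n_called": len(called)}


def module_trait_recovery(
    n_seeds: int = 10,
    n_modules: int = 5,
    module_size: int = 50,
    n_proteins: int = 300,
    n_types: int = 15,
    n_animals: int = 3,
    seed: int = 0,
) -> dict:
    """Planted-module recovery through the full simulate-profile-network path.

    One module is tied to the vGat-like trait; the network must recover
    the module partition (adjusted Rand index vs truth) and that module's
    eigenprotein must show the largest signed correlation with the
    vGat-like trait among all detected modules.
    """
    from sklearn.metrics import adjusted_rand_score

    aris, vgat_top = [], []
    for s in range(n_seeds):
        truth = _no_structure(
            n_types=n_types, n_proteins=n_proteins, n_modules=n_modules,
            module_size=module_size, module_loading=0.9, n_trait_modules=1,
            seed=seed * 100_003 + s,
        )
        scenario = SortingScenario(seed=seed * 90_007 + s,
                                   n_animals=n_animals)
        table = quantmodel.normalize_runs(simulate_experiment(truth, scenario))
        type_avg = profiles.build_profile_matrix(table).type_averaged()
        net = conet.build_network(type_avg, traits=truth.traits)
        lab = net.modules
        aris.append(
            adjusted_rand_score(truth.module_assignment.reindex(lab.index),
                                lab)
        )
        overlap = pd.crosstab(truth.module_assignment.reindex(lab.index), lab)
        detected_vgat = overlap.loc[1].idxmax() if 1 in overlap.index else 0
        # signed maximum: the vGat-like and VGlut1-like traits are strongly
        # anti-correlated across types, so the excitatory module's
        # anti-correlation can rival the inhibitory module's |r|; positive
        # r with the vGat-like trait identifies the inhibitory module
        r_vgat = net.module_trait_r["vGat_IF"]
        vgat_top.append(
            detected_vgat != 0 and r_vgat.idxmax() == detected_vgat
        )
    return {
        "ari": aris,
        "mean_ari": float(np.mean(aris)),
        "vgat_module_is_top": vgat_top,
        "n_vgat_top": int(np.sum(vgat_top)),
    }


def membership_recovery(
    n_proteins: int = 1200,
    n_planted: int = 120,
    effect_log2: float = 1.5,
    seed: int = 0,
) -> dict:
    """Sensitivity and precision of membership calls for planted proteomes.

    One region carries three cell types; one protein set is planted as
    enriched in the first. Calls for that type are scored against the
    planted set. Scoring uses a clean diagnostic scenario — pure sort, no
    contaminant pseudo-proteome, fixed feature counts: under the
    contaminated default mixture, sorting genuinely enriches every
    non-contaminant protein by a small compositional margin and Poisson
    feature counts leave a fraction of proteins below the testability
    minimum, so a planted-set truth would mislabel real signal and
    unquantifiable proteins as errors.
    """
    labels = ["Camk2a_CX", "Gad2_CX", "Syn1_CX"]
    truth = _no_structure(
        n_types=3, n_proteins=n_proteins, n_modules=0, profile_sd=0.0,
        type_labels=labels, seed=seed * 100_003 + 23,
    )
    planted_a = truth.proteins[:n_planted]
    truth.true_abundance.loc[planted_a, "Camk2a_CX"] += effect_log2
    scenario = SortingScenario(seed=seed * 90_007 + 23, purity=1.0,
                               contaminant_fraction=0.0,
                               fixed_features=True)
    table = quantmodel.normalize_runs(simulate_experiment(truth, scenario))

    groups = _region_groups(table.runs)
    fits = quantmodel.fit_proteins(table, groups)
    vs_control = {}
    for label in labels:
        cell = label.split("_")[0]
        res = quantmodel.compare_many(
            fits, {f"{cell}_CX_sorted": 1.0, "CX_control": -1.0}, label=label
        )
        vs_control[label] = quantmodel.adjust_and_call(res)
    direct_ab = quantmodel.adjust_and_call(
        quantmodel.compare_many(
            fits, {"Camk2a_CX_sorted": 1.0, "Gad2_CX_sorted": -1.0}
        )
    )
    direct_ac = quantmodel.adjust_and_call(
        quantmodel.compare_many(
            fits, {"Camk2a_CX_sorted": 1.0, "Syn1_CX_sorted": -1.0}
        )
    )
    calls = membership.call_proteome(
        vs_control["Camk2a_CX"], direct_ab, direct_ac,
        synapse_type="Camk2a_CX",
    )
    called = {c.protein for c in calls if c.status == "enriched"}
    tp = len(called & set(planted_a))
    sensitivity = tp / n_planted
    precision = tp / len(called) if called else 0.0
    return {"sensitivity": sensitivity, "precision": precision,
            "n_called": len(called), "n_planted": n_planted}


def _default_profile_matrix(seed: int, n_animals: int = 5):
    truth = generate_ground_truth(
        n_types=15, n_proteins=300, n_modules=3, module_size=40,
        seed=seed * 100_003 + 31,
        complex_spec=ComplexSpec(n_complexes=6, size=5),
        pair_spec=PairSpec(n_pairs=10),
    )
    scenario = SortingScenario(seed=seed * 90_007 + 31, n_animals=n_animals)
    table = quantmodel.normalize_runs(simulate_experiment(truth, scenario))
    return truth, profiles.build_profile_matrix(table).type_averaged()


def complex_pair_separation(seed: int = 0, n_random: int = 5000) -> dict:
    """Median correlation of planted complex pairs vs random pairs."""
    truth, type_avg = _default_profile_matrix(seed)
    out = pairstats.complex_coregulation(
        type_avg, truth.complexes, n_random=n_random, seed=seed * 90_007 + 37
    )
    out["median_gap"] = out["median_complex_r"] - out["median_random_r"]
    return out


def negative_pair_screen_recovery(seed: int = 0) -> dict:
    """Detection of planted anti-correlated pairs among random candidates."""
    truth, type_avg = _default_profile_matrix(seed)
    rng = np.random.default_rng(seed * 90_007 + 41)
    prot = type_avg.values.index.to_numpy()
    candidates = list(truth.negative_pairs)
    extra = rng.choice(len(prot), size=(200, 2))
    candidates += [(prot[a], prot[b]) for a, b in extra if a != b]
    screened, significant = pairstats.screen_negative_pairs(
        type_avg, candidates
    )
    planted = {tuple(p) for p in truth.negative_pairs}
    found = {(s.protein_a, s.protein_b) for s in significant} & planted
    return {
        "n_planted": len(planted),
        "n_planted_detected": len(found),
        "n_significant_negative": len(significant),
        "n_screened": len(screened),
    }


def sphere_diameter_recovery(
    true_diameter: float = 600.0,
    n_spheres: int = 100,
    n_sections: int = 30,
    seed: int = 0,
) -> dict:
    """End-to-end diameter estimate from sampled cross-sections."""
    rng = np.random.default_rng(seed * 90_007 + 43)
    curve = spheresim.build_calibration(
        np.linspace(true_diameter / 6, true_diameter * 5 / 3, 10),
        seed=seed * 100_003 + 43,
    )
    estimates = [
        spheresim.estimate_diameter(
            spheresim.sample_cross_sections(
                true_diameter / 2, n_sections,
                int(rng.integers(0, 2**31 - 1)),
            ).mean(),
            curve,
        )
        for _ in range(n_spheres)
    ]
    mean_est = float(np.mean(estimates))
    return {
        "true_diameter": true_diameter,
        "mean_estimate": mean_est,
        "relative_error": abs(mean_est - true_diameter) / true_diameter,
    }
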
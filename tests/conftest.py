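"""Shared fixtures: small synthetic experiments reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from syndiversity import quantmodel, synthdata


@pytest.fixture(scope="session")
def default_truth():
    """Moderate default-structure ground truth (15 types, 14 modules)."""
    return synthdata.generate_ground_truth(
        n_types=15, n_proteins=700, n_modules=14, seed=11, module_size=40
    )


@pytest.fixture(scope="session")
def small_experiment():
    """Small simulated experiment: 3 planted modules, 15 types, 3 animals."""
    truth = synthdata.generate_ground_truth(
        n_types=15, n_proteins=250, n_modules=3, seed=5, module_size=40
    )
    scenario = synthdata.SortingScenario(seed=6, n_animals=3)
    table = synthdata.simulate_experiment(truth, scenario)
    return truth, scenario, table


@pytest.fixture(scope="session")
def normalized_profiles(small_experiment):
    """Profile matrix (per-animal and type-averaged) of the small experiment."""
    from syndiversity import profiles

    truth, scenario, table = small_experiment
    norm = quantmodel.normalize_runs(table)
    pm = profiles.build_profile_matrix(norm)
    return truth, pm, pm.type_averaged()


def make_feature_table(
    group_means: dict[str, float],
    n_features: int = 6,
    n_runs_per_group: int = 6,
    noise_sd: float = 0.0,
    feature_effects: np.ndarray | None = None,
    seed: int = 0,
    protein: str = "P1",
) -> tuple[pd.DataFrame, pd.Series]:
    """Single-protein feature-level records for given group log2 means."""
    rng = np.random.default_rng(seed)
    if feature_effects is None:
        feature_effects = np.arange(n_features, dtype=float) * 0.5
    rows = []
    groups = {}
    for g, mu in group_means.items():
        for r in range(n_runs_per_group):
            run = f"{g}_r{r}"
            groups[run] = g
            for f in range(n_features):
                y = mu + feature_effects[f] + (
                    rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                )
                rows.append(
                    {"protein": protein, "feature": f"f{f}", "run": run,
                     "intensity": 2.0**y}
                )
    return pd.DataFrame(rows), pd.Series(groups)
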
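"""Matched-pair log2 fold-change profiles, PCA, and variance partitioning.

The cross-type profile of a protein is its normalized log2(sorted/control)
value per matched pair (same animal, same region): the universal quantity
for all cross-type analyses (PCA, correlation networks, pair statistics).
Protein-level summarization uses the feature-wise median of paired log2
ratios, a robust pairwise statistic that is invariant to per-run offsets
already consumed by median normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import FeatureTable

__all__ = [
    "ProfileMatrix",
    "build_profile_matrix",
    "run_pca",
    "partition_variance",
]


@dataclass
class ProfileMatrix:
    """Proteins x samples matrix of matched-pair log2 fold changes.

    ``values``: DataFrame, rows proteins, one column per sorted/control
    pair (NaN = protein missing in either run of the pair).
    ``columns_meta``: per-column annotation (animal, cell_type, region,
    age, sex, synapse_type).
    """

    values: pd.DataFrame
    columns_meta: pd.DataFrame

    def type_averaged(self) -> "ProfileMatrix":
        """Average the per-animal columns of each synapse type."""
        syn = self.columns_meta.set_index("column")["synapse_type"]
        avg = self.values.T.groupby(syn.reindex(self.values.columns)).mean().T
        meta = self.columns_meta.groupby("synapse_type", sort=True).first()
        meta = meta.reset_index()
        meta["column"] = meta["synapse_type"]
        avg = avg[list(meta["synapse_type"])]
        return ProfileMatrix(values=avg, columns_meta=meta)

    def complete(self) -> "ProfileMatrix":
        """Restrict to proteins without any missing value."""
        keep = self.values.notna().all(axis=1)
        return ProfileMatrix(
            values=self.values.loc[keep], columns_meta=self.columns_meta
        )

    def write(self, values_path: str, meta_path: str) -> None:
        self.values.to_csv(values_path, sep="\t")
        self.columns_meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read(cls, values_path: str, meta_path: str) -> "ProfileMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(values=values, columns_meta=meta)


def build_profile_matrix(table: FeatureTable) -> ProfileMatrix:
    """Per-pair protein log2(sorted/control) from a normalized feature table.

    For each animal, the sorted run is matched to the control run of the
    same animal. Per protein, the pair value is the median over features
    (observed in both runs) of log2(sorted) - log2(control); this equals
    the median of feature-centered abundances' difference, with centering
    performed across the pair. Proteins absent in either run are missing.
    """
    runs = table.runs
    sorted_runs = runs[runs["fraction"] == "sorted"]
    control_by_animal = (
        runs[runs["fraction"] == "control"].set_index("animal")["run"]
    )
    orphans = [
        r for r, a in zip(sorted_runs["run"], sorted_runs["animal"])
        if a not in control_by_animal.index
    ]
    if orphans:
        raise ValueError(f"sorted run(s) without matched control: {orphans}")

    rec = table.records
    log2i = pd.Series(np.log2(rec["intensity"].to_numpy()), index=rec.index)
    by_run = {
        run: grp.assign(log2=log2i.loc[grp.index])
        .set_index(["protein", "feature"])["log2"]
        for run, grp in rec.groupby("run", sort=False)
    }

    columns = {}
    meta_rows = []
    for _, row in sorted_runs.iterrows():
        s_run, animal = row["run"], row["animal"]
        c_run = control_by_animal[animal]
        s = by_run.get(s_run, pd.Series(dtype=float))
        c = by_run.get(c_run, pd.Series(dtype=float))
        common = s.index.intersection(c.index)
        diff = (s.loc[common] - c.loc[common]).groupby(level="protein").median()
        columns[animal] = diff
        meta_rows.append(
            {
                "column": animal,
                "animal": animal,
                "cell_type": row["cell_type"],
                "region": row["region"],
                "age": row["age"],
                "sex": row["sex"],
                "synapse_type": f"{row['cell_type']}_{row['region']}",
            }
        )
    values = pd.DataFrame(columns)
    values.index.name = "protein"
    meta = pd.DataFrame(meta_rows)
    return ProfileMatrix(values=values, columns_meta=meta)


def run_pca(
    matrix: ProfileMatrix,
    n_components: int | None = None,
    scale: bool = False,
    max_missing_frac: float = 0.3,
) -> dict:
    """PCA over profile columns (samples) with deterministic sign convention.

    Proteins with more than ``max_missing_frac`` missing columns are
    dropped; remaining missing values are imputed by the protein-wise mean
    (both counts reported). Columns are the observations. Signs are fixed
    so the largest-magnitude loading of each component is positive.
    """
    vals = matrix.values
    frac_missing = vals.isna().mean(axis=1)
    kept = vals.loc[frac_missing <= max_missing_frac]
    n_dropped = len(vals) - len(kept)
    imputed = kept.apply(lambda r: r.fillna(r.mean()), axis=1)
    n_imputed = int(kept.isna().to_numpy().sum())

    X = imputed.to_numpy().T  # samples x proteins
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    from sklearn.decomposition import PCA

    max_rank = min(X.shape)
    k = max_rank if n_components is None else min(n_components, max_rank)
    truncated = n_components is not None and n_components > max_rank
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return {
        "scores": pd.DataFrame(
            scores, index=vals.columns,
            columns=[f"PC{i+1}" for i in range(k)],
        ),
        "loadings": pd.DataFrame(
            loadings.T, index=imputed.index,
            columns=[f"PC{i+1}" for i in range(k)],
        ),
        "variance_fraction": pca.explained_variance_ratio_,
        "n_proteins_dropped": n_dropped,
        "n_values_imputed": n_imputed,
        "truncated": truncated,
    }


def _subset_r2(
    Y: np.ndarray, designs: Mapping[frozenset, np.ndarray]
) -> dict[frozenset, np.ndarray]:
    """R^2 of every covariate subset for every profile (column of Y)."""
    tss = (Y**2).sum(axis=0)
    tss_safe = np.where(tss > 0, tss, 1.0)
    out = {}
    for subset, Q in designs.items():
        if Q.shape[1] == 0:
            out[subset] = np.zeros(Y.shape[1])
        else:
            proj = Q.T @ Y
            out[subset] = (proj**2).sum(axis=0) / tss_safe
    return out


def partition_variance(
    matrix: ProfileMatrix,
    covariates: Sequence[str] = ("cell_type", "region", "age", "sex"),
) -> dict:
    """Per-protein variance fractions explained by categorical covariates.

    For each protein profile, sequential sums of squares from a linear
    model containing all covariates are averaged over every covariate
    ordering (the LMG/Shapley decomposition, exact for the <= 4 default
    covariates). Fractions lie in [0, 1] and sum to at most 1; the
    remainder is residual. Covariates whose one-hot design adds no rank to
    the others (aliased) are flagged and reported as NaN. The summary
    compares per-protein fraction distributions between covariates with
    two-sided paired t tests.
    """
    covariates = list(covariates)
    if len(covariates) > 6:
        raise ValueError("exact all-orderings partition limited to 6 covariates")
    meta = matrix.columns_meta.set_index("column").loc[matrix.values.columns]
    n = len(meta)
    for c in covariates:
        lv = meta[c].astype(str)
        if lv.nunique() < 2 or lv.value_counts().min() < 2:
            raise ValueError(
                f"covariate {c!r} needs >= 2 levels with >= 2 columns each"
            )

    # centered one-hot blocks per covariate
    blocks = {}
    for c in covariates:
        d = pd.get_dummies(meta[c].astype(str), drop_first=True).to_numpy(float)
        blocks[c] = d - d.mean(axis=0)

    # orthonormal basis and rank for every covariate subset
    designs: dict[frozenset, np.ndarray] = {}
    ranks: dict[frozenset, int] = {}
    subsets = [frozenset()]
    for c in covariates:
        subsets += [s | {c} for s in subsets]
    for s in subsets:
        if not s:
            designs[s] = np.empty((n, 0))
            ranks[s] = 0
            continue
        D = np.hstack([blocks[c] for c in sorted(s)])
        Q, R = np.linalg.qr(D)
        keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())
        designs[s] = Q[:, keep]
        ranks[s] = int(keep.sum())

    aliased = [
        c for c in covariates
        if ranks[frozenset(covariates)]
        == ranks[frozenset(covariates) - {c}]
    ]

    Yfull = matrix.values.dropna(axis=0)
    Y = Yfull.to_numpy().T
    Y = Y - Y.mean(axis=0)
    r2 = _subset_r2(Y, designs)

    orderings = list(permutations(covariates))
    fractions = {c: np.zeros(Y.shape[1]) for c in covariates}
    for order in orderings:
        seen: frozenset = frozenset()
        for c in order:
            fractions[c] += r2[seen | {c}] - r2[seen]
            seen = seen | {c}
    for c in covariates:
        fractions[c] /= len(orderings)
    frac_df = pd.DataFrame(fractions, index=Yfull.index)
    for c in aliased:
        frac_df[c] = np.nan
    frac_df["residual"] = (1.0 - frac_df[covariates].sum(axis=1)).clip(lower=0.0)

    tests = []
    for i, a in enumerate(covariates):
        for b in covariates[i + 1:]:
            if a in aliased or b in aliased:
                continue
            t, p = stats.ttest_rel(frac_df[a], frac_df[b])
            tests.append(
                {"covariate_a": a, "covariate_b": b,
                 "mean_a": float(frac_df[a].mean()),
                 "mean_b": float(frac_df[b].mean()),
                 "t": float(t), "p": float(p)}
            )
    return {
        "fractions": frac_df,
        "summary": pd.DataFrame(tests),
        "aliased": aliased,
        "n_proteins": len(frac_df),
    }
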
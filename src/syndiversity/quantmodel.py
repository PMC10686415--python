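"""Per-protein differential-enrichment testing from feature-level intensities.

The quantification model follows the feature-based linear-model approach
used for label-free DIA data. Per protein, log2 feature intensities are
fitted to an additive fixed-effects model with feature and run effects; the
run effects (plus the average feature effect) are the protein's run-level
abundances. Group least-squares means and the residual variance are then
estimated at the run level, because biological replicate variation is
shared by all features of a protein within a run — pooling feature-level
residuals would treat correlated measurements as independent and grossly
overstate the effective sample size. This two-stage form is the reduced,
no-technical-replicate case of the mixed-effects formulation standard for
this design (feature effects fixed, one biological replicate per run).

Calls are made with a fold-change-gated Benjamini-Hochberg procedure: only
proteins whose estimated fold change exceeds the cutoff enter the
multiple-testing adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import FeatureTable

__all__ = [
    "ProteinFit",
    "ComparisonResult",
    "normalize_runs",
    "filter_testability",
    "fit_protein_model",
    "fit_proteins",
    "compare_groups",
    "compare_many",
    "adjust_and_call",
]

DEFAULT_MIN_FEATURES = 6
DEFAULT_MIN_MEASUREMENTS = 12
DEFAULT_FC_CUTOFF = 1.1
DEFAULT_ALPHA = 0.05
# residual variances below this (log2^2 units) are numerically zero: no valid t
VARIANCE_FLOOR = 1e-12


@dataclass
class ProteinFit:
    """Least-squares fit of log2 intensity ~ feature + group for one protein."""

    protein: str
    groups: list[str]
    ls_means: np.ndarray  # log2 group least-squares means
    cov_unscaled: np.ndarray  # (X'X)^-1 block of the group coefficients
    sigma2: float  # pooled residual variance (nan if df == 0)
    df_resid: int
    n_features: int
    n_measurements: Mapping[str, int] = field(default_factory=dict)
    testable: bool = True
    dropped_features: list[str] = field(default_factory=list)

    def group_index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in fit for {self.protein}")


@dataclass
class ComparisonResult:
    """One protein x contrast differential-enrichment result."""

    protein: str
    contrast: str
    log2fc: float
    se: float
    df: int
    t: float
    p: float
    p_adj: float = np.nan
    call: str = "not testable"

    def as_dict(self) -> dict:
        return {
            "protein": self.protein,
            "contrast": self.contrast,
            "log2fc": self.log2fc,
            "se": self.se,
            "df": self.df,
            "t": self.t,
            "p": self.p,
            "p_adj": self.p_adj,
            "call": self.call,
        }


def normalize_runs(table: FeatureTable) -> FeatureTable:
    """Equalize per-run log2 medians to the global median (median centering).

    The global reference is the median of the per-run medians, so a
    single-run table is returned unchanged. Missing entries (absent rows)
    are untouched. Raises if a run annotated in the table has no observed
    intensity.
    """
    rec = table.records
    log2i = np.log2(rec["intensity"].to_numpy())
    med = pd.Series(log2i, index=rec.index).groupby(rec["run"]).median()
    empty = set(table.runs["run"]) - set(med.index)
    if empty:
        raise ValueError(f"run(s) with no observed intensities: {sorted(empty)}")
    target = float(med.median())
    shift = (target - med).reindex(rec["run"]).to_numpy()
    out = rec.copy()
    out["intensity"] = np.exp2(log2i + shift)
    return FeatureTable(records=out, runs=table.runs.copy())


def filter_testability(
    protein_slice: pd.DataFrame,
    groups: pd.Series,
    compared: Sequence[str],
    min_features: int = DEFAULT_MIN_FEATURES,
    min_measurements: int = DEFAULT_MIN_MEASUREMENTS,
) -> dict:
    """Testability of one protein for a two-condition comparison.

    A protein is testable when it has at least ``min_features`` distinct
    features (precursor/fragment combinations) and at least
    ``min_measurements`` observed measurements in *each* compared condition.
    """
    g = groups.reindex(protein_slice["run"]).to_numpy()
    n_features = protein_slice["feature"].nunique()
    n_meas = {c: int((g == c).sum()) for c in compared}
    testable = n_features >= min_features and all(
        n >= min_measurements for n in n_meas.values()
    )
    return {
        "n_features": n_features,
        "n_measurements": n_meas,
        "testable": testable,
    }


def _design(
    feat_codes: np.ndarray, run_codes: np.ndarray, n_feat: int, n_runs: int
) -> np.ndarray:
    """Full-rank design: one column per run, one per non-reference feature.

    Run columns come first, so the run coefficients are directly per-run
    intercepts; adding the mean feature effect yields the run-level
    protein abundance.
    """
    n_obs = feat_codes.size
    X = np.zeros((n_obs, n_runs + n_feat - 1))
    X[np.arange(n_obs), run_codes] = 1.0
    mask = feat_codes > 0
    X[np.nonzero(mask)[0], n_runs + feat_codes[mask] - 1] = 1.0
    return X


class _DesignCache:
    """Cache pseudo-inverse solves keyed by the exact design pattern.

    Simulated tables share observation patterns across thousands of
    proteins; reusing the factorization makes whole-table fitting cheap.
    """

    def __init__(self) -> None:
        self._store: dict[bytes, tuple[np.ndarray, np.ndarray, int]] = {}

    def solve(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        key = X.tobytes() + str(X.shape).encode()
        hit = self._store.get(key)
        if hit is None:
            xtx = X.T @ X
            xtx_pinv = np.linalg.pinv(xtx)
            rank = int(np.linalg.matrix_rank(X))
            hit = (xtx_pinv @ X.T, xtx_pinv, rank)
            if len(self._store) < 256:
                self._store[key] = hit
        return hit


def fit_protein_model(
    protein_slice: pd.DataFrame,
    groups: pd.Series,
    min_features: int = DEFAULT_MIN_FEATURES,
    min_measurements: int = DEFAULT_MIN_MEASUREMENTS,
    _cache: _DesignCache | None = None,
) -> ProteinFit:
    """Fit log2(intensity) ~ feature + group for one protein's records.

    ``groups`` maps run id -> group label; runs mapped to NaN are excluded.
    Features observed in fewer than two runs are dropped (unestimable
    feature effects) and recorded. Returns a fit with ``testable=False``
    when residual degrees of freedom are zero or counts fall below the
    testability thresholds.
    """
    protein = str(protein_slice["protein"].iloc[0]) if len(protein_slice) else "NA"
    g = groups.reindex(protein_slice["run"]).to_numpy()
    keep = pd.notna(g)
    return _fit_core(
        protein,
        protein_slice["feature"].to_numpy()[keep],
        protein_slice["run"].to_numpy()[keep],
        g[keep].astype(str),
        np.log2(protein_slice["intensity"].to_numpy()[keep]),
        min_features,
        min_measurements,
        _cache or _DesignCache(),
    )


def _fit_core(
    protein: str,
    features: np.ndarray,
    run_arr: np.ndarray,
    g: np.ndarray,
    y: np.ndarray,
    min_features: int,
    min_measurements: int,
    cache: "_DesignCache",
) -> ProteinFit:
    if y.size == 0:
        return ProteinFit(
            protein=protein, groups=[], ls_means=np.empty(0),
            cov_unscaled=np.empty((0, 0)), sigma2=np.nan, df_resid=0,
            n_features=0, testable=False,
        )

    # drop features observed only once (their effect absorbs the observation)
    feat_levels, feat_codes = np.unique(features, return_inverse=True)
    counts = np.bincount(feat_codes)
    dropped = list(feat_levels[counts < 2])
    if dropped:
        m = counts[feat_codes] >= 2
        features, run_arr, g, y = features[m], run_arr[m], g[m], y[m]
        feat_levels, feat_codes = np.unique(features, return_inverse=True)
    if y.size == 0:
        return ProteinFit(
            protein=protein, groups=[], ls_means=np.empty(0),
            cov_unscaled=np.empty((0, 0)), sigma2=np.nan, df_resid=0,
            n_features=0, testable=False, dropped_features=dropped,
        )

    group_levels = np.unique(g)
    n_groups = group_levels.size
    run_levels, run_codes = np.unique(run_arr, return_inverse=True)
    n_feat, n_runs = feat_levels.size, run_levels.size

    # stage 1: run-level protein abundances from log2 ~ feature + run
    if n_feat > 1:
        X = _design(feat_codes, run_codes, n_feat, n_runs)
        solver, _, _ = cache.solve(X)
        beta = solver @ y
        feat_eff = np.concatenate([[0.0], beta[n_runs:]])
        run_abund = beta[:n_runs] + feat_eff.mean()
    else:
        counts = np.bincount(run_codes, minlength=n_runs)
        run_abund = np.bincount(run_codes, weights=y, minlength=n_runs) / counts

    # each run belongs to exactly one group
    first_obs = np.full(n_runs, -1, dtype=int)
    for i in range(run_codes.size - 1, -1, -1):
        first_obs[run_codes[i]] = i
    run_group = g[first_obs]

    # stage 2: group least-squares means and pooled run-level variance
    ls_means = np.empty(n_groups)
    n_runs_per_group = np.empty(n_groups)
    ss_resid = 0.0
    for gi, lv in enumerate(group_levels):
        vals = run_abund[run_group == lv]
        n_runs_per_group[gi] = vals.size
        ls_means[gi] = vals.mean() if vals.size else np.nan
        if vals.size > 1:
            ss_resid += float(((vals - vals.mean()) ** 2).sum())
    df_resid = int(n_runs - n_groups)
    sigma2 = ss_resid / df_resid if df_resid > 0 else np.nan

    n_meas = {lv: int((g == lv).sum()) for lv in group_levels}
    # a strictly positive residual variance is required for a valid t test;
    # exact interpolation (noise-free toys) is flagged untestable
    testable = (
        df_resid > 0
        and sigma2 > VARIANCE_FLOOR
        and n_feat >= min_features
        and all(n >= min_measurements for n in n_meas.values())
    )
    return ProteinFit(
        protein=protein,
        groups=list(group_levels),
        ls_means=ls_means,
        cov_unscaled=np.diag(1.0 / n_runs_per_group),
        sigma2=sigma2,
        df_resid=df_resid,
        n_features=int(n_feat),
        n_measurements=n_meas,
        testable=testable,
        dropped_features=dropped,
    )


def fit_proteins(
    table: FeatureTable,
    groups: pd.Series,
    min_features: int = DEFAULT_MIN_FEATURES,
    min_measurements: int = DEFAULT_MIN_MEASUREMENTS,
) -> dict[str, ProteinFit]:
    """Fit every protein in the table; shares design factorizations.

    Equivalent to calling :func:`fit_protein_model` per protein, but maps
    run groups once and slices numpy arrays instead of DataFrames.
    """
    cache = _DesignCache()
    rec = table.records
    g_all = groups.reindex(rec["run"]).to_numpy()
    keep = pd.notna(g_all)
    prot = rec["protein"].to_numpy()[keep]
    feat = rec["feature"].to_numpy()[keep]
    run = rec["run"].to_numpy()[keep]
    g_all = g_all[keep].astype(str)
    y = np.log2(rec["intensity"].to_numpy()[keep])

    order = np.argsort(prot, kind="stable")
    prot, feat, run, g_all, y = (
        prot[order], feat[order], run[order], g_all[order], y[order]
    )
    uniq, starts = np.unique(prot, return_index=True)
    bounds = np.append(starts, prot.size)
    fits: dict[str, ProteinFit] = {}
    for i, protein in enumerate(uniq):
        lo, hi = bounds[i], bounds[i + 1]
        fits[str(protein)] = _fit_core(
            str(protein), feat[lo:hi], run[lo:hi], g_all[lo:hi], y[lo:hi],
            min_features, min_measurements, cache,
        )
    # proteins whose runs all lack a group mapping: untestable placeholder
    missing = set(map(str, rec["protein"].unique())) - set(fits)
    for protein in sorted(missing):
        fits[protein] = ProteinFit(
            protein=protein, groups=[], ls_means=np.empty(0),
            cov_unscaled=np.empty((0, 0)), sigma2=np.nan, df_resid=0,
            n_features=0, testable=False,
        )
    return fits


def compare_groups(
    fit: ProteinFit,
    contrast: Mapping[str, float],
    label: str | None = None,
    min_features: int = DEFAULT_MIN_FEATURES,
    min_measurements: int = DEFAULT_MIN_MEASUREMENTS,
) -> ComparisonResult:
    """Test a zero-sum contrast of group least-squares means.

    log2FC is the weighted sum of LS-means; the standard error comes from
    the pooled residual variance and the design; two-sided p from the t
    distribution at the fit's residual degrees of freedom. A zero t
    statistic reports p = 1. Testability is contrast-specific: the feature
    minimum applies to the protein, the measurement minimum to every
    condition the contrast touches.
    """
    if abs(sum(contrast.values())) > 1e-9:
        raise ValueError("contrast weights must sum to 0")
    missing = [g for g in contrast if g not in fit.groups]
    if missing:
        raise KeyError(
            f"contrast references group(s) absent from fit: {missing}"
        )
    name = label or " - ".join(
        f"{w:+g}*{g}" for g, w in contrast.items()
    )
    w = np.zeros(len(fit.groups))
    for gname, weight in contrast.items():
        w[fit.group_index(gname)] = weight
    log2fc = float(w @ fit.ls_means)
    testable = (
        fit.df_resid > 0
        and fit.n_features >= min_features
        and all(
            fit.n_measurements.get(g, 0) >= min_measurements for g in contrast
        )
    )
    if (not testable or not np.isfinite(fit.sigma2)
            or fit.sigma2 <= VARIANCE_FLOOR):
        return ComparisonResult(
            protein=fit.protein, contrast=name, log2fc=log2fc,
            se=np.nan, df=fit.df_resid, t=np.nan, p=np.nan,
            call="not testable",
        )
    var = fit.sigma2 * float(w @ fit.cov_unscaled @ w)
    se = np.sqrt(var)
    if se == 0.0:
        t = np.inf if log2fc != 0 else 0.0
    else:
        t = log2fc / se
    p = 1.0 if t == 0.0 else float(2.0 * stats.t.sf(abs(t), fit.df_resid))
    return ComparisonResult(
        protein=fit.protein, contrast=name, log2fc=log2fc, se=se,
        df=fit.df_resid, t=float(t), p=p, call="not significant",
    )


def compare_many(
    fits: Mapping[str, ProteinFit],
    contrast: Mapping[str, float],
    label: str | None = None,
) -> list[ComparisonResult]:
    """Apply one contrast to all fits where its groups are present."""
    out = []
    for fit in fits.values():
        if all(g in fit.groups for g in contrast):
            out.append(compare_groups(fit, contrast, label))
        else:
            out.append(
                ComparisonResult(
                    protein=fit.protein,
                    contrast=label or "contrast",
                    log2fc=np.nan, se=np.nan, df=0, t=np.nan, p=np.nan,
                    call="not testable",
                )
            )
    return out


def adjust_and_call(
    results: Iterable[ComparisonResult],
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
    bh_scope: str = "fc_gated",
) -> list[ComparisonResult]:
    """Benjamini-Hochberg adjustment gated on the fold-change cutoff.

    With ``bh_scope='fc_gated'`` (the default), BH runs only over proteins
    whose |log2FC| strictly exceeds log2(fc_cutoff); proteins failing the
    gate keep an undefined adjusted p and are called not significant.
    ``bh_scope='all'`` adjusts every testable protein instead. Calls:
    enriched (log2FC > 0, adjusted p < alpha, gate passed), de-enriched
    (symmetric), otherwise not significant / not testable.
    """
    if bh_scope not in ("fc_gated", "all"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    res = list(results)
    log_cut = np.log2(fc_cutoff)
    testable = [r for r in res if np.isfinite(r.p)]
    if bh_scope == "fc_gated":
        in_adjust = [r for r in testable if abs(r.log2fc) > log_cut]
    else:
        in_adjust = testable
    for r in res:
        if np.isfinite(r.p):
            r.call = "not significant"
            r.p_adj = np.nan
        else:
            r.call = "not testable"
    if in_adjust:
        padj = multipletests([r.p for r in in_adjust], method="fdr_bh")[1]
        for r, q in zip(in_adjust, padj):
            r.p_adj = float(q)
            if q < alpha and abs(r.log2fc) > log_cut:
                r.call = "enriched" if r.log2fc > 0 else "de-enriched"
    return res


def results_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparison results, one row per protein x contrast."""
    return pd.DataFrame([r.as_dict() for r in results])
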
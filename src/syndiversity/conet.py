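"""Weighted protein co-abundance network over synapse-type profiles.

Builds a signed-hybrid weighted correlation network: robust biweight
midcorrelation between protein profiles, adjacency = positive correlations
raised to a soft power (default beta = 6, negatives zeroed), topological
overlap, average-linkage module detection with eigenprotein merging,
module eigenproteins (first principal component of the standardized member
profiles), and Pearson module-trait correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .profiles import ProfileMatrix

__all__ = [
    "NetworkModel",
    "bicor",
    "bicor_matrix",
    "adjacency_signed_hybrid",
    "topological_overlap",
    "detect_modules",
    "eigenproteins",
    "module_trait_correlation",
    "export_network",
    "build_network",
]

DEFAULT_BETA = 6.0
DEFAULT_WEIGHT_CUTOFF = 0.3
DEFAULT_MIN_MODULE_SIZE = 20
DEFAULT_MERGE_THRESHOLD = 0.75
BICOR_TUNING = 9.0


@dataclass
class NetworkModel:
    """Adjacency, modules, eigenproteins, and module-trait correlations."""

    proteins: pd.Index
    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    beta: float
    modules: pd.Series  # protein -> module label, 0 = unassigned
    eigenprotein: pd.DataFrame  # module x type
    module_trait_r: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None
    n_filtered_incomplete: int = 0


def _bicor_weights(x: np.ndarray, c: float = BICOR_TUNING) -> np.ndarray | None:
    """Tukey biweights on median-centered data; None when MAD is zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return None
    u = (x - med) / (c * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x: np.ndarray, y: np.ndarray, c: float = BICOR_TUNING) -> float:
    """Biweight midcorrelation of two profiles (tuning constant 9).

    Observations are weighted by Tukey biweights computed from the median
    and the median absolute deviation, making the statistic robust to
    single outlying types. A side with zero MAD (at least half the values
    identical) falls back to Pearson weighting (mean-centering) for both
    sides, matching the robust-correlation convention for degenerate
    scales. Requires at least 4 paired finite observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValueError("bicor needs >= 4 paired finite observations")
    x, y = x[ok], y[ok]
    a = _bicor_weights(x, c)
    b = _bicor_weights(y, c)
    if a is None or b is None:
        a, b = x - x.mean(), y - y.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def bicor_matrix(values: pd.DataFrame, c: float = BICOR_TUNING) -> pd.DataFrame:
    """Pairwise bicor of all rows (proteins) of a complete profile matrix."""
    X = values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("bicor_matrix requires complete profiles")
    if X.shape[1] < 4:
        raise ValueError("bicor needs >= 4 observations per profile")
    W = np.empty_like(X)
    for i in range(X.shape[0]):
        w = _bicor_weights(X[i], c)
        W[i] = (X[i] - X[i].mean()) if w is None else w
    norms = np.sqrt((W**2).sum(axis=1))
    norms[norms == 0] = np.nan
    R = (W @ W.T) / np.outer(norms, norms)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=values.index, columns=values.index)


def adjacency_signed_hybrid(
    corr: pd.DataFrame, beta: float = DEFAULT_BETA
) -> pd.DataFrame:
    """Signed-hybrid soft-threshold adjacency: a = corr^beta for corr > 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    C = corr.to_numpy(dtype=float)
    A = np.where(C > 0, C, 0.0) ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=corr.index, columns=corr.columns)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    measuring shared neighborhood in addition to the direct edge.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    dissimilarity: pd.DataFrame,
    matrix: ProfileMatrix | None = None,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = None,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
) -> pd.Series:
    """Average-linkage modules from a dissimilarity (1 - TOM by default).

    A static cut at ``cut_height`` (default: 95% of the maximum merge
    height, so branches joining only near the top of the tree are treated
    as distinct) defines candidate clusters; clusters smaller than
    ``min_module_size`` are set to the unassigned label 0; modules whose
    eigenproteins correlate above ``merge_threshold`` are merged
    iteratively (requires ``matrix``). Labels are reassigned 1, 2, ... by
    decreasing module size.
    """
    D = dissimilarity.to_numpy(dtype=float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    if cut_height is None:
        cut_height = 0.95 * float(Z[:, 2].max())
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=dissimilarity.index, name="module")
    sizes = labels.value_counts()
    labels[labels.map(sizes) < min_module_size] = 0

    if matrix is not None:
        labels = _merge_by_eigenprotein(labels, matrix, merge_threshold)

    # relabel by decreasing size, 0 stays unassigned
    sizes = labels[labels > 0].value_counts().sort_values(ascending=False)
    remap = {old: i + 1 for i, old in enumerate(sizes.index)}
    remap[0] = 0
    return labels.map(remap).astype(int)


def _merge_by_eigenprotein(
    labels: pd.Series, matrix: ProfileMatrix, threshold: float
) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            return labels
        eig = eigenproteins(matrix, labels)
        best, best_r = None, threshold
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                if a not in eig.index or b not in eig.index:
                    continue
                r = float(np.corrcoef(eig.loc[a], eig.loc[b])[0, 1])
                if r > best_r:
                    best, best_r = (a, b), r
        if best is None:
            return labels
        labels[labels == best[1]] = best[0]


def eigenproteins(
    matrix: ProfileMatrix,
    labels: pd.Series,
    max_missing_frac: float = 0.3,
) -> pd.DataFrame:
    """First principal component of each module's standardized profiles.

    Rows are modules, columns the profile columns (synapse types). Each
    eigenprotein has unit variance and non-negative correlation with its
    module's mean profile. Missing values beyond ``max_missing_frac`` per
    protein exclude the protein; remaining gaps are mean-imputed.
    """
    vals = matrix.values
    out = {}
    for m in sorted(set(labels) - {0}):
        members = labels.index[labels == m]
        sub = vals.loc[vals.index.intersection(members)]
        sub = sub.loc[sub.isna().mean(axis=1) <= max_missing_frac]
        if len(sub) < 2:
            continue
        sub = sub.apply(lambda r: r.fillna(r.mean()), axis=1)
        Z = sub.to_numpy(dtype=float)
        Z = Z - Z.mean(axis=1, keepdims=True)
        sd = Z.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = Z / sd
        # first right singular vector across types
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        e = vt[0]
        mean_profile = Z.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        e = (e - e.mean()) / e.std(ddof=1)
        out[m] = e
    return pd.DataFrame(out, index=vals.columns).T.rename_axis("module")


def module_trait_correlation(
    eigen: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of eigenproteins with synapse-type traits.

    Categorical traits are one-hot encoded; p values are two-sided from
    the t distribution with n - 2 degrees of freedom. A constant trait
    yields NaN.
    """
    n = eigen.shape[1]
    if n < 4:
        raise ValueError("need >= 4 synapse types for trait correlation")
    T = pd.DataFrame(index=traits.index)
    for col in traits.columns:
        if traits[col].dtype.kind in "biufc":
            T[col] = traits[col].astype(float)
        else:
            dummies = pd.get_dummies(traits[col], prefix=col)
            for d in dummies.columns:
                T[d] = dummies[d].astype(float)
    T = T.loc[eigen.columns]
    r = pd.DataFrame(index=eigen.index, columns=T.columns, dtype=float)
    p = pd.DataFrame(index=eigen.index, columns=T.columns, dtype=float)
    for m in eigen.index:
        e = eigen.loc[m].to_numpy(dtype=float)
        for tr in T.columns:
            tv = T[tr].to_numpy(dtype=float)
            if np.std(tv) == 0 or np.std(e) == 0:
                continue
            rv = float(np.corrcoef(e, tv)[0, 1])
            rv = float(np.clip(rv, -1.0, 1.0))
            if abs(rv) >= 1.0:
                pv = 0.0
            else:
                tstat = rv * np.sqrt((n - 2) / (1.0 - rv**2))
                pv = float(2.0 * stats.t.sf(abs(tstat), n - 2))
            r.loc[m, tr] = rv
            p.loc[m, tr] = pv
    return r, p


def export_network(
    adjacency: pd.DataFrame,
    weight_cutoff: float = DEFAULT_WEIGHT_CUTOFF,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Undirected edge list with weights strictly above the cutoff.

    Each unordered pair appears once (source index < target index), with
    the module labels of both endpoints when provided.
    """
    A = adjacency.to_numpy(dtype=float)
    iu, ju = np.triu_indices_from(A, k=1)
    keep = A[iu, ju] > weight_cutoff
    prot = adjacency.index.to_numpy()
    df = pd.DataFrame(
        {
            "source": prot[iu[keep]],
            "target": prot[ju[keep]],
            "weight": A[iu, ju][keep],
        }
    )
    if labels is not None:
        df["module_source"] = labels.reindex(df["source"]).to_numpy()
        df["module_target"] = labels.reindex(df["target"]).to_numpy()
    return df


def build_network(
    matrix: ProfileMatrix,
    traits: pd.DataFrame | None = None,
    beta: float = DEFAULT_BETA,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = None,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    use_tom: bool = True,
) -> NetworkModel:
    """Full network construction on the complete-profile subset.

    Only proteins without missing profile values enter the network (the
    number filtered is recorded on the model). Clustering operates on
    1 - TOM by default; ``use_tom=False`` uses 1 - adjacency instead.
    """
    complete = matrix.complete()
    n_filtered = len(matrix.values) - len(complete.values)
    corr = bicor_matrix(complete.values)
    adj = adjacency_signed_hybrid(corr, beta)
    diss = (1.0 - topological_overlap(adj)) if use_tom else (1.0 - adj)
    if not use_tom:
        diss = diss.copy()
        np.fill_diagonal(diss.to_numpy(), 0.0)
    labels = detect_modules(
        diss, matrix=complete, min_module_size=min_module_size,
        cut_height=cut_height, merge_threshold=merge_threshold,
    )
    eig = eigenproteins(complete, labels)
    r = p = None
    if traits is not None and len(eig):
        r, p = module_trait_correlation(eig, traits)
    return NetworkModel(
        proteins=complete.values.index,
        correlation=corr,
        adjacency=adj,
        beta=beta,
        modules=labels,
        eigenprotein=eig,
        module_trait_r=r,
        module_trait_p=p,
        n_filtered_incomplete=n_filtered,
    )
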
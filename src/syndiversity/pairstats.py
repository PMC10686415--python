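"""Pairwise co-regulation statistics over cross-type profile matrices.

Covers three questions asked of synapse-type abundance profiles: do
annotated protein-complex subunits co-vary more than random protein pairs
(permutation test on the median Pearson r), which candidate pairs are
significantly anti-correlated across synapse types (t test on Pearson r
with Benjamini-Hochberg control), and which user-supplied gene sets are
over-represented in a query set (hypergeometric upper tail).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ProfileMatrix

__all__ = [
    "PairScreenResult",
    "pair_correlation",
    "complex_coregulation",
    "screen_negative_pairs",
    "hypergeometric_ora",
]

MIN_PAIR_OBS = 4


@dataclass
class PairScreenResult:
    """Correlation screen outcome for one protein pair."""

    protein_a: str
    protein_b: str
    r: float
    n: int
    p: float
    p_adj: float
    direction: str  # negative / positive


def pair_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Pearson r, n, and two-sided t-test p for one pair of profiles.

    Uses complete paired observations only; requires at least 4. The p
    value comes from t = r * sqrt(n-2) / sqrt(1-r^2) with n - 2 degrees
    of freedom. Constant profiles yield NaN r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < MIN_PAIR_OBS:
        raise ValueError(f"pair needs >= {MIN_PAIR_OBS} complete observations")
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, n, np.nan
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, n, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, n, p


def _pair_r(values: pd.DataFrame, pairs: np.ndarray) -> np.ndarray:
    """Pearson r for an array of row-index pairs of a complete matrix."""
    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = np.nan
    a, b = pairs[:, 0], pairs[:, 1]
    return np.clip(
        (Xc[a] * Xc[b]).sum(axis=1) / (norm[a] * norm[b]), -1.0, 1.0
    )


def complex_coregulation(
    matrix: ProfileMatrix,
    complexes: Mapping[str, Sequence[str]],
    n_random: int = 10000,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Within-complex vs random-pair profile correlation.

    Computes Pearson r for every pair of quantified subunits within each
    complex, and for ``n_random`` random cross-protein pairs (excluding
    within-complex pairs) as the null. The permutation p value is the
    fraction of null medians -- medians of random-pair sets matched in size
    to the complex-pair set, resampled ``n_permutations`` times from the
    random-pair pool -- at least as large as the observed complex median.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.dropna(axis=0)
    idx = {p: i for i, p in enumerate(values.index)}

    complex_pairs: list[tuple[int, int]] = []
    n_dropped = 0
    forbidden: set[tuple[int, int]] = set()
    for members in complexes.values():
        present = [idx[m] for m in members if m in idx]
        n_dropped += len(members) - len(present)
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                lo, hi = min(a, b), max(a, b)
                forbidden.add((lo, hi))
                complex_pairs.append((lo, hi))
    complex_pairs = sorted(set(complex_pairs))
    if not complex_pairs:
        raise ValueError("no complex with >= 2 quantified members")

    n_prot = len(values)
    rand_pairs = []
    while len(rand_pairs) < n_random:
        cand = rng.integers(0, n_prot, size=(2 * n_random, 2))
        cand = cand[cand[:, 0] != cand[:, 1]]
        cand.sort(axis=1)
        for a, b in cand:
            key = (int(a), int(b))
            if key not in forbidden:
                rand_pairs.append(key)
                if len(rand_pairs) >= n_random:
                    break
    rand_pairs = np.array(rand_pairs[:n_random])

    r_complex = _pair_r(values, np.array(complex_pairs))
    r_random = _pair_r(values, rand_pairs)
    r_complex = r_complex[np.isfinite(r_complex)]
    r_random = r_random[np.isfinite(r_random)]
    obs = float(np.median(r_complex))

    k = len(r_complex)
    draws = rng.integers(0, len(r_random), size=(n_permutations, k))
    null_medians = np.median(r_random[draws], axis=1)
    p_perm = float((null_medians >= obs).mean())

    return {
        "median_complex_r": obs,
        "median_random_r": float(np.median(r_random)),
        "r_complex": r_complex,
        "r_random": r_random,
        "n_complex_pairs": k,
        "n_random_pairs": len(r_random),
        "n_members_dropped": n_dropped,
        "p_permutation": p_perm,
    }


def screen_negative_pairs(
    matrix: ProfileMatrix,
    candidate_pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    adjust: bool = True,
) -> tuple[list[PairScreenResult], list[PairScreenResult]]:
    """Correlation screen over candidate pairs; returns (all, significant-negative).

    Pearson r across the profile columns, two-sided t p value, BH across
    all screened pairs (``adjust=False`` uses raw p values instead). The
    significant-negative subset requires r < 0 and adjusted p < alpha.
    Pairs with a constant profile are excluded and reported with NaN.
    """
    vals = matrix.values
    rows: list[PairScreenResult] = []
    for a, b in candidate_pairs:
        if a not in vals.index or b not in vals.index:
            continue
        r, n, p = pair_correlation(vals.loc[a].to_numpy(), vals.loc[b].to_numpy())
        rows.append(
            PairScreenResult(
                protein_a=a, protein_b=b, r=r, n=n, p=p, p_adj=np.nan,
                direction="negative" if (np.isfinite(r) and r < 0) else "positive",
            )
        )
    valid = [s for s in rows if np.isfinite(s.p)]
    if valid:
        if adjust:
            padj = multipletests([s.p for s in valid], method="fdr_bh")[1]
        else:
            padj = [s.p for s in valid]
        for s, q in zip(valid, padj):
            s.p_adj = float(q)
    significant = [
        s for s in valid
        if s.direction == "negative" and np.isfinite(s.p_adj) and s.p_adj < alpha
    ]
    return rows, significant


def hypergeometric_ora(
    query: Sequence[str],
    universe: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a query set.

    Gene sets are intersected with the universe; for each set the
    upper-tail probability of observing at least the overlap count is
    computed, then BH-adjusted across sets. An empty set after
    intersection is reported with overlap 0 and p = 1.
    """
    query_s = set(query)
    universe_s = set(universe)
    offenders = sorted(query_s - universe_s)
    if offenders:
        raise ValueError(f"query not contained in universe, e.g. {offenders[:5]}")
    M = len(universe_s)
    n = len(query_s)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & universe_s)
        k = len(set(members) & query_s)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K > 0 else 1.0
        rows.append(
            {"set": name, "set_size": K, "query_size": n,
             "overlap": k, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
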
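"""Synapse-type proteome membership calling.

A protein belongs to the proteome of synapse type A (in one brain region)
when it satisfies at least one of three criteria:

I.   enriched sorted-vs-control AND not significantly different in the
     direct comparison of type A against the companion type B;
II.  significantly enriched in the direct A-over-B comparison AND a positive
     log2 fold change sorted-vs-control;
III. as II for the direct comparison against a third type C.

"Not significantly different" means not in the adjusted-significant set of
the direct comparison, whether the protein failed the fold-change gate or
the adjusted p threshold. The shared/type-enriched partition labels a
protein shared when it is enriched over control in both compared types and
not significant in their direct comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quantmodel import ComparisonResult, ProteinFit, compare_groups

__all__ = [
    "ProteomeCall",
    "call_proteome",
    "partition_shared",
    "interaction_contrast",
    "overlap_with_reference",
    "read_gmt",
]


@dataclass
class ProteomeCall:
    """Membership decision for one protein in one synapse type."""

    protein: str
    synapse_type: str
    status: str  # enriched / de-enriched / not significant / not quantified
    criterion: str  # I / II / III / none
    partition: str = "unassigned"
    flags: str = ""


def _index(results: Iterable[ComparisonResult]) -> dict[str, ComparisonResult]:
    return {r.protein: r for r in results}


def call_proteome(
    vs_control: Iterable[ComparisonResult],
    vs_type_b: Iterable[ComparisonResult] | None,
    vs_type_c: Iterable[ComparisonResult] | None,
    synapse_type: str = "A",
) -> list[ProteomeCall]:
    """Apply the three-criterion membership rule for one synapse type.

    The criterion recorded is the first satisfied in order I, II, III;
    membership itself is the OR. Criteria II/III additionally require the
    sorted-vs-control comparison to be testable for the protein — a protein
    present only in a direct comparison cannot vouch for control enrichment
    and is flagged. De-enrichment status is carried through from the
    control comparison for non-members.
    """
    ctrl = _index(vs_control)
    direct_b = _index(vs_type_b) if vs_type_b is not None else {}
    direct_c = _index(vs_type_c) if vs_type_c is not None else {}

    calls: list[ProteomeCall] = []
    proteins = sorted(set(ctrl) | set(direct_b) | set(direct_c))
    for p in proteins:
        rc = ctrl.get(p)
        rb = direct_b.get(p)
        rcx = direct_c.get(p)
        flags = []
        if rc is None or rc.call == "not testable":
            # no usable control comparison: cannot establish enrichment
            if rb is not None or rcx is not None:
                flags.append("no-control-comparison")
            calls.append(
                ProteomeCall(p, synapse_type, "not quantified", "none",
                             flags=";".join(flags))
            )
            continue

        ctrl_enriched = rc.call == "enriched"
        ctrl_positive = np.isfinite(rc.log2fc) and rc.log2fc > 0
        b_significant = rb is not None and rb.call in ("enriched", "de-enriched")
        b_over = rb is not None and rb.call == "enriched"
        c_over = rcx is not None and rcx.call == "enriched"

        criterion = "none"
        if ctrl_enriched and not b_significant:
            criterion = "I"
        elif b_over and ctrl_positive:
            criterion = "II"
        elif c_over and ctrl_positive:
            criterion = "III"

        if criterion != "none":
            status = "enriched"
        elif rc.call == "de-enriched":
            status = "de-enriched"
        else:
            status = "not significant"
        calls.append(
            ProteomeCall(p, synapse_type, status, criterion,
                         flags=";".join(flags))
        )
    return calls


def partition_shared(
    calls_a: Iterable[ProteomeCall],
    calls_b: Iterable[ProteomeCall],
    direct: Iterable[ComparisonResult],
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Partition proteins into A-enriched / B-enriched / shared / unassigned.

    A-enriched: significant in the direct A-over-B comparison (positive);
    B-enriched symmetric. Shared: enriched over control in both types and
    not significant in the direct comparison. Everything else unassigned.
    """
    a = {c.protein: c for c in calls_a}
    b = {c.protein: c for c in calls_b}
    d = _index(direct)
    rows = []
    for p in sorted(set(a) | set(b) | set(d)):
        rd = d.get(p)
        enr_a = p in a and a[p].status == "enriched"
        enr_b = p in b and b[p].status == "enriched"
        if rd is not None and rd.call == "enriched":
            part = f"{label_a}-enriched"
        elif rd is not None and rd.call == "de-enriched":
            part = f"{label_b}-enriched"
        elif enr_a and enr_b:
            part = "shared"
        else:
            part = "unassigned"
        rows.append({"protein": p, "partition": part,
                     "enriched_a": enr_a, "enriched_b": enr_b})
    return pd.DataFrame(rows).set_index("protein")


def interaction_contrast(
    fit: ProteinFit,
    a_sorted: str,
    a_control: str,
    b_sorted: str,
    b_control: str,
    label: str | None = None,
    **kwargs,
) -> ComparisonResult:
    """Difference-of-differences contrast within one joint per-protein fit.

    Estimate = (A_sorted - A_control) - (B_sorted - B_control); the standard
    error is propagated through the joint design, which is why all four
    groups must come from a single fit rather than two separate ones.
    """
    contrast = {a_sorted: 1.0, a_control: -1.0, b_sorted: -1.0, b_control: 1.0}
    name = label or f"({a_sorted}-{a_control})-({b_sorted}-{b_control})"
    return compare_groups(fit, contrast, label=name, **kwargs)


def overlap_with_reference(
    members: Sequence[str],
    universe: Sequence[str],
    reference: Sequence[str],
) -> dict:
    """Overlap fraction of a member set with a reference set, plus ORA p.

    Fraction = |members ∩ reference| / |members|; the hypergeometric
    enrichment p value is delegated to the over-representation test.
    """
    members_s, universe_s = set(members), set(universe)
    if not members_s:
        raise ValueError("member set is empty; overlap fraction undefined")
    if not members_s <= universe_s:
        bad = sorted(members_s - universe_s)[:5]
        raise ValueError(f"members outside the universe, e.g. {bad}")
    reference_s = set(reference) & universe_s
    overlap = members_s & reference_s
    from .pairstats import hypergeometric_ora

    ora = hypergeometric_ora(
        sorted(members_s), sorted(universe_s), {"reference": sorted(reference_s)}
    )
    return {
        "n_members": len(members_s),
        "n_reference": len(reference_s),
        "n_overlap": len(overlap),
        "fraction": len(overlap) / len(members_s),
        "p": float(ora["p"].iloc[0]),
    }


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read gene sets in GMT format (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
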
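"""Three-phase short-form development pipeline.

Phase 1 selects, per original-scale domain and under fixed per-domain
quotas, the pilot items with the largest discrimination index (point-
biserial case/control effect x corrected within-domain item-total
correlation). Phase 2 prunes the pilot by per-item ROC AUC of case vs
non-case discrimination inside the psychiatric sample and re-orders the
survivors so the five most discriminating items open the questionnaire
(enabling a short form), the remainder interleaved across subscales.
Phase 3 (``evaluate_final``) assembles the validation report: per-group
score summaries, rank-test comparisons against the case group, ROC curves
and operating points at the screening cut-offs, reliability per group, and
the factor solution with the case group excluded.

Every ranking is deterministic; ties resolve by ascending item id and all
stage tables are kept in an audit log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .instrument import (
    GROUP_ASD,
    GROUP_NONPSYCH,
    CohortResult,
    InstrumentDefinition,
    ResponseRecord,
    batch_score,
    score_matrix,
)
from .psychometrics import (
    DiscriminationScore,
    FactorSolution,
    GroupComparison,
    ReliabilityResult,
    ROCResult,
    cronbach_alpha,
    discrimination_index,
    empirical_roc,
    operating_point,
    principal_factor_analysis,
)

__all__ = [
    "DomainQuota",
    "Phase1Result",
    "ReductionReport",
    "ValidationReport",
    "phase1_select",
    "phase2_prune",
    "reorder_items",
    "evaluate_final",
    "PILOT_QUOTAS",
]

# Pilot quotas proportional to the original four-domain scale (18 items).
PILOT_QUOTAS: dict[str, int] = {
    "circumscribed_interests": 4,
    "language": 2,
    "social_relatedness": 8,
    "sensory_motor": 4,
}


@dataclass
class DomainQuota:
    domain: str
    n_select: int


@dataclass
class Phase1Result:
    selected: list            # item ids, ranked within domain
    table: pd.DataFrame       # per item: domain, r_pb, r_it, index, rank, selected
    audit: list[str] = field(default_factory=list)


@dataclass
class ReductionReport:
    selected: list            # surviving item ids in the new order
    dropped: list             # (item_id, auc) for removed items
    per_item: pd.DataFrame    # per item: auc, dropped flag
    audit: list[str] = field(default_factory=list)


def _quota_mapping(quotas) -> dict[str, int]:
    if isinstance(quotas, Mapping):
        return dict(quotas)
    return {q.domain: q.n_select for q in quotas}


def phase1_select(
    item_scores: pd.DataFrame,
    groups: pd.Series,
    domains: Mapping,
    quotas,
    case_label: str = GROUP_ASD,
    control_label: str = GROUP_NONPSYCH,
) -> Phase1Result:
    """Quota-constrained discrimination-index selection on an item bank.

    ``item_scores``: subjects x items (0-3); ``domains``: item -> domain
    label; ``quotas``: per-domain number of items to keep. Only case and
    control rows enter the index. Within each domain items are ranked by
    index descending, ties broken by ascending item id.
    """
    quotas = _quota_mapping(quotas)
    mask = groups.isin([case_label, control_label])
    if not (groups == case_label).any() or not (groups == control_label).any():
        raise UsageError("both case and control groups must be present")
    sub = item_scores.loc[mask.values]
    flags = (groups[mask.values] == case_label).to_numpy()

    missing = set(item_scores.columns) - set(domains)
    if missing:
        raise UsageError(f"items without a domain label: {sorted(missing)}")

    rows = []
    audit = []
    for domain, n_select in quotas.items():
        members = [c for c in item_scores.columns if domains[c] == domain]
        if n_select > len(members):
            raise UsageError(
                f"quota {n_select} exceeds domain size {len(members)} for {domain!r}"
            )
        dm = sub[members]
        scores: list[DiscriminationScore] = [
            discrimination_index(sub[c].to_numpy(), flags, dm, item_key=c)
            for c in members
        ]
        ranked = sorted(
            scores,
            key=lambda s: (-(s.index if s.defined else -np.inf), s.item_id),
        )
        for rank, s in enumerate(ranked, start=1):
            rows.append(
                {
                    "item_id": s.item_id,
                    "domain": domain,
                    "r_pb": s.r_pb,
                    "r_it": s.r_it,
                    "index": s.index,
                    "rank": rank,
                    "selected": rank <= n_select,
                }
            )
        kept = [s.item_id for s in ranked[:n_select]]
        audit.append(f"phase1 {domain}: kept {kept} of {len(members)} items")
    table = pd.DataFrame(rows).set_index("item_id")
    selected = list(table.index[table["selected"]])
    return Phase1Result(selected=selected, table=table, audit=audit)


def per_item_auc(
    item_scores: pd.DataFrame, groups: pd.Series, case_label: str = GROUP_ASD
) -> pd.Series:
    """Per-item ROC AUC of case vs non-case discrimination."""
    flags = (groups == case_label).to_numpy()
    if flags.all() or not flags.any():
        raise UsageError("need both case and non-case records")
    aucs = {
        c: empirical_roc(item_scores[c].to_numpy(), flags).auc
        for c in item_scores.columns
    }
    return pd.Series(aucs, name="auc")


def phase2_prune(
    item_scores: pd.DataFrame,
    groups: pd.Series,
    n_drop: int = 4,
    case_label: str = GROUP_ASD,
    subscales: Optional[Mapping] = None,
    n_lead: int = 5,
) -> ReductionReport:
    """Per-item ROC pruning on the psychiatric pilot sample.

    The ``n_drop`` items with the lowest AUC (case vs the remaining
    psychiatric records) are removed; survivors are re-ordered by
    :func:`reorder_items`. Ties resolve by ascending item id.
    """
    if n_drop >= item_scores.shape[1]:
        raise UsageError("n_drop must be smaller than the item count")
    aucs = per_item_auc(item_scores, groups, case_label)
    order = sorted(aucs.index, key=lambda c: (aucs[c], c))
    dropped_ids = order[:n_drop]
    kept = [c for c in item_scores.columns if c not in dropped_ids]
    new_order = reorder_items(kept, aucs.to_dict(), subscales=subscales, n_lead=n_lead)
    per_item = pd.DataFrame({"auc": aucs})
    per_item["dropped"] = per_item.index.isin(dropped_ids)
    audit = [
        f"phase2 per-item AUC: {dict(aucs.round(4))}",
        f"phase2 dropped (lowest {n_drop}): {dropped_ids}",
        f"phase2 final order: {new_order}",
    ]
    return ReductionReport(
        selected=new_order,
        dropped=[(i, float(aucs[i])) for i in dropped_ids],
        per_item=per_item,
        audit=audit,
    )


def reorder_items(
    items: Sequence,
    auc: Mapping,
    subscales: Optional[Mapping] = None,
    n_lead: int = 5,
) -> list:
    """Deterministic questionnaire ordering.

    The ``n_lead`` items with the highest AUC open the questionnaire in
    descending AUC order (ties by ascending id). The remainder is
    interleaved across subscales: repeatedly pick from the subscale with the
    most items left (ties by subscale name) that differs from the previous
    pick when feasible, taking each subscale's items best-AUC first. Without
    subscale labels the remainder simply continues in descending AUC order.
    """
    by_power = sorted(items, key=lambda i: (-auc[i], i))
    lead, rest = by_power[:n_lead], by_power[n_lead:]
    if not rest:
        return lead
    if subscales is None:
        return lead + rest
    pools: dict[object, list] = {}
    for i in rest:  # already in (-auc, id) order
        pools.setdefault(subscales[i], []).append(i)
    out = list(lead)
    prev = None
    while any(pools.values()):
        candidates = sorted(
            (s for s, p in pools.items() if p),
            key=lambda s: (-len(pools[s]), str(s)),
        )
        pick = next((s for s in candidates if s != prev), candidates[0])
        out.append(pools[pick].pop(0))
        prev = pick
    return out


# --------------------------------------------------------------------------
# phase 3: validation report
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Everything the validation phase computes on a scored cohort."""

    cohort: CohortResult
    group_summary: pd.DataFrame
    comparisons: dict[str, GroupComparison]       # control group -> vs-case test
    rocs: dict[str, ROCResult]                    # control group -> total-score ROC
    short_form_rocs: dict[str, ROCResult]
    operating_points: pd.DataFrame                # per control group, both cut-offs
    reliability: dict[str, ReliabilityResult]     # group (and "all") -> alpha
    subscale_reliability: pd.DataFrame            # group x subscale alpha
    factors: Optional[FactorSolution]             # case group excluded
    case_group: str
    warnings: list[str] = field(default_factory=list)


def evaluate_final(
    cohort: Sequence[ResponseRecord],
    instrument: InstrumentDefinition,
    case_group: str = GROUP_ASD,
    n_factors: Optional[int] = 3,
) -> ValidationReport:
    """Validate an instrument on a multi-group cohort.

    Invalid records are excluded throughout. Comparisons, ROC curves and
    operating points (at the total-score and short-form cut-offs) are
    computed case group vs each other group; reliability per group and
    overall; the exploratory factor analysis runs on the cohort minus the
    case group (with every case included the strong group separation
    collapses the structure onto a single factor).
    """
    result = batch_score(cohort, instrument)
    valid = result.valid_reports
    groups = sorted({r.group for r in valid})
    if case_group not in groups:
        raise UsageError(f"case group {case_group!r} absent from the cohort")
    warnings: list[str] = []

    totals = {g: np.array([r.total for r in valid if r.group == g]) for g in groups}
    shorts = {g: np.array([r.short_form for r in valid if r.group == g]) for g in groups}
    case_totals = totals[case_group]
    case_shorts = shorts[case_group]

    comparisons: dict[str, GroupComparison] = {}
    rocs: dict[str, ROCResult] = {}
    sf_rocs: dict[str, ROCResult] = {}
    op_rows = []
    for g in groups:
        if g == case_group:
            continue
        if totals[g].size == 0:
            warnings.append(f"group {g!r} empty after validity filtering; omitted")
            continue
        from .psychometrics import mann_whitney

        comparisons[g] = mann_whitney(case_totals, totals[g])
        pooled = np.concatenate([case_totals, totals[g]])
        labels = np.r_[np.ones(case_totals.size, bool), np.zeros(totals[g].size, bool)]
        rocs[g] = empirical_roc(pooled, labels)
        sf_pooled = np.concatenate([case_shorts, shorts[g]])
        sf_rocs[g] = empirical_roc(sf_pooled, labels)
        sens, spec = operating_point(pooled, labels, instrument.screen_cutoff)
        sf_sens, sf_spec = operating_point(sf_pooled, labels, instrument.short_form_cutoff)
        op_rows.append(
            {
                "control_group": g,
                "cutoff": instrument.screen_cutoff,
                "sensitivity": sens,
                "specificity": spec,
                "short_form_cutoff": instrument.short_form_cutoff,
                "short_form_sensitivity": sf_sens,
                "short_form_specificity": sf_spec,
            }
        )
    operating = pd.DataFrame(op_rows)

    # reliability per group and overall, on the item-score matrix
    mat, grp = score_matrix(cohort, instrument, valid_only=True)
    reliability: dict[str, ReliabilityResult] = {}
    sub_rows = []
    for g in ["all"] + groups:
        sel = mat if g == "all" else mat.loc[(grp == g).values]
        if sel.shape[0] < 3:
            warnings.append(f"group {g!r} too small for reliability; omitted")
            continue
        try:
            reliability[g] = cronbach_alpha(sel)
        except Exception as exc:
            warnings.append(f"reliability undefined for {g!r}: {exc}")
            continue
        row = {"group": g}
        for name, ids in instrument.subscales.items():
            if len(ids) < 2:
                continue
            try:
                row[name] = cronbach_alpha(sel[ids]).alpha
            except Exception:
                row[name] = np.nan
        sub_rows.append(row)
    subscale_rel = pd.DataFrame(sub_rows).set_index("group") if sub_rows else pd.DataFrame()

    # factor structure with the case group excluded
    factors = None
    non_case = mat.loc[(grp != case_group).values]
    if non_case.shape[0] > mat.shape[1]:
        try:
            factors = principal_factor_analysis(non_case, n_factors=n_factors)
        except Exception as exc:
            warnings.append(f"factor analysis degenerate: {exc}")
    else:
        warnings.append("too few non-case records for factor analysis; omitted")

    return ValidationReport(
        cohort=result,
        group_summary=result.summary,
        comparisons=comparisons,
        rocs=rocs,
        short_form_rocs=sf_rocs,
        operating_points=operating,
        reliability=reliability,
        subscale_reliability=subscale_rel,
        factors=factors,
        case_group=case_group,
        warnings=warnings,
    )
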
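"""Validation-report serialization and text rendering.

A :class:`~raads14.reduction.ValidationReport` serializes to a plain
mapping (YAML on disk, full precision) and renders to a fixed-layout text
report. Rendering is a pure function of the serialized mapping, so a
parsed report re-renders byte-identically. Display rounding: 2 decimals
for rates/AUC/r, 1 decimal for means and SDs.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import yaml

from .reduction import ValidationReport

__all__ = ["report_to_dict", "save_report", "load_report", "render_report"]


def _py(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_py(v) for v in x.tolist()]
    if isinstance(x, float) and np.isnan(x):
        return None
    if isinstance(x, dict):
        return {str(k): _py(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_py(v) for v in x]
    return x


def report_to_dict(report: ValidationReport) -> dict:
    """Serialize the validation report to a plain, YAML-safe mapping."""
    d: dict = {"case_group": report.case_group, "warnings": list(report.warnings)}
    d["group_summary"] = {
        str(g): _py(row.to_dict()) for g, row in report.group_summary.iterrows()
    }
    d["comparisons"] = {
        str(g): _py(
            {"n1": c.n1, "n2": c.n2, "U": c.U, "z": c.z, "p": c.p, "r": c.r}
        )
        for g, c in report.comparisons.items()
    }
    d["rocs"] = {str(g): {"auc": _py(r.auc)} for g, r in report.rocs.items()}
    d["short_form_rocs"] = {
        str(g): {"auc": _py(r.auc)} for g, r in report.short_form_rocs.items()
    }
    d["operating_points"] = _py(report.operating_points.to_dict(orient="records"))
    d["reliability"] = {
        str(g): _py({"alpha": r.alpha, "n_items": r.n_items, "n_subjects": r.n_subjects})
        for g, r in report.reliability.items()
    }
    d["subscale_reliability"] = {
        str(g): _py(row.to_dict()) for g, row in report.subscale_reliability.iterrows()
    }
    if report.factors is not None:
        f = report.factors
        d["factors"] = _py(
            {
                "n_factors": f.n_factors,
                "eigenvalues": f.eigenvalues,
                "variance_explained": f.variance_explained,
                "loadings": f.loadings,
                "item_keys": f.item_keys,
                "rotation": f.rotation,
            }
        )
    else:
        d["factors"] = None
    d["n_invalid"] = len(report.cohort.invalid)
    d["invalid_reasons"] = _py(
        {
            reason: sum(1 for r in report.cohort.invalid if r.invalid_reason == reason)
            for reason in sorted(
                {r.invalid_reason for r in report.cohort.invalid if r.invalid_reason}
            )
        }
    )
    return d


def save_report(report: ValidationReport, path) -> dict:
    doc = report_to_dict(report)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, allow_unicode=True)
    return doc


def load_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _fmt(x, nd: int) -> str:
    if x is None:
        return "NA"
    return f"{x:.{nd}f}"


def render_report(doc: Mapping | ValidationReport) -> str:
    """Fixed-layout text rendering of a (serialized) validation report."""
    if isinstance(doc, ValidationReport):
        doc = report_to_dict(doc)
    lines: list[str] = []
    add = lines.append
    case = doc["case_group"]
    add("Validation report")
    add("=================")
    add("")
    add("Group summaries (valid records), total score")
    add("group        n     mean    sd   median (range)")
    for g in sorted(doc["group_summary"]):
        s = doc["group_summary"][g]
        add(
            f"{g:<10} {int(s['n']):>4}  {_fmt(s['mean'], 1):>6}  "
            f"{_fmt(s['sd'], 1):>4}  {_fmt(s['median'], 1)} "
            f"({int(s['min'])}-{int(s['max'])})"
        )
    add("")
    add(f"Comparisons vs {case} (Mann-Whitney)")
    add("group        n1   n2        U       z      r")
    for g in sorted(doc["comparisons"]):
        c = doc["comparisons"][g]
        add(
            f"{g:<10} {c['n1']:>4} {c['n2']:>4} {c['U']:>8.1f} "
            f"{c['z']:>7.2f} {c['r']:>6.2f}"
        )
    add("")
    add(f"Discrimination of {case} (ROC AUC)")
    add("group        total-score AUC   short-form AUC")
    for g in sorted(doc["rocs"]):
        auc = doc["rocs"][g]["auc"]
        sf = doc["short_form_rocs"].get(g, {}).get("auc")
        add(f"{g:<10}   {_fmt(auc, 2):>13}   {_fmt(sf, 2):>14}")
    add("")
    add("Operating points at the screening cut-offs")
    add("group        cutoff  sens  spec   sf-cutoff  sf-sens  sf-spec")
    for row in sorted(doc["operating_points"], key=lambda r: str(r["control_group"])):
        add(
            f"{row['control_group']:<10}   {row['cutoff']:>4}  "
            f"{_fmt(row['sensitivity'], 2)}  {_fmt(row['specificity'], 2)}   "
            f"{row['short_form_cutoff']:>9}  {_fmt(row['short_form_sensitivity'], 2):>7}  "
            f"{_fmt(row['short_form_specificity'], 2):>7}"
        )
    add("")
    add("Reliability (Cronbach's alpha)")
    add("group        alpha     n")
    for g in sorted(doc["reliability"]):
        r = doc["reliability"][g]
        add(f"{g:<10}  {_fmt(r['alpha'], 2):>5}  {r['n_subjects']:>4}")
    if doc.get("subscale_reliability"):
        add("")
        add("Subscale alpha per group")
        subscales = sorted(
            {k for row in doc["subscale_reliability"].values() for k in row}
        )
        add("group        " + "  ".join(f"{s[:12]:>12}" for s in subscales))
        for g in sorted(doc["subscale_reliability"]):
            row = doc["subscale_reliability"][g]
            add(
                f"{g:<10}  "
                + "  ".join(f"{_fmt(row.get(s), 2):>12}" for s in subscales)
            )
    add("")
    if doc.get("factors"):
        f = doc["factors"]
        add(f"Factor solution excluding {case} ({f['n_factors']} factors, "
            f"rotation: {f['rotation']})")
        ve = ", ".join(_fmt(100 * v, 1) + "%" for v in f["variance_explained"])
        add(f"variance explained: {ve}")
        add("item    " + "  ".join(f"F{j + 1:>6}" for j in range(f["n_factors"])))
        for key, row in zip(f["item_keys"], f["loadings"]):
            add(f"{str(key):<6} " + "  ".join(f"{_fmt(v, 2):>7}" for v in row))
    else:
        add("Factor solution: not computed")
    add("")
    add(f"Invalid records: {doc['n_invalid']} {doc.get('invalid_reasons', {})}")
    if doc["warnings"]:
        add("")
        for w in doc["warnings"]:
            add(f"warning: {w}")
    add("")
    return "\n".join(lines)
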
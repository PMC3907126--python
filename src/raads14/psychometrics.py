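"""From-scratch psychometric kernel.

Rank-based group comparison (Mann-Whitney U with mid-ranks and tie-corrected
normal approximation), the r = |z|/sqrt(N) effect size, empirical ROC curves
and their exact equivalence with the U statistic, screening cut-off
selection, Cronbach's alpha with corrected item-total correlations, the
discrimination index used for short-form item selection, and exploratory
factor analysis by iterated principal-axis factoring with optional varimax
rotation.

Conventions
-----------
* Ties are handled by mid-ranks everywhere; the z approximation uses the
  tie-corrected variance and no continuity correction; p-values are
  two-sided normal probabilities.
* ``GroupComparison.U`` is the conventionally reported statistic
  min(U1, U2); ``u_case_loss`` (the number of case-control pairs the case
  loses, ties counted half) is the orientation :func:`auc_from_u` consumes,
  so that ``auc = 1 - u_case_loss/(n1*n2)`` holds for every dataset.
* z is oriented so that cases scoring higher than controls gives z < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateDataError, UsageError

__all__ = [
    "GroupComparison",
    "ROCResult",
    "ReliabilityResult",
    "DiscriminationScore",
    "FactorSolution",
    "mann_whitney",
    "effect_size_r",
    "empirical_roc",
    "auc_from_u",
    "operating_point",
    "select_cutoff",
    "cronbach_alpha",
    "corrected_item_total",
    "discrimination_index",
    "principal_factor_analysis",
    "varimax",
    "tucker_congruence",
]


# --------------------------------------------------------------------------
# rank test and effect size
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Mann-Whitney comparison of case scores (group 1) vs control scores."""

    n1: int
    n2: int
    U: float            # min(U1, U2), the conventionally reported statistic
    u_case_loss: float  # pairs where the case scores lower (+ half the ties)
    z: float            # tie-corrected normal deviate; cases higher -> z < 0
    p: float            # two-sided
    r: float            # |z| / sqrt(n1 + n2)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Mann-Whitney U test of ``x`` (cases) vs ``y`` (controls).

    Mid-ranks for ties; z from the tie-corrected variance without continuity
    correction; r = |z|/sqrt(n1+n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise UsageError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # pairs the case wins (+ half ties)
    u2 = n1 * n2 - u1              # pairs the case loses (+ half ties)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var > 0:
        z = (u2 - mu) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * norm.sf(abs(z)) if var > 0 else 1.0
    return GroupComparison(
        n1=n1,
        n2=n2,
        U=float(min(u1, u2)),
        u_case_loss=float(u2),
        z=float(z),
        p=float(min(p, 1.0)),
        r=effect_size_r(z, n),
    )


def effect_size_r(z: float, N: int) -> float:
    """Rank-test effect size r = |z| / sqrt(N); small/medium/large at
    0.1/0.3/0.5 by convention."""
    if N < 1:
        raise UsageError("N must be at least 1")
    return float(abs(z) / np.sqrt(N))


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC over the rule "score >= threshold -> positive"."""

    thresholds: np.ndarray   # ascending distinct score values
    sensitivity: np.ndarray  # per threshold, non-increasing in threshold
    specificity: np.ndarray  # per threshold, non-decreasing in threshold
    auc: float


def _split_classes(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise UsageError("scores and labels must have equal length")
    cases = scores[labels]
    controls = scores[~labels]
    if cases.size == 0 or controls.size == 0:
        raise UsageError("both classes must be present")
    return cases, controls


def empirical_roc(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """One operating point per distinct score; AUC by trapezoidal
    integration over (1-specificity, sensitivity), which with mid-rank tie
    handling equals the U-based AUC exactly."""
    cases, controls = _split_classes(scores, labels)
    thr = np.unique(np.concatenate([cases, controls]))  # ascending
    sens = np.array([(cases >= t).mean() for t in thr])
    spec = np.array([(controls < t).mean() for t in thr])
    # integrate from the strictest rule (no positives) to the laxest
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, sensitivity=sens, specificity=spec, auc=auc)


def auc_from_u(U: float, n1: int, n2: int) -> float:
    """AUC from the case-loss-oriented Mann-Whitney statistic:
    ``auc = 1 - U/(n1*n2)`` (U small when cases score higher)."""
    if n1 < 1 or n2 < 1:
        raise UsageError("group sizes must be positive")
    if not 0 <= U <= n1 * n2:
        raise UsageError(f"U={U} outside [0, {n1 * n2}]")
    return 1.0 - U / (n1 * n2)


def operating_point(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule "score >= threshold"."""
    cases, controls = _split_classes(scores, labels)
    return float((cases >= threshold).mean()), float((controls < threshold).mean())


def select_cutoff(
    scores: Sequence[float],
    labels: Sequence[bool],
    min_sensitivity: float = 0.93,
    rule: str = "highest",
) -> int:
    """Screening cut-off: the integer threshold attaining sensitivity >=
    ``min_sensitivity``.

    Sensitivity is non-increasing in the threshold, so the qualifying
    thresholds form an interval reaching down to the minimum score. The
    default rule returns the *highest* qualifying threshold — the "lowest
    score" that still labels >= 93% of cases positive (this is the reading
    that yields 14 for the bundled screen rather than the degenerate minimum
    score). ``rule="lowest"`` returns the other endpoint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases = scores[labels]
    if cases.size == 0:
        raise UsageError("case group is empty")
    lo = int(np.floor(scores.min()))
    hi = int(np.ceil(scores.max())) + 1
    qualifying = [
        t for t in range(lo, hi + 1) if (cases >= t).mean() >= min_sensitivity
    ]
    if not qualifying:
        raise UsageError("no threshold attains the required sensitivity")
    if rule == "highest":
        return max(qualifying)
    if rule == "lowest":
        return min(qualifying)
    raise UsageError(f"unknown rule: {rule!r}")


# --------------------------------------------------------------------------
# reliability
# --------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    alpha: float
    item_total: dict          # item key -> corrected item-total correlation
    n_items: int
    n_subjects: int


def _as_matrix(item_matrix):
    import pandas as pd

    if isinstance(item_matrix, pd.DataFrame):
        return item_matrix.to_numpy(dtype=float), list(item_matrix.columns)
    m = np.asarray(item_matrix, dtype=float)
    return m, list(range(m.shape[1]))


def cronbach_alpha(item_matrix) -> ReliabilityResult:
    """Cronbach's alpha and corrected item-total correlations.

    alpha = k/(k-1) * (1 - sum(item variances)/variance(total)); the
    corrected item-total correlation of item j is its Pearson correlation
    with the sum of the remaining items. Sample variances (ddof=1).
    """
    m, keys = _as_matrix(item_matrix)
    n, k = m.shape
    if k < 2:
        raise UsageError("alpha requires at least 2 items")
    if n < 3:
        raise UsageError("alpha requires at least 3 subjects")
    total = m.sum(axis=1)
    var_total = total.var(ddof=1)
    if var_total <= 0:
        raise DegenerateDataError("total score has zero variance; alpha undefined")
    alpha = k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / var_total)

    item_total = {}
    for j, key in enumerate(keys):
        rest = total - m[:, j]
        item_total[key] = _safe_pearson(m[:, j], rest)
    return ReliabilityResult(
        alpha=float(alpha), item_total=item_total, n_items=k, n_subjects=n
    )


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.cov(a, b, ddof=1)[0, 1] / (sa * sb))


def corrected_item_total(item: np.ndarray, others_total: np.ndarray) -> float:
    """Pearson correlation of an item with the sum of the other items."""
    return _safe_pearson(np.asarray(item, float), np.asarray(others_total, float))


# --------------------------------------------------------------------------
# discrimination index
# --------------------------------------------------------------------------

@dataclass
class DiscriminationScore:
    """Item-selection score: point-biserial group effect x corrected
    item-total correlation within the item's domain."""

    item_id: object
    r_pb: float
    r_it: float
    index: float
    defined: bool = True


def discrimination_index(
    item_scores: Sequence[float],
    group_flags: Sequence[bool],
    domain_matrix,
    item_key=None,
) -> DiscriminationScore:
    """Discrimination index of one item.

    ``r_pb`` is the Pearson (point-biserial) correlation between the item
    score and the binary case indicator; ``r_it`` is the corrected
    item-total correlation of the item within ``domain_matrix`` (the score
    matrix of every item in the item's domain, this item included). A
    zero-variance item yields an undefined, flagged score.
    """
    item = np.asarray(item_scores, dtype=float)
    flags = np.asarray(group_flags, dtype=float)
    dm, keys = _as_matrix(domain_matrix)
    if item.size != flags.size or dm.shape[0] != item.size:
        raise UsageError("item scores, flags and domain matrix sizes disagree")
    if item.std(ddof=1) == 0:
        return DiscriminationScore(item_key, np.nan, np.nan, np.nan, defined=False)
    r_pb = _safe_pearson(item, flags)
    # the domain matrix includes the item itself; correct by subtracting it
    domain_total = dm.sum(axis=1) - item
    r_it = _safe_pearson(item, domain_total)
    defined = np.isfinite(r_pb) and np.isfinite(r_it)
    idx = r_pb * r_it if defined else np.nan
    return DiscriminationScore(item_key, r_pb, r_it, idx, defined=bool(defined))


# --------------------------------------------------------------------------
# exploratory factor analysis
# --------------------------------------------------------------------------

@dataclass
class FactorSolution:
    """Principal-axis factoring solution on the item correlation matrix."""

    eigenvalues: np.ndarray           # reduced-matrix eigenvalues, descending
    loadings: np.ndarray              # item x factor (rotated if rotation set)
    loadings_unrotated: np.ndarray
    variance_explained: np.ndarray    # lambda_i / n_items per retained factor
    n_factors: int
    communalities: np.ndarray
    rotation: Optional[str] = None
    converged: bool = True
    item_keys: list = field(default_factory=list)


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Raw varimax rotation (SVD algorithm); column signs fixed so each
    factor's loading sum is non-negative."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (Lr @ np.diag((Lr**2).sum(axis=0))) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    out = L @ R
    signs = np.sign(out.sum(axis=0))
    signs[signs == 0] = 1.0
    return out * signs


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return float("nan")
    return float(abs(a @ b) / denom)


def principal_factor_analysis(
    item_matrix,
    n_factors: Optional[int] = None,
    rotate: Optional[str] = "varimax",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> FactorSolution:
    """Iterated principal-axis factoring of the item correlation matrix.

    Initial communalities are squared multiple correlations; each iteration
    eigendecomposes the reduced correlation matrix, takes the leading
    ``n_factors`` components as loadings, and updates the communalities,
    until the largest communality change falls below ``tol``. When
    ``n_factors`` is None it is set once to the number of reduced-matrix
    eigenvalues at least as large as their mean (the scree judgment is a
    parameter, not a rule the data dictate). ``variance_explained`` is
    lambda_i / n_items.
    """
    m, keys = _as_matrix(item_matrix)
    n, k = m.shape
    if k < 3:
        raise UsageError("factor analysis requires at least 3 items")
    if n <= k:
        raise UsageError("need more subjects than items")
    if np.any(m.std(axis=0, ddof=1) == 0):
        raise DegenerateDataError("zero-variance item; correlation matrix singular")
    R = np.corrcoef(m, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("singular correlation matrix") from exc
    h2 = 1.0 - 1.0 / np.diag(Rinv)  # squared multiple correlations
    h2 = np.clip(h2, 0.0, 0.999)

    m_factors = n_factors
    converged = False
    loadings = None
    evals = None
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, v = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        if m_factors is None:
            m_factors = max(1, int((w >= w.mean()).sum()))
        lam = np.clip(w[:m_factors], 0.0, None)
        loadings = v[:, :m_factors] * np.sqrt(lam)
        h2_new = np.clip((loadings**2).sum(axis=1), 0.0, 0.999)
        evals = w
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            converged = True
            break
        h2 = h2_new

    # fix loading signs for determinism (largest-magnitude loading positive)
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] = -loadings[:, j]

    rotated = loadings
    if rotate == "varimax":
        rotated = varimax(loadings)
    elif rotate is not None:
        raise UsageError(f"unknown rotation: {rotate!r}")

    var_explained = np.clip(evals[:m_factors], 0.0, None) / k
    return FactorSolution(
        eigenvalues=evals,
        loadings=rotated,
        loadings_unrotated=loadings,
        variance_explained=var_explained,
        n_factors=m_factors,
        communalities=h2,
        rotation=rotate,
        converged=converged,
        item_keys=keys,
    )
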
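"""Synthetic Likert-cohort generator.

Responses are drawn from a cumulative-logit graded-response model: each
subject carries a standardized latent trait made of a general component plus
three correlated subscale components, and each item maps the trait to an
ordinal 0-3 score through a logistic link with item-specific discrimination
and three ordered thresholds. Reverse-phrased items emit the complementary
category so that instrument scoring recovers the model score. Contamination
(straight-lining, per-item missingness) is applied last.

The calibrated default configuration reproduces, by a deterministic
coarse-grid + local-refinement search on the group trait parameters, the
four diagnostic-group total-score profiles the screen was validated on:
ASD 30.8 +/- 8.6 (left-skewed), ADHD 15.4 +/- 9.3, other psychiatric
disorders 12.6 +/- 9.3, and non-psychiatric controls 3.9 +/- 4.6
(right-skewed), on the 0-42 total-score scale.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

from .errors import UsageError
from .instrument import (
    DOMAIN_CIRCUMSCRIBED,
    DOMAIN_LANGUAGE,
    DOMAIN_SENSORY,
    DOMAIN_SOCIAL,
    GROUP_ADHD,
    GROUP_ASD,
    GROUP_NONPSYCH,
    GROUP_OPD,
    InstrumentDefinition,
    ItemDefinition,
    ResponseRecord,
    raads14,
)

__all__ = [
    "GroupProfile",
    "ItemModel",
    "SimulationConfig",
    "generate_cohort",
    "calibrate_defaults",
    "calibrate_profiles",
    "default_items",
    "pilot_items",
    "bank_items",
    "instrument_for",
    "draw_total_scores",
    "TABLE_TARGETS",
]

# Validation-study total-score targets per group: (mean, sd, n).
TABLE_TARGETS: dict[str, tuple[float, float, int]] = {
    GROUP_ASD: (30.8, 8.6, 77),
    GROUP_ADHD: (15.4, 9.3, 301),
    GROUP_OPD: (12.6, 9.3, 69),
    GROUP_NONPSYCH: (3.9, 4.6, 590),
}

_DEFAULT_LABELS = [
    "never true",
    "true only when I was younger than 16",
    "true only now",
    "true now and when I was young",
]  # index == forward score


@dataclass
class GroupProfile:
    """Latent-trait location/scale (standardized units) and size of one group."""

    label: str
    trait_mean: float
    trait_sd: float
    n: int

    def __post_init__(self):
        if self.trait_sd <= 0:
            raise UsageError("trait_sd must be positive")
        if self.n < 1:
            raise UsageError("group size must be at least 1")


@dataclass
class ItemModel:
    """Graded-response parameters of one item."""

    item_id: int
    discrimination: float
    thresholds: tuple[float, float, float]
    subscale: str
    factor_loading: float = 0.4  # share of trait variance from the subscale factor
    domain: Optional[str] = None
    reversed: bool = False

    def __post_init__(self):
        if self.discrimination <= 0:
            raise UsageError("discrimination must be positive")
        t = tuple(self.thresholds)
        if not (t[0] < t[1] < t[2]):
            raise UsageError("thresholds must be strictly increasing")
        self.thresholds = t
        if not 0.0 <= self.factor_loading <= 1.0:
            raise UsageError("factor_loading must lie in [0, 1]")


@dataclass
class SimulationConfig:
    profiles: list[GroupProfile]
    items: list[ItemModel]
    seed: int = 2013
    straight_line_rate: float = 0.0
    missing_rate: float = 0.0
    subscale_cor: float = 0.5
    category_labels: Sequence[str] = field(default_factory=lambda: list(_DEFAULT_LABELS))

    def __post_init__(self):
        for rate in (self.straight_line_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise UsageError("contamination rates must lie in [0, 1]")
        if not 0.0 <= self.subscale_cor <= 1.0:
            raise UsageError("subscale_cor must lie in [0, 1]")
        if len(self.category_labels) != 4:
            raise UsageError("exactly 4 category labels are required")


# --------------------------------------------------------------------------
# item banks
# --------------------------------------------------------------------------

def default_items() -> list[ItemModel]:
    """The 14-item bank mirroring the bundled screen: subscale/domain
    assignments and the reverse flag follow the instrument; the short-form
    items (1-5) are given the strongest discrimination."""
    inst = raads14()
    bases = np.linspace(-0.9, 0.5, inst.n_items)
    items = []
    for it, base in zip(inst.items, bases):
        a = 1.8 if it.short_form else 1.3
        items.append(
            ItemModel(
                item_id=it.item_id,
                discrimination=a,
                thresholds=(base, base + 0.8, base + 1.6),
                subscale=it.subscale,
                factor_loading=0.4,
                domain=it.original_domain,
                reversed=it.reversed,
            )
        )
    return items


def pilot_items() -> list[ItemModel]:
    """An 18-item pilot bank: the 14 default items plus 4 weakly
    discriminating items filling the per-domain pilot quotas
    (circumscribed interests 4, language 2, social relatedness 8,
    sensory motor 4)."""
    items = default_items()
    extras = [
        (15, DOMAIN_CIRCUMSCRIBED, "mentalizing_deficits"),
        (16, DOMAIN_CIRCUMSCRIBED, "mentalizing_deficits"),
        (17, DOMAIN_SOCIAL, "social_anxiety"),
        (18, DOMAIN_SENSORY, "sensory_reactivity"),
    ]
    for item_id, domain, subscale in extras:
        items.append(
            ItemModel(
                item_id=item_id,
                discrimination=0.35,
                thresholds=(-0.5, 0.4, 1.3),
                subscale=subscale,
                factor_loading=0.2,
                domain=domain,
            )
        )
    return items


def bank_items(
    n_per_domain: Mapping[str, int],
    noise_per_domain: Mapping[str, int] | int = 0,
    seed: int = 7,
) -> list[ItemModel]:
    """A synthetic item bank with ``n_per_domain`` informative items per
    domain plus purely uninformative (near-zero discrimination) ones.

    Informative discriminations are spread deterministically over
    [0.8, 2.0]; thresholds over a [-1, 0.6] base grid. Subscales default to
    the domain name (one factor per domain).
    """
    rng = np.random.default_rng(seed)
    if isinstance(noise_per_domain, int):
        noise_per_domain = {d: noise_per_domain for d in n_per_domain}
    items: list[ItemModel] = []
    next_id = 1
    for domain, n_inf in n_per_domain.items():
        n_noise = noise_per_domain.get(domain, 0)
        a_inf = np.linspace(0.8, 2.0, max(n_inf, 1))
        for j in range(n_inf + n_noise):
            informative = j < n_inf
            a = float(a_inf[j]) if informative else 0.05
            base = float(rng.uniform(-1.0, 0.6))
            items.append(
                ItemModel(
                    item_id=next_id,
                    discrimination=a,
                    thresholds=(base, base + 0.8, base + 1.6),
                    subscale=domain,
                    factor_loading=0.3,
                    domain=domain,
                )
            )
            next_id += 1
    return items


def instrument_for(
    items: Sequence[ItemModel],
    name: str = "synthetic bank",
    short_form_ids: Sequence[int] = (),
) -> InstrumentDefinition:
    """A generic scoring instrument for a simulated bank (synthetic item
    texts; same 4-category duration scale as the bundled screen)."""
    defs = [
        ItemDefinition(
            item_id=i + 1,
            text=f"synthetic item {im.item_id}",
            reversed=im.reversed,
            original_domain=im.domain,
            subscale=im.subscale,
            short_form=im.item_id in set(short_form_ids),
        )
        for i, im in enumerate(items)
    ]
    return InstrumentDefinition(
        name=name,
        items=defs,
        categories=list(_DEFAULT_LABELS),
        forward_scores={lab: s for s, lab in enumerate(_DEFAULT_LABELS)},
    )


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _item_scores(
    profile_mean: float,
    profile_sd: float,
    items: Sequence[ItemModel],
    subscale_cor: float,
    g: np.ndarray,
    c: np.ndarray,
    e: np.ndarray,
    u: np.ndarray,
    subscale_index: Mapping[str, int],
) -> np.ndarray:
    """Vectorized graded-response scores (subjects x items), 0-3, trait-aligned."""
    rho = subscale_cor
    d = np.sqrt(rho) * c[:, None] + np.sqrt(1.0 - rho) * e  # (n, n_subscales)
    n = g.size
    k = len(items)
    scores = np.empty((n, k), dtype=np.int64)
    for j, im in enumerate(items):
        v = im.factor_loading
        theta = profile_mean + profile_sd * (
            np.sqrt(1.0 - v) * g + np.sqrt(v) * d[:, subscale_index[im.subscale]]
        )
        b = np.asarray(im.thresholds)
        cum = expit(im.discrimination * (theta[:, None] - b[None, :]))  # P(score>=k)
        scores[:, j] = (u[:, j, None] <= cum).sum(axis=1)
    return scores


def _group_draws(rng: np.random.Generator, n: int, n_subscales: int, k: int):
    g = rng.standard_normal(n)
    c = rng.standard_normal(n)
    e = rng.standard_normal((n, n_subscales))
    u = rng.random((n, k))
    return g, c, e, u


def generate_cohort(config: SimulationConfig) -> list[ResponseRecord]:
    """Draw one cohort. Fully reproducible from ``config.seed``; the emitted
    answers are category labels (reverse-phrased items emit the
    complementary category)."""
    rng = np.random.default_rng(config.seed)
    subscales = sorted({im.subscale for im in config.items})
    sub_ix = {s: i for i, s in enumerate(subscales)}
    labels = list(config.category_labels)
    k = len(config.items)
    records: list[ResponseRecord] = []
    for profile in config.profiles:
        g, c, e, u = _group_draws(rng, profile.n, len(subscales), k)
        scores = _item_scores(
            profile.trait_mean,
            profile.trait_sd,
            config.items,
            config.subscale_cor,
            g,
            c,
            e,
            u,
            sub_ix,
        )
        straight = rng.random(profile.n) < config.straight_line_rate
        straight_cat = rng.integers(0, 4, size=profile.n)
        miss = rng.random((profile.n, k)) < config.missing_rate
        for i in range(profile.n):
            answers: dict[int, Optional[str]] = {}
            for j, im in enumerate(config.items):
                if straight[i]:
                    s_emit = int(straight_cat[i])
                else:
                    s = int(scores[i, j])
                    s_emit = 3 - s if im.reversed else s
                answers[im.item_id] = None if miss[i, j] else labels[s_emit]
            records.append(
                ResponseRecord(
                    subject_id=f"{profile.label}-{i + 1:05d}",
                    group=profile.label,
                    answers=answers,
                )
            )
    return records


def simulate_totals(
    config: SimulationConfig, instrument: Optional[InstrumentDefinition] = None
) -> dict[str, np.ndarray]:
    """Per-group total scores of a generated cohort (no contamination
    filtering; intended for calibration and quick checks)."""
    from .instrument import score_record

    inst = instrument if instrument is not None else instrument_for(config.items)
    totals: dict[str, list[int]] = {}
    for rec in generate_cohort(config):
        totals.setdefault(rec.group, []).append(
            score_record(rec, inst).total
        )
    return {g: np.asarray(v) for g, v in totals.items()}


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

_CAL_SEED = 20130001  # internal, fixed: calibration is deterministic


def _calibration_totals(
    mu: float,
    sigma: float,
    items: Sequence[ItemModel],
    subscale_cor: float,
    draws,
    sub_ix,
) -> np.ndarray:
    g, c, e, u = draws
    scores = _item_scores(mu, sigma, items, subscale_cor, g, c, e, u, sub_ix)
    # trait-aligned scores: reversal only permutes the emitted category, the
    # recovered score is unchanged, so totals are computed directly
    return scores.sum(axis=1)


def calibrate_profiles(
    targets: Mapping[str, tuple[float, float, int]],
    items: Sequence[ItemModel],
    subscale_cor: float = 0.5,
) -> list[GroupProfile]:
    """Deterministic moment-matching of group trait parameters.

    For each group a coarse grid over (trait_mean, trait_sd) is scored by the
    squared distance between simulated and target total-score mean/SD using
    common random numbers, then refined locally on a finer grid with a larger
    calibration sample. Independent of any user-facing seed.
    """
    subscales = sorted({im.subscale for im in items})
    sub_ix = {s: i for i, s in enumerate(subscales)}
    k = len(items)

    def best_on(grid_mu, grid_sigma, draws):
        best = None
        for mu in grid_mu:
            for sigma in grid_sigma:
                totals = _calibration_totals(mu, sigma, items, subscale_cor, draws, sub_ix)
                loss = (totals.mean() - m_t) ** 2 + (totals.std(ddof=1) - s_t) ** 2
                if best is None or loss < best[0]:
                    best = (loss, mu, sigma)
        return best[1], best[2]

    profiles = []
    for label, (m_t, s_t, n) in targets.items():
        rng = np.random.default_rng(_CAL_SEED)
        coarse_draws = _group_draws(rng, 5000, len(subscales), k)
        fine_draws = _group_draws(rng, 20000, len(subscales), k)
        mu, sigma = best_on(
            np.arange(-3.5, 3.51, 0.25), np.arange(0.3, 2.41, 0.15), coarse_draws
        )
        mu, sigma = best_on(
            np.arange(mu - 0.25, mu + 0.26, 0.05),
            np.arange(max(sigma - 0.15, 0.05), sigma + 0.16, 0.03),
            fine_draws,
        )
        profiles.append(
            GroupProfile(label=label, trait_mean=round(mu, 3), trait_sd=round(sigma, 3), n=n)
        )
    return profiles


@functools.lru_cache(maxsize=1)
def _calibrated_profiles_cached() -> tuple[GroupProfile, ...]:
    return tuple(calibrate_profiles(TABLE_TARGETS, default_items()))


def calibrate_defaults(
    seed: int = 2013,
    n_per_group: Optional[int] = None,
    straight_line_rate: float = 0.03,
    missing_rate: float = 0.01,
) -> SimulationConfig:
    """The bundled calibrated configuration: four diagnostic groups at the
    validation-study total-score moments, default group sizes as in the
    validation sample (77/301/69/590), ~3% straight-liners and 1% per-item
    missingness."""
    profiles = [replace(p) for p in _calibrated_profiles_cached()]
    if n_per_group is not None:
        profiles = [replace(p, n=n_per_group) for p in profiles]
    return SimulationConfig(
        profiles=profiles,
        items=default_items(),
        seed=seed,
        straight_line_rate=straight_line_rate,
        missing_rate=missing_rate,
    )


def config_from_yaml(path) -> SimulationConfig:
    """Load a simulation config; omitted items default to the bundled
    14-item bank, omitted profiles to the calibrated group profiles."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    items = (
        [ItemModel(**{**d, "thresholds": tuple(d["thresholds"])}) for d in doc["items"]]
        if "items" in doc
        else default_items()
    )
    profiles = (
        [GroupProfile(**d) for d in doc["profiles"]]
        if "profiles" in doc
        else [replace(p) for p in _calibrated_profiles_cached()]
    )
    kwargs = {
        k: doc[k]
        for k in ("seed", "straight_line_rate", "missing_rate", "subscale_cor",
                  "category_labels")
        if k in doc
    }
    return SimulationConfig(profiles=profiles, items=items, **kwargs)


def draw_total_scores(
    mean: float,
    sd: float,
    n: int,
    seed: int,
    bounds: tuple[int, int] = (0, 42),
) -> np.ndarray:
    """Integer total scores from a normal profile, rounded and clipped to
    the instrument's score range — a direct generator for quick
    sensitivity/specificity checks at printed group moments."""
    if n < 1:
        raise UsageError("n must be at least 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(mean, sd, size=n)
    return np.clip(np.rint(x), bounds[0], bounds[1]).astype(int)
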
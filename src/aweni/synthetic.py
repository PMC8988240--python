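"""Synthetic multi-site survey generator.

Emulates the statistical structure the abbreviation pipeline assumes: a
latent empowerment factor per respondent (with site-level shifts, so that
some sites are systematically less empowered), binary indicators drawn from
a logistic item model on that factor with shared within-theme and (weaker)
within-DD perturbations — indicators measuring one theme co-move most, and
indicators in one domain-dimension co-move more than across DDs, the way
thematically organised survey items do — and outcomes —
BMI and a 0-10 food-group count — positively associated with empowerment.

The defaults reproduce the study conditions the pipeline is meant for:
five sites, two "training-like" sites of 971 respondents total shifted
down on the latent scale and three validation sites of 1427 (n = 2398),
with overall empowerment prevalence calibrated to about 45%.

Everything is deterministic given the config's seed; the same config
always yields a byte-identical table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .index_core import compute_scores
from .schema import IndexSchema, get_fixture

__all__ = ["SiteSpec", "GeneratorConfig", "default_config", "generate_survey"]

log = logging.getLogger(__name__)

GROUPS = ("index_woman", "spouse", "mother_in_law", "older_woman")

_AGE_RANGES = {
    "index_woman": (18, 36),
    "spouse": (21, 51),
    "mother_in_law": (40, 71),
    "older_woman": (70, 86),
}


@dataclass(frozen=True)
class SiteSpec:
    """One survey site: label, sample size, shift on the latent scale."""

    name: str
    n: int
    shift: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All parameters of the synthetic survey.

    ``difficulty_base`` and ``difficulty_spread`` define the per-indicator
    intercepts a_j (spread evenly within each DD) unless ``intercepts``
    overrides them; ``slope`` is the common loading b_j on the latent
    factor unless ``slopes`` overrides it.  ``theme_sd`` and ``dd_sd``
    scale the shared within-theme and within-DD perturbations.  Outcome
    parameters are on their natural
    scales: BMI in kg/m^2, the MDD effect on the probit scale of the
    per-food-group success probability.
    """

    sites: tuple[SiteSpec, ...]
    latent_sd: float = 1.0
    dd_sd: float = 0.3
    theme_sd: float = 0.55
    slope: float = 1.2
    difficulty_base: float = 0.0
    difficulty_spread: float = 0.7
    intercepts: Mapping[str, float] | None = None
    slopes: Mapping[str, float] | None = None
    missing_rate: float = 0.0
    bmi_intercept: float = 19.5
    bmi_effect: float = 0.8
    bmi_noise_sd: float = 1.8
    group_effects: Mapping[str, float] = field(
        default_factory=lambda: {"spouse": 0.8, "mother_in_law": 0.6, "older_woman": -0.3}
    )
    mdd_intercept: float = 0.0
    mdd_effect: float = 0.35
    group_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "index_woman": 0.41,
            "spouse": 0.20,
            "mother_in_law": 0.20,
            "older_woman": 0.19,
        }
    )
    pregnancy_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("at least one site is required")
        if any(s.n < 1 for s in self.sites):
            raise ValueError("every site needs n >= 1")
        if len({s.name for s in self.sites}) != len(self.sites):
            raise ValueError("site names must be unique")
        if self.latent_sd <= 0 or self.bmi_noise_sd <= 0:
            raise ValueError("latent_sd and bmi_noise_sd must be positive")
        if self.dd_sd < 0 or self.theme_sd < 0:
            raise ValueError("dd_sd and theme_sd must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.pregnancy_rate <= 1.0):
            raise ValueError("pregnancy_rate must lie in [0, 1]")
        mix = dict(self.group_mix)
        if set(mix) != set(GROUPS):
            raise ValueError(f"group_mix must assign all of {GROUPS}")
        if any(v < 0 for v in mix.values()) or not np.isclose(sum(mix.values()), 1.0):
            raise ValueError("group_mix must be non-negative and sum to 1")


def default_config(seed: int = 0) -> GeneratorConfig:
    """The calibrated default: 5 sites, n=2398, ~45% empowered overall.

    Sites A and B (n = 971 together) sit 0.5 sd below the latent mean and
    play the role of the less-empowered training region; sites C-E
    (n = 1427) sit 0.34 sd above it.  ``difficulty_base`` was calibrated
    once, by a numerical solve under these defaults, so that the overall
    share with composite score >= 0.5 is approximately 45%.
    """
    return GeneratorConfig(
        sites=(
            SiteSpec("siteA", 486, -0.50),
            SiteSpec("siteB", 485, -0.50),
            SiteSpec("siteC", 476, 0.34),
            SiteSpec("siteD", 476, 0.34),
            SiteSpec("siteE", 475, 0.34),
        ),
        difficulty_base=-0.17,
        seed=seed,
    )


def _indicator_params(config: GeneratorConfig, schema: IndexSchema):
    by_dd = schema.indicators_by_dd()
    a = {}
    for dd, names in by_dd.items():
        m = len(names)
        offsets = np.linspace(-1.0, 1.0, m) if m > 1 else np.zeros(1)
        for name, off in zip(names, offsets):
            a[name] = config.difficulty_base + config.difficulty_spread * off
    if config.intercepts is not None:
        a.update({k: float(v) for k, v in config.intercepts.items()})
    b = {name: config.slope for name in schema.names}
    if config.slopes is not None:
        b.update({k: float(v) for k, v in config.slopes.items()})
    return a, b


def generate_survey(
    config: GeneratorConfig, schema: IndexSchema | None = None
) -> pd.DataFrame:
    """Draw one survey table under ``config``.

    Returns a DataFrame with the standard metadata columns
    (respondent_id, site, group, age, pregnant, bmi, food_groups) followed
    by one {0,1} column per schema indicator (NaN where masked missing).
    """
    schema = schema if schema is not None else get_fixture("weni33")
    rng = np.random.default_rng(config.seed)

    site_labels = np.concatenate([[s.name] * s.n for s in config.sites])
    shifts = np.concatenate([[s.shift] * s.n for s in config.sites])
    n = site_labels.size
    theta = rng.normal(shifts, config.latent_sd)

    dds = schema.dds
    dd_index = {dd: i for i, dd in enumerate(dds)}
    themes = list(dict.fromkeys((ind.dd, ind.theme) for ind in schema.indicators))
    theme_index = {t: i for i, t in enumerate(themes)}
    u_dd = rng.normal(0.0, config.dd_sd, size=(n, len(dds)))
    u_theme = rng.normal(0.0, config.theme_sd, size=(n, len(themes)))

    a, b = _indicator_params(config, schema)
    a_vec = np.array([a[ind.name] for ind in schema.indicators])
    b_vec = np.array([b[ind.name] for ind in schema.indicators])
    dd_col = np.array([dd_index[ind.dd] for ind in schema.indicators])
    theme_col = np.array(
        [theme_index[(ind.dd, ind.theme)] for ind in schema.indicators]
    )

    logits = (
        a_vec[None, :]
        + theta[:, None] * b_vec[None, :]
        + u_dd[:, dd_col]
        + u_theme[:, theme_col]
    )
    prob = expit(logits)
    n_clipped = int(np.sum((prob < 1e-9) | (prob > 1 - 1e-9)))
    if n_clipped:
        log.warning("%d indicator probabilities clipped away from {0, 1}", n_clipped)
    prob = np.clip(prob, 1e-9, 1 - 1e-9)
    X = rng.binomial(1, prob).astype(float)

    groups = rng.choice(GROUPS, size=n, p=[config.group_mix[g] for g in GROUPS])
    lo = np.array([_AGE_RANGES[g][0] for g in groups])
    hi = np.array([_AGE_RANGES[g][1] for g in groups])
    age = lo + np.floor(rng.random(n) * (hi - lo)).astype(int)
    pregnant = (groups == "index_woman") & (rng.random(n) < config.pregnancy_rate)

    frame = pd.DataFrame(X, columns=list(schema.names))
    scores = compute_scores(frame, schema)
    status = scores["status"].to_numpy()

    geff = np.array([config.group_effects.get(g, 0.0) for g in groups])
    bmi = (
        config.bmi_intercept
        + config.bmi_effect * status
        + geff
        + rng.normal(0.0, config.bmi_noise_sd, n)
    )
    food_groups = rng.binomial(10, ndtr(config.mdd_intercept + config.mdd_effect * theta))

    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = np.where(mask, np.nan, X)
        frame = pd.DataFrame(X, columns=list(schema.names))

    out = pd.DataFrame(
        {
            "respondent_id": [f"r{i:06d}" for i in range(n)],
            "site": site_labels,
            "group": groups,
            "age": age,
            "pregnant": pregnant,
            "bmi": np.round(bmi, 2),
            "food_groups": food_groups,
        }
    )
    return pd.concat([out, frame], axis=1)
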
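"""Synthetic stated-preference generator for bicyclist route choice.

Emulates the survey design the estimator targets: each respondent faces five
scenarios of three unlabeled route alternatives described by eight attributes
(grade, traffic volume, roadway type, infrastructure continuity and
segregation, mean and maximum NO2 exposure in ppb, travel time in minutes).
Each scenario shows exactly five attributes: the three core ones (mean
exposure, max exposure, travel time) plus one roadway and one bike-route
attribute rotated round-robin across respondents, mirroring the partitioned
design whose blocks are pooled at estimation time.

Choices are simulated from a user-specified latent-class truth: a segment is
drawn per respondent from the membership logit, respondent-level random
coefficients are drawn if the segment mixes, and each scenario's choice is
drawn from the segment's RUM or RRM probabilities.  True segment labels ride
along for diagnostics but are never read by estimation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import mnl_probabilities, rrm_probabilities, rrm_regret, rum_utilities
from .mixture import membership_probabilities
from .modelspec import RRM, RUM, ModelSpec, ParameterSet
from .panel import ChoicePanel

__all__ = ["DesignConfig", "TruthConfig", "generate_design", "generate_covariates",
           "simulate_choices", "simulate_panel", "DEFAULT_CATALOG"]

# level catalog of the emulated SP design; categorical base levels are the
# first entry and are omitted from the dummy coding
DEFAULT_CATALOG = {
    "categorical": {
        "grade": ["flat", "moderate", "steep"],
        "traffic": ["light", "moderate", "heavy"],
        "road": ["residential", "minor_arterial", "major_arterial"],
        "continuity": ["discontinuous", "continuous"],
        "segregation": ["shared", "exclusive"],
    },
    "numeric": {
        "mean_exposure": [5.0, 10.0, 15.0],
        "max_exposure": [20.0, 40.0, 60.0],
        "travel_time": [20.0, 25.0, 30.0, 35.0, 40.0],
    },
    "roadway_block": ["grade", "traffic", "road"],
    "bike_block": ["continuity", "segregation"],
    "core": ["mean_exposure", "max_exposure", "travel_time"],
}

# demographic mix loosely following the survey sample profile (42% female,
# 60% aged 18-34, 42% car-free households); biking frequency and commute
# length proportions are round defaults
DEFAULT_DEMOGRAPHICS = {
    "female": 0.42,
    "age_35plus": 0.40,
    "auto_owner": 0.58,
    "bike_daily": 0.45,
    "long_commute": 0.30,
}


@dataclass(frozen=True)
class DesignConfig:
    """Partitioned SP design settings (Table-1-style attribute catalog)."""

    n_respondents: int
    scenarios_per_respondent: int = 5
    n_alternatives: int = 3
    catalog: dict = field(default_factory=lambda: DEFAULT_CATALOG)
    seed: int = 0


@dataclass(frozen=True)
class TruthConfig:
    """Generating model: spec + parameters + covariate mix."""

    spec: ModelSpec
    params: ParameterSet
    demographics: dict = field(default_factory=lambda: DEFAULT_DEMOGRAPHICS)
    seed: int = 0


def _dummy_names(catalog):
    groups, names = {}, []
    for cat, levels in catalog["categorical"].items():
        cols = [f"{cat}_{lv}" for lv in levels[1:]]
        groups[cat] = cols
        names.extend(cols)
    names.extend(catalog["numeric"])
    return groups, names


def generate_design(config: DesignConfig) -> ChoicePanel:
    """Design skeleton: attributes and availability, no choices yet.

    Levels are drawn uniformly at random per alternative; each respondent's
    rotating roadway/bike attributes are assigned round-robin so the pooled
    sample covers every block.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    cat = config.catalog
    groups, names = _dummy_names(cat)
    C, K, I = config.n_respondents, config.scenarios_per_respondent, config.n_alternatives
    M = len(names)
    x = np.zeros((C, K, I, M))
    avail = np.zeros((C, K, M), dtype=bool)
    col = {n: j for j, n in enumerate(names)}

    for n in cat["core"]:
        levels = np.asarray(cat["numeric"][n])
        x[..., col[n]] = rng.choice(levels, size=(C, K, I))
        avail[..., col[n]] = True

    road = cat["roadway_block"]
    bike = cat["bike_block"]
    for c in range(C):
        for shown in (road[c % len(road)], bike[c % len(bike)]):
            levels = cat["categorical"][shown]
            draw = rng.integers(0, len(levels), size=(K, I))
            for j, lv in enumerate(levels[1:], start=1):
                x[c, :, :, col[f"{shown}_{lv}"]] = (draw == j)
            for lv in levels[1:]:
                avail[c, :, col[f"{shown}_{lv}"]] = True

    z = np.ones((C, 1))
    return ChoicePanel(x=x, chosen=None, z=z, attribute_names=names,
                       covariate_names=["intercept"], availability=avail,
                       respondent_ids=np.arange(C), dummy_groups=groups)


def generate_covariates(n_respondents: int, settings: dict | None = None,
                        seed: int = 0):
    """Binary respondent covariates with an intercept column.

    settings maps covariate name -> Bernoulli proportion.  Returns
    (z matrix (C, 1+P), names).
    """
    settings = dict(DEFAULT_DEMOGRAPHICS if settings is None else settings)
    for name, p in settings.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion for {name!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    C = n_respondents
    cols = [np.ones(C)]
    names = ["intercept"]
    for name, p in settings.items():
        cols.append((rng.random(C) < p).astype(float))
        names.append(name)
    return np.column_stack(cols), names


def simulate_choices(design: ChoicePanel, truth: TruthConfig,
                     z: np.ndarray | None = None,
                     covariate_names: list[str] | None = None) -> ChoicePanel:
    """Simulate panel choices from the generating latent-class model.

    Per respondent: draw a segment from the membership logit, draw
    respondent-level coefficients for any mixed attributes, then sample each
    scenario's choice from the segment's kernel probabilities.  The returned
    panel carries ``true_segments`` for diagnostics.
    """
    rng = np.random.default_rng(truth.seed)
    spec, params = truth.spec, truth.params
    if z is None:
        z, covariate_names = generate_covariates(
            design.n_respondents, truth.demographics,
            seed=int(rng.integers(2**31)))
    panel = ChoicePanel(
        x=design.x, chosen=None, z=np.asarray(z, dtype=float),
        attribute_names=design.attribute_names, covariate_names=list(covariate_names),
        availability=design.availability, respondent_ids=design.respondent_ids,
        dummy_groups=design.dummy_groups)

    C, K, I, _ = panel.x.shape
    if spec.n_segments == 1:
        seg_of = np.zeros(C, dtype=int)
    else:
        z_mem = panel.z[:, panel.covariate_index(spec.membership_covariates)]
        pcs = membership_probabilities(z_mem, params.gamma, spec)
        u = rng.random(C)
        seg_of = (pcs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    prob = np.zeros((C, K, I))
    for s, seg in enumerate(spec.segments):
        members = np.flatnonzero(seg_of == s)
        if members.size == 0:
            continue
        beta = np.repeat(params.beta[s][None, :], C, axis=0)
        if seg.random_attributes:
            ridx = [seg.attributes.index(a) for a in seg.random_attributes]
            xi = rng.standard_normal((C, len(ridx)))
            beta[:, ridx] += params.spread(s) * xi
        # kernels take one coefficient vector; loop distinct respondents only
        # when coefficients vary, otherwise vectorize across the segment
        if seg.random_attributes:
            for c in members:
                sub = _single_respondent_view(panel, c)
                prob[c] = _kernel_probs(sub, seg, beta[c])[0]
        else:
            prob[members] = _kernel_probs(panel, seg, params.beta[s])[members]

    u = rng.random((C, K))
    chosen = (prob.cumsum(axis=2) < u[:, :, None]).sum(axis=2)
    return panel.with_choices(chosen, true_segments=seg_of)


def _kernel_probs(panel, seg, beta):
    if seg.rule == RRM:
        return rrm_probabilities(rrm_regret(panel, beta, seg.attributes))
    return mnl_probabilities(rum_utilities(panel, beta, seg.attributes))


def _single_respondent_view(panel: ChoicePanel, c: int) -> ChoicePanel:
    return ChoicePanel(
        x=panel.x[c:c + 1], chosen=None, z=panel.z[c:c + 1],
        attribute_names=panel.attribute_names, covariate_names=panel.covariate_names,
        availability=panel.availability[c:c + 1], dummy_groups=panel.dummy_groups)


def simulate_panel(design_config: DesignConfig, truth: TruthConfig) -> ChoicePanel:
    """One-shot: design skeleton + covariates + simulated choices."""
    return simulate_choices(generate_design(design_config), truth)
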
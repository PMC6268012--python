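"""Fit statistics and the sequential search over segment compositions.

AIC = 2k - 2 ln L and BIC = -2 ln L + K ln Q, with Q the number of choice
observations.  The search mirrors the sequential strategy used for
heterogeneous-rule latent-class models: start from the two single-segment
models (one per rule), then greedily add one RUM or one RRM segment to the
incumbent until the selection criterion stops improving or a segment's
population share falls below an admissibility floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modelspec import RRM, RUM, FitStatistics, ModelSpec, SegmentSpec
from .mixture import EstimationResult, estimate

__all__ = ["aic", "bic", "fit_statistics", "fit_table", "search_compositions", "SearchState"]


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion 2k - 2 ln L (loglik is already ln L)."""
    return 2.0 * k - 2.0 * loglik


def bic(loglik: float, k: int, n_obs: int) -> float:
    """Bayesian information criterion -2 ln L + K ln Q."""
    return -2.0 * loglik + k * np.log(n_obs)


def fit_statistics(loglik: float, k: int, n_obs: int) -> FitStatistics:
    return FitStatistics(loglik=float(loglik), n_params=int(k), n_obs=int(n_obs),
                         aic=aic(loglik, k), bic=bic(loglik, k, n_obs))


def fit_table(results) -> pd.DataFrame:
    """Comparison table sorted by BIC ascending, ties broken by fewer parameters.

    Accepts EstimationResult objects or (label, loglik, k, n_obs) tuples.
    """
    rows = []
    for i, r in enumerate(results):
        if isinstance(r, EstimationResult):
            label = " + ".join(f"{sum(1 for g in r.spec.segments if g.rule == rule)} {rule}"
                               for rule in (RRM, RUM))
            f = r.fit
            rows.append((label, f.loglik, f.n_params, f.n_obs, f.bic, f.aic))
        else:
            label, L, k, q = r
            rows.append((label, L, k, q, bic(L, k, q), aic(L, k)))
    if not rows:
        raise ValueError("fit_table needs at least one result")
    df = pd.DataFrame(rows, columns=["model", "loglik", "k", "n_obs", "bic", "aic"])
    return df.sort_values(["bic", "k"], kind="stable").reset_index(drop=True)


@dataclass
class SearchState:
    """Record of a composition search: every evaluated model plus the incumbent."""

    evaluated: list = field(default_factory=list)  # (composition, result-or-error)
    incumbent: tuple | None = None                 # (n_rum, n_rrm)
    incumbent_result: EstimationResult | None = None
    criterion: str = "BIC"
    min_share: float = 0.05

    def criterion_value(self, result: EstimationResult) -> float:
        return result.fit.bic if self.criterion == "BIC" else result.fit.aic

    def table(self) -> pd.DataFrame:
        ok = [r for _, r in self.evaluated if isinstance(r, EstimationResult)]
        return fit_table(ok)


def _build_spec(n_rum: int, n_rrm: int, rum_attributes, rrm_attributes,
                membership_covariates) -> ModelSpec:
    segs = tuple(SegmentSpec(rule=RRM, attributes=tuple(rrm_attributes)) for _ in range(n_rrm)) \
        + tuple(SegmentSpec(rule=RUM, attributes=tuple(rum_attributes)) for _ in range(n_rum))
    memb = tuple(membership_covariates) if (n_rum + n_rrm) > 1 else ()
    return ModelSpec(segments=segs, membership_covariates=memb)


def search_compositions(panel, *, rum_attributes, rrm_attributes,
                        membership_covariates=(), max_segments: int = 4,
                        candidate_rules=(RUM, RRM), criterion: str = "BIC",
                        min_share: float = 0.05, exhaustive: bool = False,
                        **estimate_kwargs) -> SearchState:
    """Greedy BIC-driven search over (n_RUM, n_RRM) segment compositions.

    Begins with the single-segment model of each candidate rule, then tries
    adding one segment of either rule to the incumbent; stops when neither
    addition improves the criterion or when a new model's smallest population
    share drops below ``min_share``.  Estimation failures are recorded per
    composition, never fatal.  ``exhaustive=True`` instead enumerates every
    composition with 1..max_segments total segments.
    """
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    state = SearchState(criterion=criterion, min_share=min_share)
    results: dict[tuple, EstimationResult] = {}

    def run(comp):
        if comp in results or any(c == comp for c, _ in state.evaluated):
            return results.get(comp)
        spec = _build_spec(comp[0], comp[1], rum_attributes, rrm_attributes,
                           membership_covariates)
        try:
            res = estimate(panel, spec, **estimate_kwargs)
        except Exception as exc:  # recorded, not fatal
            state.evaluated.append((comp, exc))
            return None
        state.evaluated.append((comp, res))
        results[comp] = res
        return res

    def admissible(res):
        return res is not None and (res.shares.size == 1 or res.shares.min() >= min_share)

    if exhaustive:
        comps = [(r, s - r) for s in range(1, max_segments + 1) for r in range(s + 1)]
        for comp in comps:
            if (comp[0] and RUM not in candidate_rules) or (comp[1] and RRM not in candidate_rules):
                continue
            run(comp)
        admitted = [(c, r) for c, r in state.evaluated
                    if isinstance(r, EstimationResult) and admissible(r)]
        if admitted:
            best = min(admitted, key=lambda cr: (state.criterion_value(cr[1]),
                                                 cr[1].fit.n_params))
            state.incumbent, state.incumbent_result = best
        return state

    seeds = []
    if RUM in candidate_rules:
        seeds.append((1, 0))
    if RRM in candidate_rules:
        seeds.append((0, 1))
    best_comp, best_res = None, None
    for comp in seeds:
        res = run(comp)
        if admissible(res) and (best_res is None
                                or state.criterion_value(res) < state.criterion_value(best_res)):
            best_comp, best_res = comp, res

    while best_comp is not None and sum(best_comp) < max_segments:
        candidates = []
        if RUM in candidate_rules:
            candidates.append((best_comp[0] + 1, best_comp[1]))
        if RRM in candidate_rules:
            candidates.append((best_comp[0], best_comp[1] + 1))
        improved = False
        for comp in candidates:
            res = run(comp)
            if admissible(res) and state.criterion_value(res) < state.criterion_value(best_res):
                best_comp, best_res = comp, res
                improved = True
        if not improved:
            break

    state.incumbent, state.incumbent_result = best_comp, best_res
    return state
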
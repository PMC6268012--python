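"""Model composition types: segments, rules, and the flat parameter layout.

A latent-class model is a finite mixture of ``S`` segments.  Each segment has
its own decision rule — random utility maximization (RUM) or random regret
minimization (RRM) — its own attribute list, and optionally random (mixed)
coefficients on a subset of those attributes.  Membership in a segment is a
multinomial logit on respondent covariates with one segment as the base
(coefficients fixed at zero) for identification.

``ParameterLayout`` provides the bijection between the structured
``ParameterSet`` and the single real vector the optimizer works on; mixing
standard deviations enter on the log scale so positivity holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RUM",
    "RRM",
    "SegmentSpec",
    "ModelSpec",
    "ParameterSet",
    "ParameterLayout",
    "FitStatistics",
    "validate_spec",
]

RUM = "RUM"
RRM = "RRM"


class SpecError(ValueError):
    """Raised for invalid model specifications."""


@dataclass(frozen=True)
class SegmentSpec:
    """One latent segment: decision rule plus attribute lists."""

    rule: str
    attributes: tuple[str, ...]
    random_attributes: tuple[str, ...] = ()
    label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "random_attributes", tuple(self.random_attributes))
        if self.rule not in (RUM, RRM):
            raise SpecError(f"rule must be {RUM!r} or {RRM!r}, got {self.rule!r}")
        extra = set(self.random_attributes) - set(self.attributes)
        if extra:
            raise SpecError(f"random_attributes not in attributes: {sorted(extra)}")

    @property
    def n_params(self) -> int:
        return len(self.attributes) + len(self.random_attributes)


@dataclass(frozen=True)
class ModelSpec:
    """Ordered segment list plus the membership-model covariates."""

    segments: tuple[SegmentSpec, ...]
    membership_covariates: tuple[str, ...] = ()
    base_segment: int = 0

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "membership_covariates", tuple(self.membership_covariates))
        if len(self.segments) < 1:
            raise SpecError("at least one segment required")
        if not (0 <= self.base_segment < len(self.segments)):
            raise SpecError("base_segment out of range")
        if len(self.segments) == 1 and self.membership_covariates:
            raise SpecError("membership covariates meaningless with a single segment")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def validate_spec(spec: ModelSpec, panel) -> ModelSpec:
    """Check every referenced attribute/covariate exists on the panel."""
    attrs = set(panel.attribute_names)
    for s, seg in enumerate(spec.segments):
        unknown = set(seg.attributes) - attrs
        if unknown:
            raise SpecError(
                f"segment {s} references unknown attribute(s) {sorted(unknown)}; "
                f"panel has {sorted(attrs)}"
            )
    unknown = set(spec.membership_covariates) - set(panel.covariate_names)
    if unknown:
        raise SpecError(f"unknown membership covariate(s) {sorted(unknown)}")
    return spec


@dataclass
class ParameterSet:
    """Structured parameters for a ModelSpec.

    gamma : dict segment-index -> membership coefficient vector (non-base only)
    beta : list of per-segment coefficient vectors (alpha for RUM, delta for RRM)
    log_spread : list of per-segment log mixing standard deviations, aligned to
        each segment's ``random_attributes``
    """

    gamma: dict[int, np.ndarray]
    beta: list[np.ndarray]
    log_spread: list[np.ndarray]

    def spread(self, s: int) -> np.ndarray:
        return np.exp(self.log_spread[s])

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            gamma={k: v.copy() for k, v in self.gamma.items()},
            beta=[b.copy() for b in self.beta],
            log_spread=[r.copy() for r in self.log_spread],
        )


class ParameterLayout:
    """Flatten/unflatten mapping between ParameterSet and one real vector.

    Order: membership gammas for each non-base segment (spec order), then per
    segment its beta followed by its log-spreads.  ``flatten(unflatten(v)) == v``
    for every vector of the right length.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.n_membership = len(spec.membership_covariates)
        self.slices: dict[tuple, slice] = {}
        pos = 0
        S = spec.n_segments
        if S > 1:
            for s in range(S):
                if s == spec.base_segment:
                    continue
                self.slices[("gamma", s)] = slice(pos, pos + self.n_membership)
                pos += self.n_membership
        for s, seg in enumerate(spec.segments):
            self.slices[("beta", s)] = slice(pos, pos + len(seg.attributes))
            pos += len(seg.attributes)
            self.slices[("spread", s)] = slice(pos, pos + len(seg.random_attributes))
            pos += len(seg.random_attributes)
        self.n_params = pos

    def flatten(self, params: ParameterSet) -> np.ndarray:
        vec = np.empty(self.n_params)
        for (kind, s), sl in self.slices.items():
            if kind == "gamma":
                part = params.gamma[s]
            elif kind == "beta":
                part = params.beta[s]
            else:
                part = params.log_spread[s]
            part = np.asarray(part, dtype=float)
            if part.shape != (sl.stop - sl.start,):
                raise SpecError(f"{kind} for segment {s}: expected length {sl.stop - sl.start}")
            vec[sl] = part
        return vec

    def unflatten(self, vec: np.ndarray) -> ParameterSet:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_params,):
            raise SpecError(f"parameter vector must have length {self.n_params}")
        gamma, beta, spread = {}, [], []
        for s in range(self.spec.n_segments):
            if ("gamma", s) in self.slices:
                gamma[s] = vec[self.slices[("gamma", s)]].copy()
            beta.append(vec[self.slices[("beta", s)]].copy())
            spread.append(vec[self.slices[("spread", s)]].copy())
        return ParameterSet(gamma=gamma, beta=beta, log_spread=spread)

    def labels(self) -> list[str]:
        """Human-readable name per flat-vector entry (reporting order)."""
        out = [""] * self.n_params
        cov = self.spec.membership_covariates
        for (kind, s), sl in self.slices.items():
            seg = self.spec.segments[s]
            for j, pos in enumerate(range(sl.start, sl.stop)):
                if kind == "gamma":
                    out[pos] = f"membership[seg{s + 1}]:{cov[j]}"
                elif kind == "beta":
                    out[pos] = f"seg{s + 1}({seg.rule}):{seg.attributes[j]}"
                else:
                    out[pos] = f"seg{s + 1}({seg.rule}):sd({seg.random_attributes[j]})"
        return out


@dataclass(frozen=True)
class FitStatistics:
    """Converged log-likelihood with AIC/BIC bookkeeping.

    ``n_obs`` counts choice observations (respondents x scenarios), matching
    how stated-preference panels are conventionally tallied.
    """

    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
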
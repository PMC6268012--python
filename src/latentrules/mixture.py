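"""Latent-class estimation: membership model, simulated likelihood, inference.

Model
-----
Respondent ``c`` belongs to segment ``s`` with multinomial-logit probability
``P_cs = exp(gamma_s' z_c) / sum_r exp(gamma_r' z_c)`` (base segment's gamma
fixed at zero).  Conditional on the segment, the respondent's K choices follow
that segment's RUM or RRM kernel, giving the panel likelihood ``L_c|s``; the
sample log-likelihood is

    LL = sum_c log sum_s P_cs * L_c|s,

evaluated via log-sum-exp over segments.  Maximization is direct quasi-Newton
(L-BFGS-B) on the unconstrained flat parameter vector with the analytic
gradient; mixing spreads enter as log sigma.  Standard errors come from the
inverse of a central finite-difference Hessian of the gradient at the optimum.

Reported segment order is canonical: RRM segments before RUM, descending
population share within rule, with membership coefficients re-based onto the
first canonical segment — this resolves label switching deterministically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .kernels import DrawSet, segment_panel_loglik
from .modelspec import (
    RRM,
    FitStatistics,
    ModelSpec,
    ParameterLayout,
    ParameterSet,
    SegmentSpec,
    validate_spec,
)
from .panel import ChoicePanel

__all__ = [
    "EstimationResult",
    "LatentClassChoiceModel",
    "estimate",
    "membership_probabilities",
    "unconditional_loglik",
    "posterior_segments",
    "population_shares",
]


@dataclass
class EstimationResult:
    """Converged estimate with inference, shares, and posteriors."""

    spec: ModelSpec
    params: ParameterSet
    loglik: float
    fit: FitStatistics
    std_errors: np.ndarray | None
    t_stats: np.ndarray | None
    param_labels: list[str]
    shares: np.ndarray
    posteriors: np.ndarray
    converged: bool
    inference_ok: bool
    n_draws: int
    seed: int
    trace: list = field(default_factory=list)

    def parameter_table(self):
        """Long-format parameter table (segment, variable, estimate, se, t)."""
        import pandas as pd

        layout = ParameterLayout(self.spec)
        vec = layout.flatten(self.params)
        se = self.std_errors if self.std_errors is not None else np.full(vec.size, np.nan)
        t = self.t_stats if self.t_stats is not None else np.full(vec.size, np.nan)
        seg_col, var_col = [], []
        for lab in self.param_labels:
            head, var = lab.split(":", 1)
            seg_col.append(head)
            var_col.append(var)
        return pd.DataFrame(
            {"segment": seg_col, "variable": var_col,
             "estimate": vec, "std_error": se, "t_stat": t}
        )


# ---------------------------------------------------------------------------
# likelihood pieces


def _membership_logits(z_mem: np.ndarray, params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    C = z_mem.shape[0]
    S = spec.n_segments
    logits = np.zeros((C, S))
    for s in range(S):
        if s == spec.base_segment or S == 1:
            continue
        gam = params.gamma[s]
        if gam.shape != (z_mem.shape[1],):
            raise ValueError(f"gamma for segment {s} misaligned with membership covariates")
        logits[:, s] = z_mem @ gam
    return logits


def membership_probabilities(z, gamma, spec: ModelSpec) -> np.ndarray:
    """P_cs matrix (C, S); each row a probability simplex."""
    z = np.asarray(z, dtype=float)
    params = ParameterSet(gamma=dict(gamma), beta=[], log_spread=[])
    logits = _membership_logits(z, params, spec)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _segment_draws(panel, spec, n_draws, seed, generator="halton-scrambled"):
    """One DrawSet per segment that has random attributes (seed offset by index)."""
    out = []
    for s, seg in enumerate(spec.segments):
        if seg.random_attributes:
            out.append(DrawSet.make(panel.n_respondents, n_draws,
                                    len(seg.random_attributes), generator, seed + s))
        else:
            out.append(None)
    return out


def _loglik_parts(panel, spec, params, seg_draws, need_grad):
    """Respondent-level pieces: returns (LL, grad or None, logP_cs, logL_c|s)."""
    z_mem = panel.z[:, panel.covariate_index(spec.membership_covariates)] \
        if spec.membership_covariates else np.ones((panel.n_respondents, 0))
    S = spec.n_segments
    logits = _membership_logits(z_mem, params, spec)
    log_pcs = logits - logsumexp(logits, axis=1, keepdims=True)

    seg_ll = np.empty((panel.n_respondents, S))
    seg_grads = []
    for s, seg in enumerate(spec.segments):
        ll, g = segment_panel_loglik(panel, seg, params.beta[s], params.log_spread[s],
                                     seg_draws[s], need_grad=need_grad)
        seg_ll[:, s] = ll
        seg_grads.append(g)

    joint = log_pcs + seg_ll  # (C, S)
    ll_c = logsumexp(joint, axis=1)
    if not np.all(np.isfinite(ll_c)):
        bad = int(np.flatnonzero(~np.isfinite(ll_c))[0])
        raise FloatingPointError(f"non-finite likelihood for respondent index {bad}")
    LL = float(ll_c.sum())
    if not need_grad:
        return LL, None, log_pcs, seg_ll

    w = np.exp(joint - ll_c[:, None])  # posteriors (C, S)
    layout = ParameterLayout(spec)
    grad = np.zeros(layout.n_params)
    pcs = np.exp(log_pcs)
    for s in range(S):
        key = ("gamma", s)
        if key in layout.slices:
            grad[layout.slices[key]] = (w[:, s] - pcs[:, s]) @ z_mem
        gseg = seg_grads[s]
        nb = len(spec.segments[s].attributes)
        grad[layout.slices[("beta", s)]] = w[:, s] @ gseg[:, :nb]
        if gseg.shape[1] > nb:
            grad[layout.slices[("spread", s)]] = w[:, s] @ gseg[:, nb:]
    return LL, grad, log_pcs, seg_ll


def unconditional_loglik(panel, spec: ModelSpec, params: ParameterSet,
                         draws=None, n_draws: int = 200, seed: int = 0) -> float:
    """Sample log-likelihood LL = sum_c log sum_s P_cs L_c|s."""
    validate_spec(spec, panel)
    if draws is None:
        draws = _segment_draws(panel, spec, n_draws, seed)
    LL, _, _, _ = _loglik_parts(panel, spec, params, draws, need_grad=False)
    return LL


def population_shares(p_cs: np.ndarray) -> np.ndarray:
    """GS_s = mean over respondents of P_cs (sums to 1)."""
    p = np.asarray(p_cs, dtype=float)
    return p.mean(axis=0)


def posterior_segments(result: EstimationResult, panel) -> np.ndarray:
    """Bayes posterior segment membership: prior P_cs times L_c|s, normalized."""
    seg_draws = _segment_draws(panel, result.spec, result.n_draws, result.seed)
    _, _, log_pcs, seg_ll = _loglik_parts(panel, result.spec, result.params,
                                          seg_draws, need_grad=False)
    joint = log_pcs + seg_ll
    return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# canonicalization (label switching)


def _canonicalize(spec: ModelSpec, params: ParameterSet, prior_shares: np.ndarray):
    """Reorder segments: RRM before RUM, descending share within rule.

    Membership coefficients are re-based so the first canonical segment is the
    base (gamma differences are preserved, hence the likelihood is unchanged).
    """
    S = spec.n_segments
    order = sorted(range(S), key=lambda s: (spec.segments[s].rule != RRM, -prior_shares[s]))
    if S == 1:
        return spec, params, order
    P = len(spec.membership_covariates)
    gam_full = np.zeros((S, P))
    for s in range(S):
        if s != spec.base_segment:
            gam_full[s] = params.gamma[s]
    gam_perm = gam_full[order]
    gam_perm = gam_perm - gam_perm[0]
    new_spec = dataclasses.replace(
        spec, segments=tuple(spec.segments[s] for s in order), base_segment=0
    )
    new_params = ParameterSet(
        gamma={s: gam_perm[s].copy() for s in range(1, S)},
        beta=[params.beta[s].copy() for s in order],
        log_spread=[params.log_spread[s].copy() for s in order],
    )
    return new_spec, new_params, order


# ---------------------------------------------------------------------------
# estimator


class LatentClassChoiceModel:
    """Latent-class RUM/RRM choice model, scikit-learn estimator style.

    Parameters
    ----------
    spec : ModelSpec
        Segment composition and membership covariates.
    n_draws : int
        Quasi-random draws per respondent for mixed segments (unused without
        random attributes).
    seed : int
        Seed for draws and multi-start perturbations.
    n_starts : int
        Number of starting points (first unperturbed, rest jittered).
    tol, grad_tol : float
        Convergence targets: relative log-likelihood change and gradient
        max-norm.
    max_iter : int
        Iteration cap per start.
    generator : str
        "halton-scrambled" (default) or "pseudo-random" draws.

    Fitted attributes (trailing underscore) mirror ``EstimationResult``.
    """

    def __init__(self, spec: ModelSpec | None = None, n_draws: int = 200, seed: int = 0,
                 n_starts: int = 5, tol: float = 1e-8, grad_tol: float = 1e-5,
                 max_iter: int = 500, generator: str = "halton-scrambled"):
        self.spec = spec
        self.n_draws = n_draws
        self.seed = seed
        self.n_starts = n_starts
        self.tol = tol
        self.grad_tol = grad_tol
        self.max_iter = max_iter
        self.generator = generator

    # sklearn plumbing -----------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("spec", "n_draws", "seed", "n_starts", "tol", "grad_tol",
                 "max_iter", "generator")}

    def set_params(self, **kwargs) -> "LatentClassChoiceModel":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # estimation -----------------------------------------------------------
    def _optimize(self, panel, spec, seg_draws, x0):
        layout = ParameterLayout(spec)

        def nll(vec):
            params = layout.unflatten(vec)
            LL, grad, _, _ = _loglik_parts(panel, spec, params, seg_draws, need_grad=True)
            return -LL, -grad

        res = minimize(nll, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter, "ftol": self.tol,
                                "gtol": self.grad_tol, "maxfun": 50 * self.max_iter})
        gmax = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        converged = bool(res.success) or gmax < 1e-3
        return res, converged

    def _single_segment_start(self, panel, seg: SegmentSpec, rng):
        """Cheap one-segment fit (no mixing) used as a warm start."""
        plain = SegmentSpec(rule=seg.rule, attributes=seg.attributes)
        sub = ModelSpec(segments=(plain,))
        layout = ParameterLayout(sub)
        res, _ = self._optimize(panel, sub, [None], np.zeros(layout.n_params))
        beta = res.x
        spread0 = np.full(len(seg.random_attributes), np.log(0.1))
        return beta, spread0

    def _starting_vector(self, panel, spec, rng):
        layout = ParameterLayout(spec)
        params = ParameterSet(
            gamma={s: np.zeros(layout.n_membership)
                   for s in range(spec.n_segments) if ("gamma", s) in layout.slices},
            beta=[], log_spread=[])
        cache: dict[tuple, tuple] = {}
        for seg in spec.segments:
            key = (seg.rule, seg.attributes, seg.random_attributes)
            if key not in cache:
                cache[key] = self._single_segment_start(panel, seg, rng)
            beta, spread = cache[key]
            params.beta.append(beta.copy())
            params.log_spread.append(spread.copy())
        return layout.flatten(params)

    def fit(self, X: ChoicePanel, y=None) -> "LatentClassChoiceModel":
        """Maximize the (simulated) likelihood on a choice panel."""
        panel = X
        spec = validate_spec(self.spec, panel)
        if panel.chosen is None:
            raise ValueError("panel has no recorded choices")
        seg_draws = _segment_draws(panel, spec, self.n_draws, self.seed, self.generator)
        rng = np.random.default_rng(self.seed)
        base = self._starting_vector(panel, spec, rng)
        layout = ParameterLayout(spec)

        best = None
        trace = []
        for j in range(max(1, self.n_starts)):
            x0 = base.copy()
            if j > 0:
                x0 += rng.normal(0.0, 0.25 * np.abs(base) + 0.1)
            try:
                res, converged = self._optimize(panel, spec, seg_draws, x0)
            except FloatingPointError as exc:
                trace.append({"start": j, "error": str(exc)})
                continue
            trace.append({"start": j, "loglik": -float(res.fun),
                          "converged": converged, "n_iter": int(res.nit)})
            if best is None or (converged, -res.fun) > (best[1], -best[0].fun):
                best = (res, converged)
        if best is None:
            raise RuntimeError(f"no start converged; diagnostics: {trace}")
        res, converged = best

        params = layout.unflatten(res.x)
        _, _, log_pcs, _ = _loglik_parts(panel, spec, params, seg_draws, need_grad=False)
        prior_shares = population_shares(np.exp(log_pcs))
        spec_c, params_c, order = _canonicalize(spec, params, prior_shares)
        seg_draws_c = _segment_draws(panel, spec_c, self.n_draws, self.seed, self.generator)
        layout_c = ParameterLayout(spec_c)
        vec_c = layout_c.flatten(params_c)

        LL, _, log_pcs, seg_ll = _loglik_parts(panel, spec_c, params_c, seg_draws_c,
                                               need_grad=False)
        se, tstat, inference_ok = self._inference(panel, spec_c, seg_draws_c, vec_c)

        pcs = np.exp(log_pcs)
        joint = log_pcs + seg_ll
        posteriors = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        from .selection import fit_statistics  # local: avoids module cycle

        fit = fit_statistics(LL, layout_c.n_params, panel.n_obs)
        self.result_ = EstimationResult(
            spec=spec_c, params=params_c, loglik=LL, fit=fit,
            std_errors=se, t_stats=tstat, param_labels=layout_c.labels(),
            shares=population_shares(pcs), posteriors=posteriors,
            converged=converged, inference_ok=inference_ok,
            n_draws=self.n_draws, seed=self.seed, trace=trace,
        )
        self.spec_ = spec_c
        self.params_ = params_c
        self.loglik_ = LL
        self.fit_ = fit
        self.shares_ = self.result_.shares
        self.posteriors_ = posteriors
        self.std_errors_ = se
        self.t_stats_ = tstat
        self.converged_ = converged
        return self

    def _inference(self, panel, spec, seg_draws, vec):
        """Standard errors via central-difference Hessian of the analytic gradient."""
        layout = ParameterLayout(spec)

        def grad_at(v):
            _, g, _, _ = _loglik_parts(panel, spec, layout.unflatten(v), seg_draws, True)
            return g

        n = vec.size
        H = np.empty((n, n))
        for j in range(n):
            h = 1e-5 * (1.0 + abs(vec[j]))
            vp, vm = vec.copy(), vec.copy()
            vp[j] += h
            vm[j] -= h
            H[:, j] = (grad_at(vp) - grad_at(vm)) / (2 * h)
        H = -(H + H.T) / 2.0  # observed information
        try:
            eig = np.linalg.eigvalsh(H)
            if eig.min() <= 0:
                return None, None, False
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
            return se, vec / se, True
        except np.linalg.LinAlgError:
            return None, None, False

    # prediction -----------------------------------------------------------
    def predict_proba(self, X: ChoicePanel) -> np.ndarray:
        """Unconditional choice probabilities (C, K, I) under the fitted model."""
        self._check_fitted()
        from .kernels import mnl_probabilities, rrm_regret, rrm_probabilities, rum_utilities

        panel, spec, params = X, self.spec_, self.params_
        z_mem = panel.z[:, panel.covariate_index(spec.membership_covariates)] \
            if spec.membership_covariates else np.ones((panel.n_respondents, 0))
        pcs = np.exp(_membership_logits(z_mem, params, spec)
                     - logsumexp(_membership_logits(z_mem, params, spec), axis=1, keepdims=True))
        out = np.zeros((panel.n_respondents, panel.n_scenarios, panel.n_alternatives))
        for s, seg in enumerate(spec.segments):
            if seg.rule == RRM:
                p = rrm_probabilities(rrm_regret(panel, params.beta[s], seg.attributes))
            else:
                p = mnl_probabilities(rum_utilities(panel, params.beta[s], seg.attributes))
            out += pcs[:, s, None, None] * p
        return out

    def score(self, X: ChoicePanel, y=None) -> float:
        """Mean per-respondent log-likelihood at the fitted parameters."""
        self._check_fitted()
        return unconditional_loglik(X, self.spec_, self.params_,
                                    n_draws=self.n_draws, seed=self.seed) / X.n_respondents

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted; call fit() first")


def estimate(panel, spec: ModelSpec, n_draws: int = 200, seed: int = 0,
             n_starts: int = 5, tol: float = 1e-8, grad_tol: float = 1e-5,
             max_iter: int = 500, generator: str = "halton-scrambled") -> EstimationResult:
    """Functional wrapper over :class:`LatentClassChoiceModel`."""
    model = LatentClassChoiceModel(spec=spec, n_draws=n_draws, seed=seed,
                                   n_starts=n_starts, tol=tol, grad_tol=grad_tol,
                                   max_iter=max_iter, generator=generator)
    return model.fit(panel).result_
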
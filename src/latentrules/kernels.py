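"""Per-segment choice-probability kernels.

Two decision rules are supported:

* RUM — linear-in-attributes utility ``U_cik = sum_m beta_m x_cikm``; choice
  probabilities are the multinomial-logit softmax of utilities over the
  alternatives of a scenario.
* RRM — regret ``R_cik = sum_{j != i} sum_m ln(1 + exp(delta_m (x_cjkm - x_cikm)))``
  accumulated over pairwise attribute disadvantages against every competitor;
  choice probabilities are the softmax of negated regrets.

Both kernels respect the availability mask: an attribute not shown in a
scenario contributes exactly zero to utility and regret.  Random-coefficient
(mixed) segments draw respondent-level coefficients ``beta_m + sigma_m * xi``
with standard-normal ``xi`` from a scrambled Halton or pseudo-random
``DrawSet``; the panel product over a respondent's K scenarios sits inside the
draw average (panel mixing), so the simulated conditional likelihood is

    L_c|s = (1/D) sum_d prod_k P_ck(chosen | beta^{(d)}_c).

All probability work is done in log space with max-subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp, ndtri
from scipy.stats import qmc

from .modelspec import RRM, RUM, SegmentSpec

__all__ = [
    "DrawSet",
    "softplus",
    "rum_utilities",
    "mnl_probabilities",
    "rrm_regret",
    "rrm_probabilities",
    "segment_panel_likelihood",
    "segment_panel_loglik",
]


def softplus(u: np.ndarray) -> np.ndarray:
    """ln(1 + exp(u)), overflow-safe (== max(u,0) + log1p(exp(-|u|)))."""
    return np.logaddexp(0.0, u)


@dataclass(frozen=True)
class DrawSet:
    """Respondent-specific standard-normal quasi-random draws.

    ``draws`` has shape (n_respondents, n_draws, n_random) and is reused
    across a respondent's scenarios (panel mixing).  Deterministic given
    (generator, seed, shape).
    """

    draws: np.ndarray
    generator: str
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @classmethod
    def make(cls, n_respondents: int, n_draws: int, n_random: int,
             generator: str = "halton-scrambled", seed: int = 0) -> "DrawSet":
        if n_random > 0 and n_draws < 1:
            raise ValueError("at least one draw required for random coefficients")
        shape = (n_respondents, n_draws, n_random)
        if n_random == 0 or n_draws == 0:
            u = np.zeros(shape)
        elif generator == "halton-scrambled":
            sampler = qmc.Halton(d=n_random, scramble=True, seed=seed)
            pts = sampler.random(n_respondents * n_draws)
            u = ndtri(pts).reshape(shape)
        elif generator == "pseudo-random":
            rng = np.random.default_rng(seed)
            u = rng.standard_normal(shape)
        else:
            raise ValueError(f"unknown draw generator {generator!r}")
        return cls(draws=u, generator=generator, seed=seed)


# ---------------------------------------------------------------------------
# deterministic kernels


def _masked_x(panel, segment_attrs):
    """Attribute slice (C,K,I,P) and its availability mask (C,K,P)."""
    idx = panel.attribute_index(segment_attrs)
    return panel.x[..., idx], panel.availability[..., idx]


def rum_utilities(panel, beta, segment_attrs) -> np.ndarray:
    """Linear utilities (C, K, I); unavailable attributes contribute zero."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(segment_attrs),):
        raise ValueError(f"beta length {beta.shape} misaligned with {len(segment_attrs)} attributes")
    xs, avail = _masked_x(panel, segment_attrs)
    return np.einsum("ckip,ckp,p->cki", xs, avail.astype(float), beta)


def mnl_probabilities(utilities: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with max-subtraction."""
    u = np.asarray(utilities, dtype=float)
    u = u - u.max(axis=-1, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=-1, keepdims=True)


def rrm_regret(panel, delta, segment_attrs) -> np.ndarray:
    """Regret tensor (C, K, I) of pairwise softplus attribute disadvantages."""
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (len(segment_attrs),):
        raise ValueError(f"delta length {delta.shape} misaligned with {len(segment_attrs)} attributes")
    xs, avail = _masked_x(panel, segment_attrs)
    # diff[c,k,i,j,p] = x_j - x_i
    diff = xs[:, :, None, :, :] - xs[:, :, :, None, :]
    sp = softplus(delta * diff)
    I = xs.shape[2]
    offdiag = 1.0 - np.eye(I)
    sp = sp * avail[:, :, None, None, :] * offdiag[None, None, :, :, None]
    return sp.sum(axis=(3, 4))


def rrm_probabilities(regret: np.ndarray) -> np.ndarray:
    """Softmax of negated regrets over alternatives."""
    return mnl_probabilities(-np.asarray(regret, dtype=float))


# ---------------------------------------------------------------------------
# panel log-likelihood per segment (with analytic gradient)


def _chosen_logprob_grad(panel, seg: SegmentSpec, coef, need_grad: bool):
    """Per-respondent sum over scenarios of log P(chosen), and its gradient.

    coef : (C, P) respondent-specific coefficients over seg.attributes.
    Returns (ll_c (C,), grad (C, P) or None).
    """
    xs, avail = _masked_x(panel, seg.attributes)
    C, K, I, P = xs.shape
    chosen = panel.chosen
    if seg.rule == RUM:
        xm = xs * avail[:, :, None, :]
        U = np.einsum("ckip,cp->cki", xm, coef)
        dU = xm  # (C,K,I,P)
    else:
        diff = xs[:, :, None, :, :] - xs[:, :, :, None, :]
        u = diff * coef[:, None, None, None, :]
        mask = avail[:, :, None, None, :] * (1.0 - np.eye(I))[None, None, :, :, None]
        R = (softplus(u) * mask).sum(axis=(3, 4))
        U = -R
        if need_grad:
            dU = -(diff * expit(u) * mask).sum(axis=3)  # (C,K,I,P)
    Umax = U.max(axis=-1, keepdims=True)
    lse = Umax[..., 0] + np.log(np.exp(U - Umax).sum(axis=-1))
    ck = np.arange(C)[:, None], np.arange(K)[None, :]
    logp = U[ck[0], ck[1], chosen] - lse  # (C,K)
    ll_c = logp.sum(axis=1)
    if not need_grad:
        return ll_c, None
    Pr = np.exp(U - lse[..., None])
    mean_dU = np.einsum("cki,ckip->ckp", Pr, dU)
    g = dU[ck[0], ck[1], chosen] - mean_dU  # (C,K,P)
    return ll_c, g.sum(axis=1)


def segment_panel_loglik(panel, seg: SegmentSpec, beta, log_spread=None,
                         draws: DrawSet | None = None, need_grad: bool = False):
    """log L_c|s per respondent, optionally with gradient.

    Gradient columns follow [beta (over seg.attributes), log_spread (over
    seg.random_attributes)].  Without random attributes the exact panel
    product is returned (no simulation); with them the draw average is
    evaluated in log space.
    """
    beta = np.asarray(beta, dtype=float)
    C = panel.n_respondents
    n_rand = len(seg.random_attributes)
    if n_rand == 0:
        coef = np.broadcast_to(beta, (C, beta.size))
        ll, g = _chosen_logprob_grad(panel, seg, coef, need_grad)
        return (ll, g) if need_grad else (ll, None)
    if draws is None or draws.n_draws == 0:
        raise ValueError("draws required for a segment with random attributes")
    log_spread = np.asarray(log_spread, dtype=float)
    sigma = np.exp(log_spread)
    ridx = np.array([seg.attributes.index(a) for a in seg.random_attributes])
    D = draws.n_draws
    A = np.empty((C, D))
    G = np.empty((C, D, beta.size)) if need_grad else None
    for d in range(D):
        coef = np.repeat(beta[None, :], C, axis=0)
        coef[:, ridx] += sigma * draws.draws[:, d, :]
        ll_d, g_d = _chosen_logprob_grad(panel, seg, coef, need_grad)
        A[:, d] = ll_d
        if need_grad:
            G[:, d, :] = g_d
    ll = logsumexp(A, axis=1) - np.log(D)
    if not need_grad:
        return ll, None
    w = np.exp(A - ll[:, None] - np.log(D))  # (C,D), rows sum to 1
    g_beta = np.einsum("cd,cdp->cp", w, G)
    # chain rule through beta_r = mu_r + sigma_r * xi: d/dlog sigma = sigma*xi*d/dbeta
    g_ls = np.einsum("cd,cdr,cdr->cr", w, G[:, :, ridx], sigma * draws.draws)
    return ll, np.concatenate([g_beta, g_ls], axis=1)


def segment_panel_likelihood(panel, seg: SegmentSpec, beta, log_spread=None,
                             draws: DrawSet | None = None) -> np.ndarray:
    """Conditional likelihood L_c|s in (0, 1] per respondent."""
    ll, _ = segment_panel_loglik(panel, seg, beta, log_spread, draws)
    return np.exp(ll)
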
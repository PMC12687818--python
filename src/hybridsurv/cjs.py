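"""Survival labeling from telemetry via a Cormack-Jolly-Seber model.

Detections are binned into 30 ten-day capture occasions over a 300-day study
window; a CJS model — a two-state (alive/dead) hidden Markov chain
conditioned on first capture, with time-varying apparent survival phi_t and
detection probability p_t — is fitted by maximum likelihood, and each bird
receives an overall apparent-survival probability that is binarized at 0.5.

Two fitting modes are provided.  ``cohort`` (default) shares phi_t and p_t
across birds and labels each bird by its posterior probability of being alive
at the final occasion (forward filtering); this is identifiable and
reproduces the effectively binary probabilities the labeling is meant to
yield.  ``per_bird`` fits each capture history alone, mirroring a
one-bird-at-a-time analysis: with 58 free parameters against one binary
vector, estimates sit on the boundary and the phi-product collapses to ~0 or
~1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "bin_detections",
    "CJSParameters",
    "cjs_likelihood",
    "cjs_likelihood_bruteforce",
    "fit_cjs",
    "alive_posterior",
    "label_survival",
    "label_cohort",
]

_BOUND = 1e-6


def bin_detections(timestamps, study_days: int = 300, occasion_days: int = 10) -> np.ndarray:
    """Collapse one bird's detection timestamps into a binary capture history.

    Occasion index is ``floor(t / occasion_days)`` with half-open bins,
    clamped into range; detections after the study window set the final
    occasion (the bird demonstrably survived past it).  Occasion 0 (release)
    is always set.
    """
    n_occ = study_days // occasion_days
    history = np.zeros(n_occ, dtype=int)
    history[0] = 1
    for t in np.atleast_1d(np.asarray(timestamps, dtype=float)):
        if t < 0:
            raise ValueError(f"negative detection timestamp: {t}")
        if t > study_days:
            history[n_occ - 1] = 1
        else:
            history[min(int(t // occasion_days), n_occ - 1)] = 1
    return history


@dataclass
class CJSParameters:
    """Time-varying CJS parameters for T occasions: phi has length T-1
    (survival over interval t -> t+1), p has length T-1 (detection at
    occasions 2..T given alive)."""

    phi: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.phi.shape != self.p.shape:
            raise ValueError("phi and p must have equal length")
        for name, v in (("phi", self.phi), ("p", self.p)):
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} entries must lie in [0, 1]")

    @classmethod
    def constant(cls, phi: float, p: float, n_occasions: int) -> "CJSParameters":
        return cls(np.full(n_occasions - 1, phi), np.full(n_occasions - 1, p))


def _forward(history: np.ndarray, phi: np.ndarray, p: np.ndarray):
    """Forward pass in probability space for one bird.

    Returns (log-likelihood, P(alive at final occasion | history)).
    States: alive / dead; dead is absorbing and silent.  Conditioned on
    release at occasion 0 (alive with certainty).
    """
    a, d = 1.0, 0.0  # joint probs of obs so far and state
    loglik = 0.0
    for t in range(1, len(history)):
        a_new = a * phi[t - 1]
        d_new = d + a * (1.0 - phi[t - 1])
        obs = history[t]
        if obs:
            a_new *= p[t - 1]
            d_new = 0.0
        else:
            a_new *= 1.0 - p[t - 1]
        a, d = a_new, d_new
        s = a + d
        if s <= 0.0:
            return -np.inf, 0.0
        # rescale to avoid underflow; accumulate log norm
        loglik += np.log(s)
        a /= s
        d /= s
    return loglik, a


def cjs_likelihood(history, params: CJSParameters) -> float:
    """Log-likelihood of one capture history under the CJS model."""
    history = np.asarray(history, dtype=int)
    if history[0] != 1:
        raise ValueError("first occasion must be the release (1)")
    if len(history) - 1 > len(params.phi):
        raise ValueError("parameter vectors shorter than the history")
    ll, _ = _forward(history, params.phi, params.p)
    return float(ll)


def cjs_likelihood_bruteforce(history, params: CJSParameters) -> float:
    """Oracle: exhaustive sum over all alive/dead latent paths.

    Exponential in the number of occasions — only for validating the forward
    pass on short histories.
    """
    history = np.asarray(history, dtype=int)
    T = len(history)
    phi, p = params.phi, params.p
    total = 0.0
    # latent state at occasions 1..T-1 (occasion 0 alive); dead absorbing
    for mask in range(2 ** (T - 1)):
        states = [1] + [(mask >> i) & 1 for i in range(T - 1)]
        prob = 1.0
        ok = True
        for t in range(1, T):
            prev, cur = states[t - 1], states[t]
            if prev == 0:
                if cur == 1:
                    ok = False
                    break
                trans = 1.0
            else:
                trans = phi[t - 1] if cur == 1 else 1.0 - phi[t - 1]
            prob *= trans
            if cur == 1:
                prob *= p[t - 1] if history[t] else 1.0 - p[t - 1]
            elif history[t]:
                ok = False
                break
        if ok:
            total += prob
    return float(np.log(total)) if total > 0 else -np.inf


def _forward_matrix(H: np.ndarray, phi: np.ndarray, p: np.ndarray):
    """Vectorized forward pass over a (n_birds, T) history matrix."""
    n, T = H.shape
    a = np.ones(n)
    d = np.zeros(n)
    loglik = np.zeros(n)
    for t in range(1, T):
        obs = H[:, t].astype(bool)
        a_new = a * phi[t - 1]
        d_new = d + a * (1.0 - phi[t - 1])
        a_new = np.where(obs, a_new * p[t - 1], a_new * (1.0 - p[t - 1]))
        d_new = np.where(obs, 0.0, d_new)
        s = a_new + d_new
        s = np.maximum(s, 1e-300)
        loglik += np.log(s)
        a = a_new / s
        d = d_new / s
    return loglik, a


def fit_cjs(
    histories,
    mode: str = "cohort",
    max_iter: int = 500,
    time_varying: bool = True,
):
    """Maximum-likelihood fit of the CJS parameters.

    Parameters are optimized on the logit scale (L-BFGS-B from a flat 0.5
    start), which keeps phi and p inside (0, 1); estimates are clipped to
    [1e-6, 1 - 1e-6].  ``cohort`` mode returns one shared parameter set;
    ``per_bird`` returns a list of per-bird fits.  With ``time_varying=False``
    a single (phi, p) pair is shared across intervals — useful for parameter
    recovery checks.
    """
    H = np.asarray(histories, dtype=int)
    if H.ndim == 1:
        H = H[None, :]
    if H.shape[0] < 1:
        raise ValueError("need at least one history")
    if mode not in ("cohort", "per_bird"):
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "cohort" and H.shape[0] < 2:
        raise ValueError("cohort mode requires >= 2 birds")
    T = H.shape[1]
    n_phi = T - 1 if time_varying else 1
    # The final (phi, p) pair is confounded in a fully time-varying CJS
    # (only their product is identified), so the last detection probability
    # is tied to the previous occasion's.
    n_p = max(T - 2, 1) if time_varying else 1

    def expand(theta):
        phi = expit(theta[:n_phi])
        p = expit(theta[n_phi:])
        if not time_varying:
            return np.full(T - 1, phi[0]), np.full(T - 1, p[0])
        if n_p < T - 1:
            p = np.append(p, p[-1])
        return phi, p

    def fit_matrix(Hm: np.ndarray) -> CJSParameters:
        def negloglik(theta):
            phi, p = expand(theta)
            ll, _ = _forward_matrix(Hm, phi, p)
            return -float(np.sum(ll))

        x0 = np.zeros(n_phi + n_p)  # logit(0.5)
        res = minimize(negloglik, x0, method="L-BFGS-B", options={"maxiter": max_iter})
        phi, p = expand(res.x)
        phi = np.clip(phi, _BOUND, 1 - _BOUND)
        p = np.clip(p, _BOUND, 1 - _BOUND)
        if not res.success and res.status not in (1,):  # 1: maxiter with usable point
            raise RuntimeError(f"CJS optimizer failed: {res.message}; best phi={phi}, p={p}")
        return CJSParameters(phi, p)

    if mode == "cohort":
        return fit_matrix(H)
    return [fit_matrix(H[i : i + 1]) for i in range(H.shape[0])]


def alive_posterior(history, params: CJSParameters) -> float:
    """P(alive at the final occasion | history) under the fitted parameters."""
    history = np.asarray(history, dtype=int)
    _, alive = _forward(history, params.phi, params.p)
    return float(alive)


def label_survival(history, fit: CJSParameters, mode: str = "cohort"):
    """Overall apparent-survival probability and binary label for one bird.

    ``per_bird`` multiplies the fitted interval survival probabilities
    (product of phi_t); ``cohort`` uses the posterior probability of being
    alive at the final occasion given the shared parameters.  Label is
    1 iff the probability exceeds 0.5.
    """
    if mode == "per_bird":
        prob = float(np.prod(fit.phi))
    elif mode == "cohort":
        prob = alive_posterior(history, fit)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return prob, int(prob > 0.5)


def label_cohort(histories, mode: str = "cohort"):
    """Fit and label a whole cohort; returns (probs, labels, fit)."""
    H = np.asarray(histories, dtype=int)
    if mode == "cohort":
        fit = fit_cjs(H, mode="cohort")
        out = [label_survival(H[i], fit, mode="cohort") for i in range(H.shape[0])]
    else:
        fits = fit_cjs(H, mode="per_bird")
        out = [label_survival(H[i], f, mode="per_bird") for i, f in zip(range(H.shape[0]), fits)]
        fit = fits
    probs = np.array([o[0] for o in out])
    labels = np.array([o[1] for o in out], dtype=int)
    return probs, labels, fit
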
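"""Maximum-likelihood estimation of polarity → division-mode transition
probabilities.

The transition model has two parameters: ``d_a``, the probability that a
polar HSC divides asymmetrically, and ``d_s``, the probability that an
apolar HSC divides symmetrically.  In a condition where a fraction
``p_polar`` of cells is polar, the probability of observing an
asymmetric division is

    P(asym) = p_polar * d_a + (1 - p_polar) * (1 - d_s)

and the number of asymmetric divisions among ``n_pairs`` scored
divisions is binomial.  ``TransitionMLE`` maximizes the summed binomial
log-likelihood over [0, 1]^2 (coarse grid seed, then bounded
Nelder-Mead) and reports profile-likelihood confidence intervals.
Polar fractions are treated as known plug-in inputs, not estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import binom, chi2
from sklearn.base import BaseEstimator

__all__ = [
    "TransitionParams",
    "ConditionObservation",
    "TransitionMLE",
    "asym_probability",
    "log_likelihood",
    "fit_mle",
    "simulate_observations",
]


@dataclass(frozen=True)
class TransitionParams:
    d_a: float
    d_s: float

    def __post_init__(self):
        if not (0 <= self.d_a <= 1 and 0 <= self.d_s <= 1):
            raise ValueError("d_a and d_s must lie in [0, 1]")


@dataclass(frozen=True)
class ConditionObservation:
    """Division-mode counts for one experimental condition."""

    label: str
    p_polar: float
    n_pairs: int
    k_asym: int

    def __post_init__(self):
        if not 0 <= self.p_polar <= 1:
            raise ValueError("p_polar must lie in [0, 1]")
        if not 0 <= self.k_asym <= self.n_pairs:
            raise ValueError("need 0 <= k_asym <= n_pairs")


def asym_probability(params: TransitionParams, p_polar: float) -> float:
    """Probability of an asymmetric division at polar fraction ``p_polar``."""
    if not 0 <= p_polar <= 1:
        raise ValueError("p_polar must lie in [0, 1]")
    return p_polar * params.d_a + (1.0 - p_polar) * (1.0 - params.d_s)


def log_likelihood(params: TransitionParams,
                   observations: list[ConditionObservation]) -> float:
    """Summed binomial log-likelihood of the observed division modes."""
    if not observations:
        raise ValueError("need at least one observation")
    total = 0.0
    for obs in observations:
        p = asym_probability(params, obs.p_polar)
        total += binom.logpmf(obs.k_asym, obs.n_pairs, p)
    return float(total)


class TransitionMLE(BaseEstimator):
    """Maximum-likelihood estimator of the transition probabilities.

    Parameters
    ----------
    grid_size : int
        Resolution of the coarse (d_a, d_s) grid used to seed the local
        refinement.
    ci_level : float
        Coverage of the profile-likelihood confidence intervals.
    flat_tol : float
        A parameter whose profile log-likelihood varies by less than
        this across [0, 1] is flagged non-identifiable.

    Attributes
    ----------
    d_a_, d_s_ : float
        Maximum-likelihood estimates.
    loglik_ : float
        Log-likelihood at the optimum.
    ci_d_a_, ci_d_s_ : tuple(float, float)
        Profile-likelihood confidence intervals.
    identifiable_d_a_, identifiable_d_s_ : bool
        False when the profile is flat (e.g. all conditions share one
        polar fraction).
    """

    def __init__(self, grid_size: int = 101, ci_level: float = 0.95,
                 flat_tol: float = 1e-6, compute_ci: bool = True):
        self.grid_size = grid_size
        self.ci_level = ci_level
        self.flat_tol = flat_tol
        self.compute_ci = compute_ci

    def fit(self, observations: list[ConditionObservation], y=None):
        obs = list(observations)
        if not obs:
            raise ValueError("need at least one observation")
        for o in obs:
            if not isinstance(o, ConditionObservation):
                raise TypeError("observations must be ConditionObservation")

        n = np.array([o.n_pairs for o in obs], dtype=float)
        k = np.array([o.k_asym for o in obs], dtype=float)
        pp = np.array([o.p_polar for o in obs], dtype=float)

        def nll(theta):
            da, ds = np.clip(theta, 0.0, 1.0)
            p = np.clip(pp * da + (1 - pp) * (1 - ds), 0.0, 1.0)
            with np.errstate(divide="ignore"):
                val = -float(np.sum(binom.logpmf(k, n, p)))
            return val if math.isfinite(val) else 1e18  # impossible observation

        g = np.linspace(0.0, 1.0, self.grid_size)
        DA, DS = np.meshgrid(g, g, indexing="ij")
        P = pp[None, None, :] * DA[..., None] + (1 - pp)[None, None, :] * (1 - DS[..., None])
        with np.errstate(divide="ignore", invalid="ignore"):
            LL = binom.logpmf(k[None, None, :], n[None, None, :], P).sum(axis=-1)
        i, j = np.unravel_index(np.nanargmax(np.where(np.isfinite(LL), LL, -np.inf)), LL.shape)
        x0 = np.array([DA[i, j], DS[i, j]])

        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
        best = np.clip(res.x, 0.0, 1.0)
        if nll(best) > nll(x0):
            best = x0
        self.d_a_, self.d_s_ = float(best[0]), float(best[1])
        self.loglik_ = -nll(best)
        self.n_conditions_ = len(obs)

        if self.compute_ci:
            self.identifiable_d_a_, self.ci_d_a_ = self._profile(nll, 0, best)
            self.identifiable_d_s_, self.ci_d_s_ = self._profile(nll, 1, best)
        else:
            self.identifiable_d_a_ = self.identifiable_d_s_ = True
            self.ci_d_a_ = self.ci_d_s_ = (float("nan"), float("nan"))
        return self

    def _profile(self, nll, axis: int, best: np.ndarray):
        """Profile log-likelihood CI for one parameter; detects flatness."""
        cutoff = chi2.ppf(self.ci_level, df=1) / 2.0
        ll_hat = -nll(best)

        def profile_ll(v):
            other = 1 - axis

            def nll1(u):
                theta = np.empty(2)
                theta[axis] = v
                theta[other] = np.clip(u[0], 0, 1)
                return nll(theta)

            r = minimize(nll1, [best[other]], method="Nelder-Mead",
                         options={"xatol": 1e-7, "fatol": 1e-9})
            return -min(r.fun, nll1([best[other]]))

        grid = np.linspace(0.0, 1.0, 21)
        prof = np.array([profile_ll(v) for v in grid])
        finite = prof[np.isfinite(prof)]
        if finite.size and finite.max() - finite.min() < self.flat_tol:
            return False, (0.0, 1.0)

        def drop(v):
            return profile_ll(v) - (ll_hat - cutoff)

        vhat = best[axis]
        lo = 0.0 if drop(0.0) >= 0 else brentq(drop, 0.0, vhat, xtol=1e-6)
        hi = 1.0 if drop(1.0) >= 0 else brentq(drop, vhat, 1.0, xtol=1e-6)
        return True, (float(lo), float(hi))

    @property
    def params_(self) -> TransitionParams:
        return TransitionParams(self.d_a_, self.d_s_)

    def predict_proba(self, p_polar) -> np.ndarray:
        """Asymmetric-division probability at the fitted parameters."""
        p_polar = np.atleast_1d(np.asarray(p_polar, dtype=float))
        return p_polar * self.d_a_ + (1 - p_polar) * (1 - self.d_s_)

    def score(self, observations: list[ConditionObservation], y=None) -> float:
        return log_likelihood(self.params_, observations)


def fit_mle(observations: list[ConditionObservation], **kwargs) -> TransitionMLE:
    """Fit the transition model; thin wrapper over :class:`TransitionMLE`."""
    return TransitionMLE(**kwargs).fit(observations)


def simulate_observations(params: TransitionParams,
                          design: list[tuple[float, int]],
                          seed: int | np.random.Generator = 0,
                          labels: list[str] | None = None
                          ) -> list[ConditionObservation]:
    """Draw division-mode counts from the transition model.

    Per condition ``(p_polar, n_pairs)``: each pair's mother is polar with
    probability ``p_polar``; polar mothers divide asymmetrically with
    probability ``d_a``, apolar mothers with probability ``1 - d_s``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for idx, (p_polar, n_pairs) in enumerate(design):
        polar = rng.random(n_pairs) < p_polar
        p_asym = np.where(polar, params.d_a, 1.0 - params.d_s)
        k = int((rng.random(n_pairs) < p_asym).sum())
        label = labels[idx] if labels else f"condition_{idx}"
        out.append(ConditionObservation(label=label, p_polar=float(p_polar),
                                        n_pairs=int(n_pairs), k_asym=k))
    return out
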
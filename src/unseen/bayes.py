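"""Bayes factors for directional hypotheses about contrast means.

Three prior families over the population mean of an analysis vector:

* half-normal starting at zero (``BF_main``), SD set from the orthogonal
  active-vs-sham contrast — small changes more probable than large ones;
* uniform over a bounded range implied by the measure's scale
  (``BF_uni``);
* the default JZS prior, a Cauchy on standardized effect size with scale
  r = 0.707 (``BF_jzs``).

For the first two families the likelihood of a candidate mean is, by
default, a shifted/scaled t density of the observed mean difference (its
standard error and df), honouring small-sample uncertainty; a normal
likelihood is available as an option.  BF > 1 favours the (directional)
alternative; BF < 1 favours the null.  A sequential stopping rule on a BF
trajectory (stop at BF >= 3 or <= 1/3) is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import cauchy, nct, norm, t as t_dist

#: Integration limit for half-normal/uniform quadrature, in prior SDs.
DEFAULT_LIMIT_SDS = 10.0
QUAD_RTOL = 1e-6

STOP_UPPER = 3.0
STOP_LOWER = 1.0 / 3.0


class BayesFactorError(ArithmeticError):
    """Quadrature failed to converge or inputs are degenerate."""


@dataclass(frozen=True)
class PriorSpec:
    """Prior family, direction and scale of a Bayes-factor test."""

    family: str  # half_normal | uniform | jzs
    direction: str = "two_sided"  # positive | negative | two_sided
    scale: float = math.nan  # half-normal SD, or JZS r
    lower: float = math.nan  # uniform only
    upper: float = math.nan

    def __post_init__(self) -> None:
        if self.family not in ("half_normal", "uniform", "jzs"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "uniform" and not self.lower < self.upper:
            raise ValueError("uniform prior requires lower < upper")
        if self.family in ("half_normal", "jzs") and not self.scale > 0:
            raise ValueError("prior scale must be > 0")


@dataclass(frozen=True)
class LikelihoodSummary:
    """Sufficient summary of an analysis vector: mean difference, SE, df."""

    mean_diff: float
    se: float
    df: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be > 0")
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass(frozen=True)
class BayesResult:
    bf: float
    prior: PriorSpec
    likelihood: LikelihoodSummary | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.bf) and self.bf > 0):
            raise BayesFactorError(f"Bayes factor {self.bf!r} not finite positive")


def prior_sd_from_orthogonal(active_sham_mean_diff: float, as_variance: bool = False) -> float:
    """Half-normal scale from the orthogonal active-vs-sham mean difference.

    Default convention: SD = |difference| / 2.  ``as_variance=True`` reads
    the rule as variance = |difference| / 2 instead (sensitivity option).
    A zero difference yields 0, which downstream code must treat as a
    degenerate (undefined) prior.
    """
    half = abs(active_sham_mean_diff) / 2.0
    return math.sqrt(half) if as_variance else half


def _likelihood_fn(lik: LikelihoodSummary, likelihood: str):
    """Density of the observed mean difference as a function of the true mean."""
    if likelihood == "t":
        return lambda theta: t_dist.pdf((lik.mean_diff - theta) / lik.se, lik.df) / lik.se
    if likelihood == "normal":
        return lambda theta: norm.pdf(lik.mean_diff, loc=theta, scale=lik.se)
    raise ValueError(f"unknown likelihood {likelihood!r}")


def _quad(f, a: float, b: float) -> float:
    val, err = integrate.quad(f, a, b, epsabs=0.0, epsrel=QUAD_RTOL, limit=400)
    if not math.isfinite(val):
        raise BayesFactorError("quadrature did not converge")
    return val


def bf_half_normal(
    lik: LikelihoodSummary,
    prior_sd: float,
    direction: str = "positive",
    likelihood: str = "t",
    limit_sds: float = DEFAULT_LIMIT_SDS,
    label: str = "BF_main",
) -> BayesResult:
    """Bayes factor under a half-normal prior starting at zero.

    ``direction='positive'`` places the prior mass on means > 0,
    ``'negative'`` on means < 0 (computed by reflecting the data, so
    direction anti-symmetry is exact).
    """
    if not prior_sd > 0:
        raise BayesFactorError("half-normal prior SD must be > 0 (degenerate prior)")
    if direction == "negative":
        flipped = LikelihoodSummary(-lik.mean_diff, lik.se, lik.df)
        res = bf_half_normal(flipped, prior_sd, "positive", likelihood, limit_sds, label)
        return BayesResult(res.bf, PriorSpec("half_normal", "negative", prior_sd), lik, label)
    if direction != "positive":
        raise ValueError("half-normal direction must be 'positive' or 'negative'")
    L = _likelihood_fn(lik, likelihood)
    prior = lambda th: 2.0 * norm.pdf(th, 0.0, prior_sd)
    num = _quad(lambda th: L(th) * prior(th), 0.0, limit_sds * prior_sd)
    bf = num / L(0.0)
    return BayesResult(bf, PriorSpec("half_normal", direction, prior_sd), lik, label)


def bf_uniform(
    lik: LikelihoodSummary,
    lower: float,
    upper: float,
    likelihood: str = "t",
    label: str = "BF_uni",
) -> BayesResult:
    """Bayes factor under a uniform prior on [lower, upper]."""
    if not lower < upper:
        raise BayesFactorError("uniform prior requires lower < upper")
    L = _likelihood_fn(lik, likelihood)
    num = _quad(L, lower, upper) / (upper - lower)
    bf = num / L(0.0)
    return BayesResult(bf, PriorSpec("uniform", "two_sided", lower=lower, upper=upper, scale=math.nan), lik, label)


def bf_jzs(t: float, n: int, r: float = 0.707, label: str = "BF_jzs") -> BayesResult:
    """One-sample JZS Bayes factor (BF10) from a t statistic.

    Cauchy(0, r) prior on the standardized effect delta; the marginal
    likelihood under H1 integrates the noncentral-t density of the observed
    t over the prior, and H0 is the central t.
    """
    if n < 2:
        raise BayesFactorError("jzs requires n >= 2")
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta: float) -> float:
        return nct.pdf(t, nu, delta * sqrt_n) * cauchy.pdf(delta, 0.0, r)

    # Split at 0 to help the quadrature with the Cauchy peak.
    num = _quad(integrand, -np.inf, 0.0) + _quad(integrand, 0.0, np.inf)
    bf = num / t_dist.pdf(t, nu)
    return BayesResult(bf, PriorSpec("jzs", "two_sided", scale=r), None, label)


def sequential_stop(
    bf_trajectory,
    upper: float = STOP_UPPER,
    lower: float = STOP_LOWER,
) -> tuple[str, int | None]:
    """Apply the optional-stopping rule to a BF trajectory.

    Returns ``("support_h1", i)`` at the first index with BF >= upper,
    ``("support_null", i)`` at the first BF <= lower (both inclusive),
    else ``("continue", None)``.
    """
    for i, bf in enumerate(bf_trajectory):
        if bf >= upper:
            return "support_h1", i
        if bf <= lower:
            return "support_null", i
    return "continue", None
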
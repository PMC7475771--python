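"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's quadrature code paths: plain
Riemann/trapezoid sums on dense grids over the scipy densities.
"""

import numpy as np
from scipy.stats import cauchy, nct, norm, t as t_dist


def t_likelihood(theta: np.ndarray, mean_diff: float, se: float, df: int) -> np.ndarray:
    return t_dist.pdf((mean_diff - theta) / se, df) / se


def riemann_bf_half_normal(
    mean_diff: float, se: float, df: int, prior_sd: float,
    direction: str = "positive", n_grid: int = 200_001,
) -> float:
    sign = 1.0 if direction == "positive" else -1.0
    theta = sign * np.linspace(0.0, 12.0 * prior_sd, n_grid)
    prior = 2.0 * norm.pdf(theta, 0.0, prior_sd)
    lik = t_likelihood(theta, mean_diff, se, df)
    num = np.trapezoid(prior * lik, theta) * sign
    return num / t_likelihood(np.array([0.0]), mean_diff, se, df)[0]


def riemann_bf_uniform(
    mean_diff: float, se: float, df: int, lower: float, upper: float,
    n_grid: int = 200_001,
) -> float:
    theta = np.linspace(lower, upper, n_grid)
    lik = t_likelihood(theta, mean_diff, se, df)
    num = np.trapezoid(lik, theta) / (upper - lower)
    return num / t_likelihood(np.array([0.0]), mean_diff, se, df)[0]


def riemann_bf_jzs(t: float, n: int, r: float = 0.707, n_grid: int = 200_001) -> float:
    # Wide enough for the Cauchy tails at this precision.
    delta = np.linspace(-60.0 * r, 60.0 * r, n_grid)
    integrand = nct.pdf(t, n - 1, delta * np.sqrt(n)) * cauchy.pdf(delta, 0.0, r)
    return np.trapezoid(integrand, delta) / t_dist.pdf(t, n - 1)
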
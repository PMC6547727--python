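"""Derived quantities: heritability, genetic correlation, Venn counts, power.

A fitted mixture is rarely interesting in its raw parameters.  This module
turns (pi, sigma_beta^2, ...) into the quantities practitioners report:

* observed-scale SNP heritability  h^2 = pi1 * H_total * sigma_beta^2;
* genome-wide genetic correlation  r_g = rho12 * pi12 / sqrt(pi1u * pi2u),
  which separates the effect-size correlation inside the shared component
  (rho12) from the amount of sharing (pi12);
* Venn-diagram counts of unique/shared causal variants, rescaled so that the
  reported variants jointly explain a given fraction of heritability (by
  default 90%) -- under a Gaussian effect prior many "causal" variants carry
  vanishingly small effects, and the rescaling avoids extrapolating into that
  regime;
* GWAS power curves S(N): the proportion of heritability captured by
  genome-wide-significant SNPs at sample size N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .likelihood import SnpContext, _eta
from .params import BivariateParams, UnivariateParams
from .uncertainty import ParamCovariance, propagate


def significance_z(alpha: float) -> float:
    """Two-sided Gaussian quantile: z with 2(1 - Phi(z)) = alpha."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    return float(stats.norm.isf(alpha / 2.0))


#: z-score of the standard genome-wide significance threshold 5e-8.
GENOME_WIDE_Z = 5.45


def heritability(p: UnivariateParams, h_total: float) -> float:
    """Observed-scale SNP heritability  h^2 = pi1 * H_total * sigma_beta^2.

    ``h_total`` is the summed heterozygosity of the reference,
    sum_j 2 p_j (1 - p_j).
    """
    return p.pi1 * h_total * p.sigma_beta2


def genetic_correlation(p: BivariateParams) -> float:
    """Genome-wide genetic correlation  r_g = rho12 * pi12 / sqrt(pi1u pi2u)."""
    pi1u, pi2u = p.pi1u, p.pi2u
    if pi1u <= 0.0 or pi2u <= 0.0:
        raise ValueError("genetic correlation undefined at zero total polygenicity")
    return p.rho12 * p.pi12 / float(np.sqrt(pi1u * pi2u))


def genetic_correlation_from_counts(
    n12: float, n1: float, n2: float, rho12: float
) -> float:
    """r_g from causal-variant counts (any common scale, e.g. thousands)."""
    if n12 + n1 <= 0 or n12 + n2 <= 0:
        raise ValueError("total causal counts must be positive")
    return rho12 * n12 / float(np.sqrt((n1 + n12) * (n2 + n12)))


def causal_fraction_for_h2(
    p: UnivariateParams,
    het_sample: np.ndarray,
    target: float = 0.9,
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """Fraction of causal variants jointly explaining ``target`` of heritability.

    Monte-Carlo: sample ``n_draws`` causal variants (heterozygosities resampled
    from ``het_sample``), draw effects from N(0, sigma_beta^2), sort the
    per-variant contributions beta^2 * p(1-p) in decreasing order, and report
    the smallest fraction whose cumulative contribution reaches the target.
    Invariant to rescaling sigma_beta^2.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target must be in (0, 1]")
    het_sample = np.asarray(het_sample, dtype=float)
    if het_sample.size == 0:
        raise ValueError("het_sample must be nonempty")
    rng = np.random.default_rng(seed)
    het = rng.choice(het_sample, size=n_draws, replace=True)
    beta = rng.normal(0.0, np.sqrt(max(p.sigma_beta2, 1e-300)), size=n_draws)
    contrib = np.sort(beta**2 * het / 2.0)[::-1]  # het = 2p(1-p) => p(1-p) = het/2
    cum = np.cumsum(contrib)
    k = int(np.searchsorted(cum, target * cum[-1])) + 1
    return min(k / n_draws, 1.0)


@dataclass
class VennCounts:
    """Causal-variant counts (thousands) per Venn component, raw and adjusted."""

    n1: float
    n2: float
    n12: float
    se_n1: float
    se_n2: float
    se_n12: float
    raw_n1: float
    raw_n2: float
    raw_n12: float
    fraction_rule: float

    def to_dict(self) -> dict:
        return {
            "n1": self.n1, "n2": self.n2, "n12": self.n12,
            "se_n1": self.se_n1, "se_n2": self.se_n2, "se_n12": self.se_n12,
            "raw_n1": self.raw_n1, "raw_n2": self.raw_n2, "raw_n12": self.raw_n12,
            "fraction_rule": self.fraction_rule,
        }


def venn_counts(
    fit2_params: BivariateParams,
    m_ref: int,
    het_sample: np.ndarray,
    level: float = 0.9,
    cov: ParamCovariance | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> VennCounts:
    """Unique/shared causal-variant counts, adjusted to explain ``level`` of h^2.

    Unique components are scaled by their trait's explained-heritability
    fraction; the shared component by the geometric mean of the two traits'
    fractions.  Counts are reported in thousands.  SEs are propagated from the
    parameter error covariance when one is supplied.
    """
    f1 = causal_fraction_for_h2(fit2_params.trait(1), het_sample, level, seed=seed)
    f2 = causal_fraction_for_h2(fit2_params.trait(2), het_sample, level, seed=seed + 1)
    f12 = float(np.sqrt(f1 * f2))

    def counts(p: BivariateParams) -> np.ndarray:
        return np.array([p.pi1 * m_ref * f1, p.pi2 * m_ref * f2,
                         p.pi12 * m_ref * f12]) / 1e3

    c = counts(fit2_params)
    raw = np.array([fit2_params.pi1, fit2_params.pi2, fit2_params.pi12]) * m_ref / 1e3
    ses = np.zeros(3)
    if cov is not None:
        for k, picker in enumerate((lambda p: counts(p)[0],
                                    lambda p: counts(p)[1],
                                    lambda p: counts(p)[2])):
            _, ses[k] = propagate(cov, picker, n_draws=n_draws, seed=seed + 10 + k)
    return VennCounts(
        n1=float(c[0]), n2=float(c[1]), n12=float(c[2]),
        se_n1=float(ses[0]), se_n2=float(ses[1]), se_n12=float(ses[2]),
        raw_n1=float(raw[0]), raw_n2=float(raw[1]), raw_n12=float(raw[2]),
        fraction_rule=level,
    )


@dataclass
class PowerCurve:
    """Projected proportion of h^2 captured by significant SNPs vs sample size."""

    n_grid: np.ndarray
    s: np.ndarray
    z_t: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"N": self.n_grid, "S": self.s})


def power_curve(
    p: UnivariateParams,
    ctx: SnpContext,
    n_grid,
    z_t: float = GENOME_WIDE_Z,
    z_max: float = 38.0,
    z_step: float = 0.05,
    gh_nodes: int = 64,
) -> PowerCurve:
    """GWAS power curve S(N) over a grid of sample sizes.

    For each SNP context j the weight function
    ``C(z, N, j) = integral delta^2 P(z|delta) P(delta | j) d delta`` (with
    z | delta ~ N(delta, sigma0^2)) is evaluated by Gauss-Hermite quadrature
    over the causal-effect prior, and

        S(N) = sum_j int_{|z| >= z_t} C dz  /  sum_j int C dz.

    ``ctx`` is typically a random subsample (~1%) of reference SNP contexts.
    """
    if len(ctx) == 0:
        raise ValueError("power_curve needs a nonempty context sample")
    n_grid = np.asarray(n_grid, dtype=float)
    zg = np.arange(-z_max, z_max + z_step / 2, z_step)
    nodes, weights = np.polynomial.hermite.hermgauss(gh_nodes)
    sig0 = np.sqrt(p.sigma0_2)
    eta = _eta(p.pi1, ctx.ell, ctx.m4_ratio)
    pi_adj = np.clip(ctx.ell * p.pi1 / eta, 0.0, 1.0)

    s_vals = np.empty(len(n_grid))
    tail_mask = np.abs(zg) >= z_t
    for a, n in enumerate(n_grid):
        num = 0.0
        den = 0.0
        for j in range(len(ctx)):
            v = n * eta[j] * p.sigma_beta2
            if v <= 0 or pi_adj[j] <= 0:
                continue
            delta = np.sqrt(2.0 * v) * nodes  # GH change of variables
            # C_j(z) on the grid: pi'_j / sqrt(pi) * sum_i w_i delta_i^2 phi(z - delta_i)
            dens = stats.norm.pdf((zg[None, :] - delta[:, None]) / sig0) / sig0
            c_z = pi_adj[j] / np.sqrt(np.pi) * (
                (weights * delta**2) @ dens
            )
            num += np.trapezoid(np.where(tail_mask, c_z, 0.0), zg)
            den += np.trapezoid(c_z, zg)
        s_vals[a] = num / den if den > 0 else 0.0
    return PowerCurve(n_grid=n_grid, s=np.clip(s_vals, 0.0, 1.0), z_t=z_t)
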
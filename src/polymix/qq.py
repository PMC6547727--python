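"""Data and model-predicted Q-Q curves, overall, stratified and conditional.

A GWAS Q-Q plot draws observed -log10 p quantiles against the expectation
under the global null.  Points are weighted by random-pruning weights so that
large LD blocks do not overcount evidence.  The model-predicted curve comes
from the fitted mixture: the fast-model density is averaged over a random
sample of SNP LD contexts, numerically integrated into a survival function of
|z|, and mapped into the same coordinates.

Conditional Q-Q curves restrict the primary trait's curve to SNPs whose
secondary-trait association passes nested p-value thresholds; their model
counterparts integrate the bivariate density over the secondary stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import SnpContext, _biv_components
from .params import BivariateParams

DEFAULT_SECONDARY_THRESHOLDS = (1.0, 0.1, 0.01, 0.001)  # nested p <= t strata


@dataclass
class QQCurve:
    expected: np.ndarray  # -log10 p under the null
    observed: np.ndarray  # -log10 p quantile (data) or model prediction
    n_total: float
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    stratum: str = "all"

    def to_frame(self) -> pd.DataFrame:
        d = {"expected": self.expected, "observed": self.observed}
        if self.ci_lo is not None:
            d["ci_lo"] = self.ci_lo
            d["ci_hi"] = self.ci_hi
        df = pd.DataFrame(d)
        df["stratum"] = self.stratum
        return df


def _weighted_quantile_curve(p_vals, w, grid_q):
    """Observed p at each weighted lower-tail quantile level in grid_q.

    A right-continuous step quantile (smallest p whose cumulative weight
    reaches the level) keeps the curve invariant under duplicating SNPs with
    proportionally split weights.
    """
    order = np.argsort(p_vals)
    p_sorted = p_vals[order]
    cum = np.cumsum(w[order]) / w.sum()
    idx = np.clip(np.searchsorted(cum, grid_q - 1e-12, side="left"), 0,
                  len(p_sorted) - 1)
    return p_sorted[idx]


def data_qq(
    z: np.ndarray,
    weights,
    strata: dict | None = None,
    max_neglog10: float | None = None,
    step: float = 0.05,
) -> list[QQCurve]:
    """Weighted empirical Q-Q curves of p = 2(1 - Phi(|z|)).

    ``strata`` maps stratum labels to boolean masks over the SNPs; weights
    inside each stratum are renormalized.  The 95% band has half-width
    1.96 sqrt(q (1-q) / n_total) on the quantile scale, with n_total the sum
    of pruning weights in the stratum.
    """
    z = np.asarray(z, dtype=float)
    w = weights.w if hasattr(weights, "w") else np.asarray(weights, dtype=float)
    if strata is None:
        strata = {"all": np.ones(len(z), dtype=bool)}
    curves = []
    for label, mask in strata.items():
        mask = np.asarray(mask, dtype=bool) & (w > 0)
        if not mask.any():
            import warnings

            warnings.warn(f"empty Q-Q stratum {label!r} omitted", stacklevel=2)
            continue
        p_vals = 2.0 * stats.norm.sf(np.abs(z[mask]))
        wm = w[mask]
        n_total = float(wm.sum())
        top = max_neglog10 or max(np.log10(n_total), 1.0)
        expected = np.arange(0.0, top + step / 2, step)
        q = 10.0 ** (-expected)
        obs_p = _weighted_quantile_curve(p_vals, wm, q)
        observed = -np.log10(np.clip(obs_p, 1e-320, 1.0))
        # binomial CI on the quantile level, mapped through the observed curve
        hw = 1.96 * np.sqrt(q * (1.0 - q) / n_total)
        p_hi = _weighted_quantile_curve(p_vals, wm, np.clip(q - hw, 0.0, 1.0))
        p_lo = _weighted_quantile_curve(p_vals, wm, np.clip(q + hw, 0.0, 1.0))
        ci_hi = -np.log10(np.clip(p_hi, 1e-320, 1.0))
        ci_lo = -np.log10(np.clip(p_lo, 1e-320, 1.0))
        curves.append(
            QQCurve(expected=expected, observed=observed, n_total=n_total,
                    ci_lo=ci_lo, ci_hi=ci_hi, stratum=label)
        )
    return curves


def _survival_from_pdf(zg: np.ndarray, pdf_half: np.ndarray) -> np.ndarray:
    """Two-sided survival P(|Z| >= z) from a symmetric density on z >= 0."""
    # reverse cumulative trapezoid of the half-line density, doubled
    rev = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf_half[1:] + pdf_half[:-1]) * np.diff(zg)
    )])
    total = rev[-1]
    return np.clip(2.0 * (total - rev) + (1.0 - 2.0 * total), 0.0, 1.0)


def model_qq(
    params,
    ctx: SnpContext,
    strata: dict | None = None,
    z2_thresholds=None,
    z_max: float = 38.0,
    z_step: float = 0.05,
) -> list[QQCurve]:
    """Model-predicted Q-Q curves from the fast-model density.

    For univariate ``params``, the density is averaged over the SNP contexts
    in ``ctx`` (optionally within each stratum mask).  For bivariate
    ``params`` with ``z2_thresholds`` (nested secondary-trait p-value cut
    points), each stratum's curve integrates the bivariate density over
    |z2| >= z(t), reproducing the conditional Q-Q construction.
    """
    zg = np.arange(0.0, z_max + z_step / 2, z_step)
    p_null = 2.0 * stats.norm.sf(zg)
    # a model Q-Q point at z: x = -log10 of the model quantile level
    # P_model(|Z| >= z), y = -log10 of the p-value attached to z
    observed = -np.log10(np.clip(p_null, 1e-320, 1.0))
    curves = []

    if isinstance(params, BivariateParams):
        thresholds = (
            DEFAULT_SECONDARY_THRESHOLDS if z2_thresholds is None else z2_thresholds
        )
        for p_thr in thresholds:
            dens, mass = _conditional_density(params, ctx, zg, p_thr)
            surv = _survival_from_pdf(zg, dens / max(mass, 1e-300))
            expected = -np.log10(np.clip(surv, 1e-320, 1.0))
            curves.append(
                QQCurve(expected=expected, observed=observed,
                        n_total=float(len(ctx)), stratum=f"p2<={p_thr:g}")
            )
        return curves

    if strata is None:
        strata = {"all": np.ones(len(ctx), dtype=bool)}
    for label, mask in strata.items():
        idx = np.nonzero(np.asarray(mask, dtype=bool))[0]
        if idx.size == 0:
            continue
        sub = ctx.subset(idx)
        # the model survival is an analytic mixture of Gaussian tails, so no
        # numerical integration error enters the extreme tail; the
        # sparse-convolution evaluator is preferred when neighbour arrays are
        # available, the moment-matched fast model otherwise
        from .likelihood import conv_tail_uni, fast_tail_uni

        if sub.has_neighbors:
            surv = np.stack([conv_tail_uni(z, params, sub).mean() for z in zg])
        else:
            surv = np.stack([fast_tail_uni(z, params, sub).mean() for z in zg])
        surv[0] = 1.0
        expected = -np.log10(np.clip(surv, 1e-320, 1.0))
        curves.append(
            QQCurve(expected=expected, observed=observed,
                    n_total=float(idx.size), stratum=label)
        )
    return curves


def _conditional_density(
    params: BivariateParams, ctx: SnpContext, zg: np.ndarray, p_thr: float
) -> tuple[np.ndarray, float]:
    """Average density of z1 restricted to the secondary stratum |z2| >= z(t).

    Each of the 8 fast-model components factorizes as
    phi(z1; v1) * N(z2 | c z1 / v1, v2 - c^2/v1), so the stratum integral over
    z2 is a Gaussian tail evaluated at each z1.
    """
    t = 0.0 if p_thr >= 1.0 else float(stats.norm.isf(p_thr / 2.0))
    w, v1, v2, c12 = _biv_components(params, ctx)
    res_c = params.rho0 * np.sqrt(params.sigma01_2 * params.sigma02_2)
    dens = np.zeros_like(zg)
    mass = 0.0
    m = len(ctx)
    for b1 in (0, 1):
        for b2 in (0, 1):
            for b12 in (0, 1):
                wt = np.ones(m)
                for on, wc in zip((b1, b2, b12), w):
                    wt = wt * (wc if on else (1.0 - wc))
                vv1 = params.sigma01_2 + b1 * v1[0] + b12 * v1[2]
                vv2 = params.sigma02_2 + b2 * v2[1] + b12 * v2[2]
                cc = res_c + b12 * c12[2]
                sd1 = np.sqrt(vv1)
                cond_var = np.maximum(vv2 - cc**2 / vv1, 1e-12)
                cond_sd = np.sqrt(cond_var)
                # (G, M) conditional stratum probability given z1
                mu = cc / vv1 * zg[:, None]
                if t == 0.0:
                    tail = np.ones_like(mu)
                else:
                    tail = stats.norm.sf((t - mu) / cond_sd) + stats.norm.sf(
                        (t + mu) / cond_sd
                    )
                phi1 = stats.norm.pdf(zg[:, None] / sd1) / sd1
                dens += (wt * phi1 * tail).mean(axis=1)
                if t == 0.0:
                    comp_mass = wt
                else:
                    comp_mass = wt * 2.0 * stats.norm.sf(t / np.sqrt(vv2))
                mass += float(np.mean(comp_mass))
    return dens, mass


def maf_ld_strata(maf: np.ndarray, ell: np.ndarray, n_bins: int = 3) -> dict:
    """Tertile (by default) MAF x LD-score bins as Q-Q stratum masks."""
    maf_edges = np.quantile(maf, np.linspace(0, 1, n_bins + 1))
    ell_edges = np.quantile(ell, np.linspace(0, 1, n_bins + 1))
    strata = {}
    for a in range(n_bins):
        m_lo, m_hi = maf_edges[a], maf_edges[a + 1]
        m_mask = (maf >= m_lo) & (maf <= m_hi if a == n_bins - 1 else maf < m_hi)
        for b in range(n_bins):
            l_lo, l_hi = ell_edges[b], ell_edges[b + 1]
            l_mask = (ell >= l_lo) & (ell <= l_hi if b == n_bins - 1 else ell < l_hi)
            strata[f"maf{a + 1}_ld{b + 1}"] = m_mask & l_mask
    return strata


def conditional_strata(z2: np.ndarray, thresholds=DEFAULT_SECONDARY_THRESHOLDS) -> dict:
    """Nested secondary-trait strata masks: p2 <= t for each threshold."""
    p2 = 2.0 * stats.norm.sf(np.abs(np.asarray(z2, dtype=float)))
    return {f"p2<={t:g}": p2 <= t for t in thresholds}
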
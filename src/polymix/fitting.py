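"""Staged maximum-likelihood estimation of the mixture parameters.

The likelihood surface couples polygenicity pi and discoverability
sigma_beta^2 through their product (which pins down heritability), so naive
joint optimization is fragile.  The univariate fit therefore proceeds in three
Nelder-Mead stages:

1. infinitesimal constraint pi = 1: fit the product sigma^2_inf = pi*sigma^2
   and initialize the residual variance sigma0^2;
2. constrained pi * sigma^2 = sigma^2_inf: split the product into its factors
   by searching along log(pi / sigma^2), the soft direction of the surface;
3. unconstrained joint fit of (pi, sigma^2, sigma0^2) in the coordinates
   (log(pi sigma^2), log(pi / sigma^2), log sigma0^2).

The bivariate fit freezes each trait's univariate parameters and proceeds in
two stages: (A) an infinitesimal (pi12 = 1) fit of the genome-wide genetic
correlation r_g and the residual correlation rho0; (B) a fit of the shared
component weight pi12 with rho12 derived from the stage-A r_g
(rho12 = r_g sqrt(pi1u pi2u) / pi12, clipped to [-1, 1]), optionally followed
by a polish releasing (pi12, rho12) jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .likelihood import SnpContext, censored_loglik, weighted_loglik
from .params import BivariateParams, UnivariateParams

PI_FLOOR = 1e-7


@dataclass
class FitOptions:
    """Options shared by the univariate and bivariate fit procedures.

    ``model`` selects the likelihood for the final stage: "fast"
    (method-of-moments), "conv" (deterministic sparse-regime evaluation of
    the causal-configuration model, the default) or "full" (Monte-Carlo over
    K sampled configurations); earlier stages always use the fast model.
    ``censor_z`` enables right-censoring of |z| beyond the threshold.
    """

    model: str = "conv"
    K: int = 200
    seed: int = 0
    censor_z: float | None = None
    max_iter: int = 500
    fatol: float = 1e-4
    xatol: float = 1e-4
    polish_rho: bool = True  # release (pi12, rho12) jointly after stage B


@dataclass
class FitResult:
    params: object
    loglik: float
    n_effective: float
    aic: float
    bic: float
    trace: list = field(default_factory=list)
    converged: bool = True
    se: dict | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "class": type(self.params).__name__,
            "loglik": self.loglik,
            "n_effective": self.n_effective,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "se": self.se,
            "trace": self.trace,
            "software": {"name": "polymix", "version": "0.1.0"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        cls_map = {"UnivariateParams": UnivariateParams, "BivariateParams": BivariateParams}
        params = cls_map[d["class"]].from_dict(d["params"])
        return cls(
            params=params,
            loglik=d["loglik"],
            n_effective=d["n_effective"],
            aic=d["aic"],
            bic=d["bic"],
            trace=d.get("trace", []),
            converged=d.get("converged", True),
            se=d.get("se"),
        )


def information_criteria(loglik: float, k: int, n_effective: float) -> tuple[float, float]:
    """AIC = 2k - 2F and BIC = k ln(n) - 2F with n the effective SNP count."""
    if n_effective <= 0:
        raise ValueError("n_effective must be positive")
    aic = 2.0 * k - 2.0 * loglik
    bic = k * float(np.log(n_effective)) - 2.0 * loglik
    return aic, bic


def _loglik(params, z, ctx, weights, options: FitOptions, model: str) -> float:
    if options.censor_z is not None:
        val = censored_loglik(
            params, z, ctx, weights, z_t=options.censor_z,
            model=model, K=options.K, seed=options.seed,
        )
    else:
        val = weighted_loglik(
            params, z, ctx, weights, model=model, K=options.K, seed=options.seed
        )
    # keep the simplex objective finite on degenerate parameter points
    return val if np.isfinite(val) else -1e30


def _minimize(fun, x0, options: FitOptions):
    res = optimize.minimize(
        fun,
        np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        options={
            "maxiter": options.max_iter,
            "fatol": options.fatol,
            "xatol": options.xatol,
        },
    )
    return res


def _uni_from_ab(a: float, b: float, sigma0_2: float) -> tuple[UnivariateParams, float]:
    """Map (log(pi*s2), log(pi/s2)) to parameters, with a penalty outside pi bounds."""
    log_pi = 0.5 * (a + b)
    penalty = 0.0
    if log_pi > 0.0:  # pi > 1: clamp, preserving the product pi*s2
        penalty = 1e3 * log_pi**2
        log_pi = 0.0
    if log_pi < np.log(PI_FLOOR):
        penalty += 1e3 * (log_pi - np.log(PI_FLOOR)) ** 2
        log_pi = np.log(PI_FLOOR)
    pi = float(np.exp(log_pi))
    s2 = float(np.exp(a - log_pi))
    return UnivariateParams(pi, s2, sigma0_2), penalty


def fit_univariate(z, ctx: SnpContext, weights, options: FitOptions | None = None) -> FitResult:
    """Three-stage univariate fit of (pi1, sigma_beta2, sigma0_2)."""
    options = options or FitOptions()
    z = np.asarray(z, dtype=float)
    w = weights.w if hasattr(weights, "w") else np.asarray(weights, dtype=float)
    n_eff = float(w.sum())
    active = w > 0
    if not active.all():  # drop zero-weight SNPs once, not per evaluation
        idx = np.nonzero(active)[0]
        z, ctx, w = z[idx], ctx.subset(idx), w[idx]
    weights = w
    trace: list = []
    converged = True

    # moment-based initial guess: mean z^2 ~ n * ell * s2_inf + sigma0^2
    wsum = w.sum()
    mean_z2 = float((w * z**2).sum() / wsum)
    mean_nl = float((w * ctx.n1 * ctx.ell).sum() / wsum)
    s2_inf0 = max((mean_z2 - 1.0) / mean_nl, 1e-4 / mean_nl)

    # stage 1: infinitesimal (pi = 1)
    def nll1(x):
        p = UnivariateParams(1.0, float(np.exp(x[0])), float(np.exp(x[1])))
        return -_loglik(p, z, ctx, weights, options, "fast")

    r1 = _minimize(nll1, [np.log(s2_inf0), 0.0], options)
    s2_inf = float(np.exp(r1.x[0]))
    sigma0_1 = float(np.exp(r1.x[1]))
    trace.append({"stage": 1, "loglik": -r1.fun, "s2_inf": s2_inf,
                  "sigma0_2": sigma0_1, "converged": bool(r1.success)})
    converged &= bool(r1.success)

    # stage 2: split the product under the constraint pi * s2 = s2_inf.
    # The infinitesimal family cannot represent the kurtosis of a sparse
    # architecture and its ML product can collapse toward zero with an
    # inflated intercept; anchor the constraint at both the stage-1 ML value
    # and the moment value (with sigma0^2 near 1) and keep the better fit.
    anchors = [s2_inf, s2_inf0]
    sig0_inits = sorted({1.0, float(np.clip(sigma0_1, 0.25, 4.0))})

    best2 = None
    for s2_anchor in anchors:
        a_fix = float(np.log(max(s2_anchor, 1e-300)))

        def nll2(x, a_fix=a_fix):
            p, pen = _uni_from_ab(a_fix, float(x[0]), float(np.exp(x[1])))
            return -_loglik(p, z, ctx, weights, options, "fast") + pen

        # scan the soft direction b = log(pi/s2) over a wide pi range
        pis = np.array([1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0.5])
        starts = [
            ([float(np.log(pi**2 / s2_anchor)), float(np.log(s0))], None)
            for pi in pis
            for s0 in sig0_inits
        ]
        vals = [nll2(x0) for x0, _ in starts]
        x_init = starts[int(np.argmin(vals))][0]
        r2 = _minimize(nll2, x_init, options)
        if best2 is None or r2.fun < best2[0].fun:
            best2 = (r2, a_fix)
    r2, a_fix = best2
    p2, _ = _uni_from_ab(a_fix, float(r2.x[0]), float(np.exp(r2.x[1])))
    trace.append({"stage": 2, "loglik": -r2.fun, "params": p2.to_dict(),
                  "converged": bool(r2.success)})
    converged &= bool(r2.success)

    # stage 3: unconstrained joint fit
    def nll3(x):
        p, pen = _uni_from_ab(float(x[0]), float(x[1]), float(np.exp(x[2])))
        return -_loglik(p, z, ctx, weights, options, options.model) + pen

    x0 = [np.log(p2.pi1 * p2.sigma_beta2), np.log(p2.pi1 / p2.sigma_beta2),
          np.log(p2.sigma0_2)]
    r3 = _minimize(nll3, x0, options)
    p3, _ = _uni_from_ab(float(r3.x[0]), float(r3.x[1]), float(np.exp(r3.x[2])))
    loglik = -float(r3.fun)
    trace.append({"stage": 3, "loglik": loglik, "params": p3.to_dict(),
                  "model": options.model, "converged": bool(r3.success)})
    converged &= bool(r3.success)

    aic, bic = information_criteria(loglik, 3, n_eff)
    return FitResult(params=p3, loglik=loglik, n_effective=n_eff, aic=aic,
                     bic=bic, trace=trace, converged=converged)


def infinitesimal_sigma2(fit: FitResult) -> float:
    """Stage-1 infinitesimal effect variance pi*sigma^2 recorded in the trace."""
    return fit.trace[0]["s2_inf"]


def _stageB_params(
    f: float, pi1u: float, pi2u: float, rg: float,
    s1_2: float, s2_2: float, s01_2: float, s02_2: float, rho0: float,
    rho12_free: float | None = None,
) -> tuple[BivariateParams, bool]:
    """Assemble bivariate params for overlap fraction f = pi12 / min(pi1u, pi2u)."""
    pi_max = min(pi1u, pi2u)
    pi12 = max(f * pi_max, PI_FLOOR * pi_max)
    clipped = False
    if rho12_free is None:
        rho12 = rg * np.sqrt(pi1u * pi2u) / pi12
        if abs(rho12) > 0.999999:
            rho12 = float(np.clip(rho12, -0.999999, 0.999999))
            clipped = True
    else:
        rho12 = rho12_free
    pi1 = max(pi1u - pi12, 0.0)
    pi2 = max(pi2u - pi12, 0.0)
    excess = pi1 + pi2 + pi12 - 1.0
    if excess > 0:  # possible when a univariate fit sits at the pi = 1 boundary
        shrink = max(pi1 + pi2 - excess, 0.0) / max(pi1 + pi2, 1e-300)
        pi1 *= shrink
        pi2 *= shrink
    p = BivariateParams(
        pi1=pi1, pi2=pi2, pi12=pi12,
        sigma1_2=s1_2, sigma2_2=s2_2, rho12=float(rho12),
        sigma01_2=s01_2, sigma02_2=s02_2, rho0=rho0,
    )
    return p, clipped


def estimate_rho0_lowz(
    z1: np.ndarray,
    z2: np.ndarray,
    w: np.ndarray,
    sigma01_2: float,
    sigma02_2: float,
    z0: float = 1.64,
) -> float:
    """Residual correlation rho0 from the null-dominated low-|z| SNPs.

    The joint likelihood is nearly flat along a ridge trading genetic
    correlation against residual correlation when the GWAS signal is strong,
    so rho0 is pinned separately: among SNPs with |z| below ``z0`` residual
    standard deviations in both traits (mostly null SNPs), the z-score pair is
    approximately the truncated residual Gaussian, whose correlation is an
    attenuated, monotone function of rho0; the weighted empirical correlation
    is inverted through that map (computed by Gauss-Legendre quadrature).
    """
    z1 = np.asarray(z1, dtype=float) / np.sqrt(sigma01_2)
    z2 = np.asarray(z2, dtype=float) / np.sqrt(sigma02_2)
    mask = (np.abs(z1) < z0) & (np.abs(z2) < z0) & (w > 0)
    if mask.sum() < 10:
        return 0.0
    ww = w[mask]
    a, b = z1[mask], z2[mask]
    am = (ww * a).sum() / ww.sum()
    bm = (ww * b).sum() / ww.sum()
    va = (ww * (a - am) ** 2).sum() / ww.sum()
    vb = (ww * (b - bm) ** 2).sum() / ww.sum()
    r_emp = float((ww * (a - am) * (b - bm)).sum() / ww.sum() / np.sqrt(va * vb))

    # attenuation map rho -> corr of BVN truncated to the square [-z0, z0]^2
    nodes, wts = np.polynomial.legendre.leggauss(48)
    x = z0 * nodes
    wq = z0 * wts
    xx, yy = np.meshgrid(x, x, indexing="ij")
    wgrid = np.outer(wq, wq)

    def trunc_corr(rho: float) -> float:
        det = 1.0 - rho**2
        pdf = np.exp(-(xx**2 - 2 * rho * xx * yy + yy**2) / (2 * det)) / (
            2 * np.pi * np.sqrt(det)
        )
        mass = (wgrid * pdf).sum()
        exy = (wgrid * xx * yy * pdf).sum() / mass
        ex2 = (wgrid * xx**2 * pdf).sum() / mass
        return exy / ex2  # symmetric truncation: var equal in both coords

    grid = np.linspace(-0.995, 0.995, 41)
    mapped = np.array([trunc_corr(r) for r in grid])
    return float(np.clip(np.interp(r_emp, mapped, grid), -0.999, 0.999))


def fit_bivariate(
    fit1: FitResult,
    fit2: FitResult,
    z_pair,
    ctx: SnpContext,
    weights,
    options: FitOptions | None = None,
) -> FitResult:
    """Two-stage bivariate fit given converged univariate fits of both traits."""
    options = options or FitOptions()
    u1: UnivariateParams = fit1.params
    u2: UnivariateParams = fit2.params
    w = weights.w if hasattr(weights, "w") else np.asarray(weights, dtype=float)
    n_eff = float(w.sum())
    z_pair = (np.asarray(z_pair[0], dtype=float), np.asarray(z_pair[1], dtype=float))
    active = w > 0
    if not active.all():
        idx = np.nonzero(active)[0]
        z_pair = (z_pair[0][idx], z_pair[1][idx])
        ctx, w = ctx.subset(idx), w[idx]
    weights = w
    trace: list = []
    converged = True

    # stage A: infinitesimal (pi12 = 1) fast-model fit of r_g, with the
    # residual correlation rho0 pinned from the null-dominated low-|z| SNPs
    # (the joint (r_g, rho0) likelihood is a near-flat ridge when the genetic
    # signal dominates the residual)
    s2_inf1 = infinitesimal_sigma2(fit1)
    s2_inf2 = infinitesimal_sigma2(fit2)
    z1, z2 = z_pair
    rho0_hat = estimate_rho0_lowz(z1, z2, w, u1.sigma0_2, u2.sigma0_2)

    def nllA(x):
        rg = float(np.clip(np.tanh(x[0]), -0.999999, 0.999999))
        p = BivariateParams(
            pi1=0.0, pi2=0.0, pi12=1.0,
            sigma1_2=s2_inf1, sigma2_2=s2_inf2, rho12=float(rg),
            sigma01_2=u1.sigma0_2, sigma02_2=u2.sigma0_2, rho0=rho0_hat,
        )
        return -_loglik(p, z_pair, ctx, weights, options, "fast")

    # moment-based start from the weighted z1*z2 cross-moment
    r_emp = float((w * z1 * z2).sum() / np.sqrt((w * z1**2).sum() * (w * z2**2).sum()))
    x0 = np.arctanh(np.clip(r_emp, -0.95, 0.95))
    rA = None
    for start in ([x0], [0.0]):
        cand_res = _minimize(nllA, start, options)
        if rA is None or cand_res.fun < rA.fun:
            rA = cand_res
    rg_inf = float(np.tanh(rA.x[0]))
    trace.append({"stage": "A", "loglik": -rA.fun, "rg": rg_inf,
                  "rho0": rho0_hat, "converged": bool(rA.success)})
    converged &= bool(rA.success)

    pi1u, pi2u = u1.pi1, u2.pi1
    frozen = dict(
        pi1u=pi1u, pi2u=pi2u, rg=rg_inf,
        s1_2=u1.sigma_beta2, s2_2=u2.sigma_beta2,
        s01_2=u1.sigma0_2, s02_2=u2.sigma0_2, rho0=rho0_hat,
    )

    # stage B: pi12 with rho12 derived from the stage-A r_g
    clip_seen = {"clipped": False}

    def nllB(x):
        f = 1.0 / (1.0 + np.exp(-float(x[0])))  # logit^-1
        p, clipped = _stageB_params(f, **frozen)
        clip_seen["clipped"] |= clipped
        return -_loglik(p, z_pair, ctx, weights, options, options.model)

    grid = np.array([0.02, 0.15, 0.3, 0.5, 0.7, 0.85, 0.98])
    gvals = [nllB([np.log(f / (1 - f))]) for f in grid]
    f0 = grid[int(np.argmin(gvals))]
    rB = _minimize(nllB, [np.log(f0 / (1 - f0))], options)
    fB = 1.0 / (1.0 + np.exp(-float(rB.x[0])))
    pB, _ = _stageB_params(fB, **frozen)
    loglik = -float(rB.fun)
    trace.append({"stage": "B", "loglik": loglik, "params": pB.to_dict(),
                  "rho12_clipped": clip_seen["clipped"],
                  "converged": bool(rB.success)})
    converged &= bool(rB.success)
    best = pB

    # optional polish: release (pi12, rho12) jointly
    if options.polish_rho:
        def nllC(x):
            f = 1.0 / (1.0 + np.exp(-float(x[0])))
            rho12 = float(np.clip(np.tanh(x[1]), -0.999999, 0.999999))
            p, _ = _stageB_params(f, rho12_free=rho12, **frozen)
            return -_loglik(p, z_pair, ctx, weights, options, options.model)

        xC0 = [float(rB.x[0]), float(np.arctanh(np.clip(pB.rho12, -0.999, 0.999)))]
        rC = _minimize(nllC, xC0, options)
        if -rC.fun >= loglik:
            fC = 1.0 / (1.0 + np.exp(-float(rC.x[0])))
            best, _ = _stageB_params(fC, rho12_free=float(np.tanh(rC.x[1])), **frozen)
            loglik = -float(rC.fun)
        trace.append({"stage": "C", "loglik": -float(rC.fun),
                      "params": best.to_dict(), "converged": bool(rC.success)})
        converged &= bool(rC.success)

    # 3 bivariate-specific free parameters on top of the frozen univariate ones
    aic, bic = information_criteria(loglik, 3, n_eff)
    return FitResult(params=best, loglik=loglik, n_effective=n_eff, aic=aic,
                     bic=bic, trace=trace, converged=converged)
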
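"""Standard errors from observed Fisher information and sampling propagation.

The curvature of the log-likelihood is measured in a transformed parameter
space where every coordinate ranges over the whole real line, so that the
quadratic approximation (and the normal sampling used for propagation) can
never leave the valid domain:

* mixture weights pi:  logit,  pi = 1 / (1 + exp(-u))
* variances sigma^2:   log,    sigma^2 = exp(u)
* correlations rho:    erf,    rho = erf(u)

The observed information is the numerical Hessian of the negative
log-likelihood at the optimum (central differences with one Richardson
extrapolation step); its inverse is the error covariance.  When the Hessian is
not positive definite, per-parameter marginal curvatures are used instead and
the covariance is flagged as marginal-only.  Errors of derived quantities
(heritability, genetic correlation, Venn counts) are propagated by sampling
parameter vectors from the transformed-space normal and applying the function
to each draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special

_UNI_FIELDS = ("pi1", "sigma_beta2", "sigma0_2")
_BIV_FIELDS = (
    "pi1", "pi2", "pi12", "sigma1_2", "sigma2_2", "rho12",
    "sigma01_2", "sigma02_2", "rho0",
)


def _transform_for(name: str):
    """(forward, inverse) maps onto the real line for a parameter field."""
    if name.startswith("pi"):
        return (
            lambda p: float(special.logit(np.clip(p, 1e-15, 1 - 1e-15))),
            lambda u: float(special.expit(u)),
        )
    if name.startswith("sigma"):
        return (lambda p: float(np.log(max(p, 1e-300))), lambda u: float(np.exp(u)))
    if name.startswith("rho"):
        return (
            lambda p: float(special.erfinv(np.clip(p, -1 + 1e-12, 1 - 1e-12))),
            lambda u: float(special.erf(u)),
        )
    raise KeyError(f"no transform registered for parameter {name!r}")


@dataclass
class ParamCovariance:
    """Covariance of parameter errors in transformed space."""

    names: tuple
    point: np.ndarray  # transformed coordinates of the optimum
    cov: np.ndarray
    params: object  # the params object at the optimum
    fallback: bool = False  # marginal-only (non-PD joint Hessian)

    @property
    def se_transformed(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def se_natural(self) -> dict:
        """Delta-method SEs on the natural scale, per parameter."""
        out = {}
        for k, name in enumerate(self.names):
            _, inv = _transform_for(name)
            u = self.point[k]
            h = 1e-5
            deriv = (inv(u + h) - inv(u - h)) / (2 * h)
            out[name] = abs(deriv) * float(np.sqrt(self.cov[k, k]))
        return out

    def realize(self, u_vec: np.ndarray):
        """Back-transform a transformed draw into a params object."""
        updates = {}
        for k, name in enumerate(self.names):
            _, inv = _transform_for(name)
            updates[name] = inv(float(u_vec[k]))
        return replace(self.params, **updates)


def default_fields(params) -> tuple:
    from .params import BivariateParams, UnivariateParams

    if isinstance(params, UnivariateParams):
        return _UNI_FIELDS
    if isinstance(params, BivariateParams):
        return _BIV_FIELDS
    raise TypeError(type(params))


def fisher_information(
    params,
    loglik_fn,
    names: tuple | None = None,
    step: float = 1e-3,
) -> ParamCovariance:
    """Observed-information error covariance at a local optimum.

    ``loglik_fn`` maps a params object to the log-likelihood.  ``names``
    selects the free parameters (defaults to all fields of the params class).
    """
    names = tuple(names or default_fields(params))
    fwd_inv = [_transform_for(n) for n in names]
    u0 = np.array([f(getattr(params, n)) for n, (f, _) in zip(names, fwd_inv)])
    d = len(names)

    def nll(u):
        updates = {n: inv(float(u[k])) for k, (n, (_, inv)) in enumerate(zip(names, fwd_inv))}
        try:
            p = replace(params, **updates)
        except ValueError:
            return np.inf
        val = loglik_fn(p)
        return np.inf if not np.isfinite(val) else -val

    def hessian(h):
        H = np.empty((d, d))
        f0 = nll(u0)
        for a in range(d):
            ea = np.zeros(d); ea[a] = h
            H[a, a] = (nll(u0 + ea) - 2 * f0 + nll(u0 - ea)) / h**2
            for b in range(a + 1, d):
                eb = np.zeros(d); eb[b] = h
                H[a, b] = H[b, a] = (
                    nll(u0 + ea + eb) - nll(u0 + ea - eb)
                    - nll(u0 - ea + eb) + nll(u0 - ea - eb)
                ) / (4 * h**2)
        return H

    H = hessian(step)
    H2 = hessian(step / 2.0)
    if np.all(np.isfinite(H)) and np.all(np.isfinite(H2)):
        H = (4.0 * H2 - H) / 3.0  # Richardson extrapolation
    elif np.all(np.isfinite(H2)):
        H = H2
    elif not np.all(np.isfinite(H)):
        H = hessian(step / 4.0)  # reduced-step retry

    fallback = False
    cov = None
    if np.all(np.isfinite(H)):
        try:
            eigvals = np.linalg.eigvalsh(H)
            if np.all(eigvals > 0):
                cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            pass
    if cov is None:
        fallback = True
        diag = np.array([max(H[k, k], 0.0) if np.isfinite(H[k, k]) else 0.0
                         for k in range(d)])
        var = np.where(diag > 0, 1.0 / np.where(diag > 0, diag, 1.0), np.inf)
        cov = np.diag(var)
    return ParamCovariance(names=names, point=u0, cov=cov, params=params,
                           fallback=fallback)


def propagate(
    cov: ParamCovariance,
    fn,
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Sampling-based error propagation for a function of the parameters.

    Draws parameter vectors from N(point, cov) in transformed space,
    back-transforms, applies ``fn`` (params -> float), and reports the point
    estimate fn(params) with the sample standard deviation of the draws.
    Draws on which ``fn`` fails are discarded; more than 10% failures is an
    error.
    """
    rng = np.random.default_rng(seed)
    finite = np.isfinite(np.diag(cov.cov))
    safe_cov = cov.cov.copy()
    safe_cov[~finite, :] = 0.0
    safe_cov[:, ~finite] = 0.0
    if not safe_cov.any():  # degenerate: no error to propagate
        return float(fn(cov.params)), 0.0
    draws = rng.multivariate_normal(cov.point, safe_cov, size=n_draws,
                                    method="svd")
    vals = []
    failures = 0
    for u in draws:
        try:
            p = cov.realize(u)
            v = float(fn(p))
            if not np.isfinite(v):
                raise ValueError
            vals.append(v)
        except (ValueError, ZeroDivisionError, FloatingPointError):
            failures += 1
    if failures > 0.1 * n_draws:
        raise RuntimeError(f"{failures}/{n_draws} propagation draws failed")
    point = float(fn(cov.params))
    se = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return point, se


def block_jackknife_se(
    estimator,
    n_items: int,
    n_blocks: int = 50,
) -> np.ndarray:
    """Delete-one-block jackknife SEs for an estimator over indexed items.

    ``estimator(keep_mask)`` must return a parameter vector computed from the
    items where the boolean mask is True.  Blocks are contiguous index ranges,
    the standard choice for SNPs ordered along the genome.
    """
    edges = np.linspace(0, n_items, n_blocks + 1).astype(int)
    thetas = []
    for b in range(n_blocks):
        mask = np.ones(n_items, dtype=bool)
        mask[edges[b]:edges[b + 1]] = False
        thetas.append(np.asarray(estimator(mask), dtype=float))
    thetas = np.stack(thetas)
    mean = thetas.mean(axis=0)
    return np.sqrt((n_blocks - 1) / n_blocks * ((thetas - mean) ** 2).sum(axis=0))
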
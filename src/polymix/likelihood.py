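"""Mixture likelihood of GWAS z-scores under the causal mixture model.

Two likelihood variants are provided:

* the **fast model**: a method-of-moments approximation in which the z-score
  of SNP j follows a finite Gaussian mixture whose weights and variances are
  adjusted by the SNP's heterozygosity-weighted LD score ``ell_j`` and the
  shape term ``m4_j / ell_j`` (the r^4 sum controls the kurtosis of the
  mixture).  For each non-null component c with weight pi_c the adjustment is

      eta_cj = pi_c * ell_j + (1 - pi_c) * m4_j / ell_j
      pi'_cj = ell_j * pi_c / eta_cj        (adjusted weight, always in [pi_c, 1])
      var'_cj = n_j * eta_cj * sigma_c^2    (adjusted, sample-size-scaled variance)

  In the bivariate case the three adjusted two-point mixtures (trait-1-only,
  trait-2-only, shared) are convolved into an eight-component bivariate
  Gaussian mixture, and the residual covariance
  [[s01^2, rho0*s01*s02], [., s02^2]] is added to every component.

* the **full model**: for each of K replicates, a causal configuration over
  the SNP's stored LD neighbours is drawn from the component weights, the
  implied z-score covariance sum_i H_i r_ij^2 Sigma_c(i) is accumulated, and
  the density is the average of the K resulting Gaussians.  Slower but free of
  the moment-matching approximation.

Both plug into the weighted (optionally right-censored) log-likelihood used by
the fit procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import UnivariateParams, BivariateParams
from .reference import LdMatrix, LdScores, ReferencePanel, PruningWeights

_LOG_2PI = float(np.log(2.0 * np.pi))
_MIN_VAR = 1e-12  # clamp for component variances


class NumericalDomainError(ValueError):
    """A likelihood quantity left its valid numerical domain."""


@dataclass
class SnpContext:
    """Per-SNP LD/sample-size context, vectorized over a set of SNPs.

    ``ell`` and ``m4_ratio`` feed the fast model; the neighbour arrays (values
    ``H_i`` and ``r_ij`` in CSR layout, self term included) feed the full
    model.  ``n2`` is None for a univariate context.
    """

    ell: np.ndarray
    m4_ratio: np.ndarray
    n1: np.ndarray
    n2: np.ndarray | None = None
    nb_indptr: np.ndarray | None = None
    nb_h: np.ndarray | None = None
    nb_r: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ell = np.asarray(self.ell, dtype=float)
        self.m4_ratio = np.asarray(self.m4_ratio, dtype=float)
        self.n1 = np.broadcast_to(np.asarray(self.n1, dtype=float), self.ell.shape).copy()
        if self.n2 is not None:
            self.n2 = np.broadcast_to(np.asarray(self.n2, dtype=float), self.ell.shape).copy()
        if np.any(self.ell <= 0):
            raise ValueError("ell must be positive (self term included)")
        if np.any(self.m4_ratio <= 0):
            raise ValueError("m4_ratio must be positive")

    def __len__(self) -> int:
        return len(self.ell)

    @property
    def has_neighbors(self) -> bool:
        return self.nb_indptr is not None

    def subset(self, idx: np.ndarray) -> "SnpContext":
        """Context restricted to SNPs ``idx`` (neighbour values carried over)."""
        idx = np.asarray(idx)
        nb_indptr = nb_h = nb_r = None
        if self.has_neighbors:
            starts = self.nb_indptr[idx]
            lens = np.diff(self.nb_indptr)[idx]
            nb_indptr = np.concatenate([[0], np.cumsum(lens)])
            total = int(nb_indptr[-1])
            # gather [start_j, start_j + len_j) ranges without a Python loop
            take = np.repeat(starts - nb_indptr[:-1], lens) + np.arange(total)
            nb_h = self.nb_h[take]
            nb_r = self.nb_r[take]
        return SnpContext(
            ell=self.ell[idx],
            m4_ratio=self.m4_ratio[idx],
            n1=self.n1[idx],
            n2=None if self.n2 is None else self.n2[idx],
            nb_indptr=nb_indptr,
            nb_h=nb_h,
            nb_r=nb_r,
        )


def make_context(
    ld: LdMatrix,
    panel: ReferencePanel,
    scores: LdScores,
    n1,
    n2=None,
    include_neighbors: bool = True,
) -> SnpContext:
    """Build the per-SNP context over the whole panel."""
    m = len(panel)
    het = panel.het
    nb_indptr = nb_h = nb_r = None
    if include_neighbors:
        lens = np.diff(ld.r.indptr) + 1  # + self term
        nb_indptr = np.concatenate([[0], np.cumsum(lens)])
        total = int(nb_indptr[-1])
        nb_h = np.empty(total)
        nb_r = np.empty(total)
        for j in range(m):
            a, b = nb_indptr[j], nb_indptr[j + 1]
            idx = ld.r.indices[ld.r.indptr[j] : ld.r.indptr[j + 1]]
            nb_h[a] = het[j]
            nb_r[a] = 1.0
            nb_h[a + 1 : b] = het[idx]
            nb_r[a + 1 : b] = ld.r.data[ld.r.indptr[j] : ld.r.indptr[j + 1]]
    return SnpContext(
        ell=scores.ell,
        m4_ratio=scores.m4 / scores.ell,
        n1=n1,
        n2=n2,
        nb_indptr=nb_indptr,
        nb_h=nb_h,
        nb_r=nb_r,
    )


# ---------------------------------------------------------------------------
# fast model
# ---------------------------------------------------------------------------

def _eta(pi_c: float, ell: np.ndarray, m4_ratio: np.ndarray) -> np.ndarray:
    return pi_c * ell + (1.0 - pi_c) * m4_ratio


def _norm_logpdf(z, var):
    return -0.5 * (_LOG_2PI + np.log(var) + z * z / var)


def fast_pdf_uni(z, p: UnivariateParams, ctx: SnpContext, log: bool = False):
    """Fast-model density of a univariate z-score.

    The density is the two-component mixture
    ``(1 - pi') N(0, s0^2) + pi' N(0, n * eta * sigma_beta^2 + s0^2)``.
    ``z`` broadcasts against the context (e.g. a (G, 1) grid against M SNPs).
    """
    eta = _eta(p.pi1, ctx.ell, ctx.m4_ratio)
    if np.any(eta <= 0):
        raise NumericalDomainError("shape parameter eta must be positive")
    pi_adj = np.clip(ctx.ell * p.pi1 / eta, 0.0, 1.0)
    var_c = np.maximum(ctx.n1 * eta * p.sigma_beta2 + p.sigma0_2, _MIN_VAR)
    var_0 = p.sigma0_2
    z = np.asarray(z, dtype=float)
    la = _norm_logpdf(z, var_0) + np.log1p(-np.minimum(pi_adj, 1.0 - 1e-16))
    lb = _norm_logpdf(z, var_c) + np.log(np.maximum(pi_adj, 1e-300))
    hi = np.maximum(la, lb)
    out = hi + np.log(np.exp(la - hi) + np.exp(lb - hi))
    return out if log else np.exp(out)


def _biv_components(p: BivariateParams, ctx: SnpContext):
    """Adjusted weights and (co)variance contributions of the 3 causal arms.

    Returns (weights, v1, v2, c12): each a list of per-SNP arrays for the
    trait-1-only, trait-2-only and shared components, already scaled by the
    GWAS sample sizes.
    """
    if ctx.n2 is None:
        raise ValueError("bivariate density needs a context with n1 and n2")
    s1, s2 = np.sqrt(p.sigma1_2), np.sqrt(p.sigma2_2)
    root_n12 = np.sqrt(ctx.n1 * ctx.n2)
    out_w, out_v1, out_v2, out_c = [], [], [], []
    for pi_c, a1, a2, rho in (
        (p.pi1, p.sigma1_2, 0.0, 0.0),
        (p.pi2, 0.0, p.sigma2_2, 0.0),
        (p.pi12, p.sigma1_2, p.sigma2_2, p.rho12),
    ):
        eta = _eta(pi_c, ctx.ell, ctx.m4_ratio)
        w = np.clip(ctx.ell * pi_c / eta, 0.0, 1.0) if pi_c > 0 else np.zeros_like(ctx.ell)
        out_w.append(w)
        out_v1.append(ctx.n1 * eta * a1)
        out_v2.append(ctx.n2 * eta * a2)
        out_c.append(root_n12 * eta * rho * s1 * s2)
    return out_w, out_v1, out_v2, out_c


def _bvn_logpdf(z1, z2, v1, v2, c):
    det = v1 * v2 - c * c
    floor = 1e-12 * v1 * v2
    if np.any(det < -floor):
        raise NumericalDomainError("assembled bivariate covariance is not PSD")
    det = np.maximum(det, floor)  # |rho| -> 1 roundoff guard
    quad = (v2 * z1 * z1 - 2.0 * c * z1 * z2 + v1 * z2 * z2) / det
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad


def fast_pdf_biv(z1, z2, p: BivariateParams, ctx: SnpContext, log: bool = False):
    """Fast-model density of a bivariate z-score pair.

    The convolution of the three adjusted two-point mixtures yields an
    eight-component bivariate Gaussian mixture (every on/off combination of
    the three causal arms), each component offset by the residual covariance.
    """
    w, v1, v2, c12 = _biv_components(p, ctx)
    res_v1, res_v2 = p.sigma01_2, p.sigma02_2
    res_c = p.rho0 * np.sqrt(p.sigma01_2 * p.sigma02_2)
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    logs = []
    for b1 in (0, 1):
        for b2 in (0, 1):
            for b12 in (0, 1):
                bits = (b1, b2, b12)
                lw = 0.0
                for on, wc in zip(bits, w):
                    wc = np.clip(wc, 1e-300, 1.0 - 1e-16)
                    lw = lw + (np.log(wc) if on else np.log1p(-wc))
                vv1 = res_v1 + b1 * v1[0] + b12 * v1[2]
                vv2 = res_v2 + b2 * v2[1] + b12 * v2[2]
                cc = res_c + b12 * c12[2]
                logs.append(lw + _bvn_logpdf(z1, z2, np.maximum(vv1, _MIN_VAR),
                                             np.maximum(vv2, _MIN_VAR), cc))
    stacked = np.stack(np.broadcast_arrays(*logs))
    hi = stacked.max(axis=0)
    out = hi + np.log(np.exp(stacked - hi).sum(axis=0))
    return out if log else np.exp(out)


def fast_tail_uni(z_t: float, p: UnivariateParams, ctx: SnpContext) -> np.ndarray:
    """P(|Z| > z_t) per SNP under the fast univariate mixture (analytic)."""
    eta = _eta(p.pi1, ctx.ell, ctx.m4_ratio)
    pi_adj = np.clip(ctx.ell * p.pi1 / eta, 0.0, 1.0)
    var_c = ctx.n1 * eta * p.sigma_beta2 + p.sigma0_2
    tail = (1.0 - pi_adj) * 2.0 * stats.norm.sf(z_t / np.sqrt(p.sigma0_2))
    tail = tail + pi_adj * 2.0 * stats.norm.sf(z_t / np.sqrt(var_c))
    return tail


def fast_tail_biv(z_t: float, p: BivariateParams, ctx: SnpContext) -> np.ndarray:
    """P(max(|Z1|,|Z2|) > z_t) per SNP under the fast bivariate mixture."""
    w, v1, v2, c12 = _biv_components(p, ctx)
    res_c = p.rho0 * np.sqrt(p.sigma01_2 * p.sigma02_2)
    m = len(ctx)
    inside = np.zeros(m)
    for b1 in (0, 1):
        for b2 in (0, 1):
            for b12 in (0, 1):
                wt = np.ones(m)
                for on, wc in zip((b1, b2, b12), w):
                    wt = wt * (wc if on else (1.0 - wc))
                vv1 = p.sigma01_2 + b1 * v1[0] + b12 * v1[2]
                vv2 = p.sigma02_2 + b2 * v2[1] + b12 * v2[2]
                cc = res_c + b12 * c12[2]
                rect = _bvn_rectangle(z_t, vv1, vv2, cc)
                inside += wt * rect
    return np.clip(1.0 - inside, 0.0, 1.0)


def _bvn_rectangle(z_t: float, v1: np.ndarray, v2: np.ndarray, c: np.ndarray) -> np.ndarray:
    """P(|Z1|<=z_t, |Z2|<=z_t) for zero-mean bivariate normals, vectorized."""
    from scipy.stats import multivariate_normal

    v1 = np.broadcast_to(v1, np.broadcast_shapes(np.shape(v1), np.shape(c))).ravel()
    v2 = np.broadcast_to(v2, v1.shape).ravel()
    c = np.broadcast_to(c, v1.shape).ravel()
    out = np.empty(v1.shape)
    for k in range(v1.size):
        cov = [[v1[k], c[k]], [c[k], v2[k]]]
        mvn = multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)
        f = mvn.cdf
        out[k] = (
            f([z_t, z_t]) - f([-z_t, z_t]) - f([z_t, -z_t]) + f([-z_t, -z_t])
        )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def _segment_sums(vals: np.ndarray, indptr: np.ndarray) -> np.ndarray:
    return np.add.reduceat(vals, indptr[:-1])


def full_pdf_uni(
    z,
    p: UnivariateParams,
    ctx: SnpContext,
    K: int = 1000,
    seed: int = 0,
    uniforms: np.ndarray | None = None,
):
    """Full-model univariate density: average over K sampled causal configs.

    Per replicate, every stored LD neighbour of SNP j (including j itself) is
    causal with probability pi1; the replicate's z variance is
    ``n * sigma_beta^2 * sum_causal H_i r_ij^2 + sigma0_2``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not ctx.has_neighbors:
        raise ValueError("context has no neighbour arrays; build with include_neighbors")
    hr2 = ctx.nb_h * ctx.nb_r**2
    rng = np.random.default_rng(seed)
    z = np.asarray(z, dtype=float)
    acc = 0.0
    for k in range(K):
        u = uniforms[k] if uniforms is not None else rng.random(hr2.shape[0])
        s = _segment_sums(hr2 * (u < p.pi1), ctx.nb_indptr)
        var = np.maximum(ctx.n1 * p.sigma_beta2 * s + p.sigma0_2, _MIN_VAR)
        acc = acc + np.exp(_norm_logpdf(z, var))
    return acc / K


def full_pdf(
    z1,
    z2,
    p: BivariateParams,
    ctx: SnpContext,
    K: int = 1000,
    seed: int = 0,
    uniforms: np.ndarray | None = None,
):
    """Full-model bivariate density: average over K sampled causal configs.

    Per replicate, each neighbour draws a component label from
    (pi0, pi1, pi2, pi12); the z covariance accumulates H_i r_ij^2 times that
    component's effect covariance, scaled by diag(sqrt(n1), sqrt(n2)), plus
    the residual covariance.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not ctx.has_neighbors:
        raise ValueError("context has no neighbour arrays; build with include_neighbors")
    if ctx.n2 is None:
        raise ValueError("bivariate density needs a context with n1 and n2")
    hr2 = ctx.nb_h * ctx.nb_r**2
    t1, t2 = p.pi1, p.pi1 + p.pi2
    t12 = t2 + p.pi12
    s1s2 = np.sqrt(p.sigma1_2 * p.sigma2_2)
    res_c = p.rho0 * np.sqrt(p.sigma01_2 * p.sigma02_2)
    root_n12 = np.sqrt(ctx.n1 * ctx.n2)
    rng = np.random.default_rng(seed)
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    acc = 0.0
    for k in range(K):
        u = uniforms[k] if uniforms is not None else rng.random(hr2.shape[0])
        c1 = u < t1
        c2 = (u >= t1) & (u < t2)
        c12 = (u >= t2) & (u < t12)
        s_1 = _segment_sums(hr2 * (c1 | c12), ctx.nb_indptr)
        s_2 = _segment_sums(hr2 * (c2 | c12), ctx.nb_indptr)
        s_12 = _segment_sums(hr2 * c12, ctx.nb_indptr)
        v1 = np.maximum(ctx.n1 * p.sigma1_2 * s_1 + p.sigma01_2, _MIN_VAR)
        v2 = np.maximum(ctx.n2 * p.sigma2_2 * s_2 + p.sigma02_2, _MIN_VAR)
        c = root_n12 * p.rho12 * s1s2 * s_12 + res_c
        acc = acc + np.exp(_bvn_logpdf(z1, z2, v1, v2, c))
    return acc / K


# ---------------------------------------------------------------------------
# sparse-convolution model: deterministic evaluation of the full-model density
# ---------------------------------------------------------------------------

def conv_pdf_uni(z, p: UnivariateParams, ctx: SnpContext):
    """Exact sparse-regime evaluation of the full-model univariate density.

    The full model's causal-configuration average is, marginally per SNP, a
    mixture over subsets S of LD neighbours:
    ``sum_S P(S) N(z; 0, n sigma_beta^2 sum_{i in S} H_i r_ij^2 + sigma0^2)``.
    When the expected number of causal neighbours ``m_j * pi`` is small the
    mixture is dominated by the empty and single-variant subsets; this
    evaluator enumerates those exactly and represents all multi-variant
    subsets by one Gaussian with the correct mass and mean variance
    (error O((m_j pi)^3) in probability mass).  Unlike the Monte-Carlo
    ``full_pdf`` it is deterministic and cheap enough for optimization.
    """
    if not ctx.has_neighbors:
        raise ValueError("context has no neighbour arrays; build with include_neighbors")
    z = np.asarray(z, dtype=float)
    pi = p.pi1
    lens = np.diff(ctx.nb_indptr).astype(float)
    a = ctx.nb_h * ctx.nb_r**2  # per-neighbour variance contribution
    ell = _segment_sums(a, ctx.nb_indptr)
    log1m = np.log1p(-min(pi, 1 - 1e-12))
    q0 = np.exp(lens * log1m)  # P(no causal neighbour)
    w_single = pi * np.exp((lens - 1.0) * log1m)  # per-neighbour single-hit mass
    p_multi = np.clip(1.0 - q0 - lens * w_single, 0.0, 1.0)

    # empty subset
    dens = q0 * np.exp(_norm_logpdf(z, p.sigma0_2))
    # single-variant subsets, enumerated per neighbour
    var_i = np.maximum(ctx.n1.repeat(lens.astype(int)) * p.sigma_beta2 * a
                       + p.sigma0_2, _MIN_VAR)
    z_rep = np.repeat(z, lens.astype(int))
    dens = dens + w_single * _segment_sums(np.exp(_norm_logpdf(z_rep, var_i)),
                                           ctx.nb_indptr)
    # multi-variant remainder: mass-weighted Gaussian at the conditional mean
    t_rest = np.where(p_multi > 0,
                      (pi * ell - w_single * ell) / np.maximum(p_multi, 1e-300),
                      0.0)
    var_m = np.maximum(ctx.n1 * p.sigma_beta2 * t_rest + p.sigma0_2, _MIN_VAR)
    dens = dens + p_multi * np.exp(_norm_logpdf(z, var_m))
    return dens


def conv_pdf_biv(z1, z2, p: BivariateParams, ctx: SnpContext):
    """Sparse-regime deterministic evaluation of the full-model bivariate density.

    Component labels per neighbour follow (pi0, pi1, pi2, pi12); empty and
    single-neighbour configurations are enumerated exactly (three labelled
    terms per neighbour), multi-neighbour configurations are pooled into one
    Gaussian with the exact mass and mean covariance.
    """
    if not ctx.has_neighbors:
        raise ValueError("context has no neighbour arrays; build with include_neighbors")
    if ctx.n2 is None:
        raise ValueError("bivariate density needs a context with n1 and n2")
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    pit = p.pi1 + p.pi2 + p.pi12
    lens = np.diff(ctx.nb_indptr).astype(float)
    reps = lens.astype(int)
    a = ctx.nb_h * ctx.nb_r**2
    ell = _segment_sums(a, ctx.nb_indptr)
    log1m = np.log1p(-min(pit, 1 - 1e-12))
    q0 = np.exp(lens * log1m)
    w1 = np.exp((lens - 1.0) * log1m)  # P(all others null) per SNP
    p_multi = np.clip(1.0 - q0 - lens * pit * w1, 0.0, 1.0)

    res_c = p.rho0 * np.sqrt(p.sigma01_2 * p.sigma02_2)
    s1s2 = np.sqrt(p.sigma1_2 * p.sigma2_2)
    root_n12 = np.sqrt(ctx.n1 * ctx.n2)

    dens = q0 * np.exp(_bvn_logpdf(z1, z2, p.sigma01_2, p.sigma02_2, res_c))

    z1_rep, z2_rep = np.repeat(z1, reps), np.repeat(z2, reps)
    n1_rep, n2_rep = np.repeat(ctx.n1, reps), np.repeat(ctx.n2, reps)
    rn_rep = np.repeat(root_n12, reps)
    for pi_c, s1_2, s2_2, rho in (
        (p.pi1, p.sigma1_2, 0.0, 0.0),
        (p.pi2, 0.0, p.sigma2_2, 0.0),
        (p.pi12, p.sigma1_2, p.sigma2_2, p.rho12),
    ):
        if pi_c <= 0:
            continue
        v1 = np.maximum(n1_rep * s1_2 * a + p.sigma01_2, _MIN_VAR)
        v2 = np.maximum(n2_rep * s2_2 * a + p.sigma02_2, _MIN_VAR)
        cc = rn_rep * rho * np.sqrt(s1_2 * s2_2) * a + res_c
        term = _segment_sums(np.exp(_bvn_logpdf(z1_rep, z2_rep, v1, v2, cc)),
                             ctx.nb_indptr)
        dens = dens + pi_c * w1 * term

    # multi-hit remainder with the exact conditional mean covariance
    scale = np.where(p_multi > 0,
                     (pit - pit * w1) * ell / np.maximum(p_multi, 1e-300), 0.0)
    frac1 = p.pi1 / pit if pit > 0 else 0.0
    frac2 = p.pi2 / pit if pit > 0 else 0.0
    frac12 = p.pi12 / pit if pit > 0 else 0.0
    v1 = np.maximum(ctx.n1 * (frac1 + frac12) * p.sigma1_2 * scale + p.sigma01_2,
                    _MIN_VAR)
    v2 = np.maximum(ctx.n2 * (frac2 + frac12) * p.sigma2_2 * scale + p.sigma02_2,
                    _MIN_VAR)
    cc = root_n12 * frac12 * p.rho12 * s1s2 * scale + res_c
    dens = dens + p_multi * np.exp(_bvn_logpdf(z1, z2, v1, v2, cc))
    return dens


def conv_tail_uni(z_t: float, p: UnivariateParams, ctx: SnpContext) -> np.ndarray:
    """P(|Z| > z_t) per SNP under the sparse-convolution mixture (analytic)."""
    if not ctx.has_neighbors:
        raise ValueError("context has no neighbour arrays; build with include_neighbors")
    pi = p.pi1
    lens = np.diff(ctx.nb_indptr).astype(float)
    a = ctx.nb_h * ctx.nb_r**2
    ell = _segment_sums(a, ctx.nb_indptr)
    log1m = np.log1p(-min(pi, 1 - 1e-12))
    q0 = np.exp(lens * log1m)
    w_single = pi * np.exp((lens - 1.0) * log1m)
    p_multi = np.clip(1.0 - q0 - lens * w_single, 0.0, 1.0)
    tail = q0 * 2.0 * stats.norm.sf(z_t / np.sqrt(p.sigma0_2))
    sd_i = np.sqrt(ctx.n1.repeat(lens.astype(int)) * p.sigma_beta2 * a + p.sigma0_2)
    tail = tail + w_single * _segment_sums(2.0 * stats.norm.sf(z_t / sd_i),
                                           ctx.nb_indptr)
    t_rest = np.where(p_multi > 0,
                      (pi * ell - w_single * ell) / np.maximum(p_multi, 1e-300), 0.0)
    sd_m = np.sqrt(ctx.n1 * p.sigma_beta2 * t_rest + p.sigma0_2)
    return tail + p_multi * 2.0 * stats.norm.sf(z_t / sd_m)


# ---------------------------------------------------------------------------
# weighted / censored log-likelihood
# ---------------------------------------------------------------------------

def _as_weights(weights, m: int) -> np.ndarray:
    if isinstance(weights, PruningWeights):
        w = weights.w
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape[0] != m:
        raise ValueError("weights not aligned with the SNP contexts")
    return w


def _pdf(params, z, ctx, model, K, seed):
    if isinstance(params, BivariateParams):
        z1, z2 = z
        if model == "fast":
            return fast_pdf_biv(z1, z2, params, ctx)
        if model == "conv":
            return conv_pdf_biv(z1, z2, params, ctx)
        return full_pdf(z1, z2, params, ctx, K=K, seed=seed)
    if model == "fast":
        return fast_pdf_uni(z, params, ctx)
    if model == "conv":
        return conv_pdf_uni(z, params, ctx)
    return full_pdf_uni(z, params, ctx, K=K, seed=seed)


_LOG_TINY = float(np.log(5e-324))


def _log_pdf(params, z, ctx, model, K, seed):
    """Per-SNP log density; fast models in log space, others clamped.

    Densities that underflow to exactly 0 in double precision are clamped to
    the smallest subnormal so extreme z-scores keep a finite, monotone
    contribution instead of flattening the objective to -inf.
    """
    if model == "fast":
        if isinstance(params, BivariateParams):
            return fast_pdf_biv(z[0], z[1], params, ctx, log=True)
        return fast_pdf_uni(z, params, ctx, log=True)
    dens = _pdf(params, z, ctx, model, K, seed)
    dens = np.asarray(dens, dtype=float)
    if np.any(dens < 0) or np.any(np.isnan(dens)):
        return None
    return np.where(dens > 0, np.log(np.maximum(dens, 5e-324)), _LOG_TINY)


def weighted_loglik(
    params,
    z,
    ctx: SnpContext,
    weights,
    model: str = "fast",
    K: int = 1000,
    seed: int = 0,
) -> float:
    """Pruning-weighted log-likelihood  F = sum_j w_j log pdf(z_j | params).

    ``z`` is a 1-D array for univariate params, or a (z1, z2) pair of arrays
    for bivariate params.  SNPs with zero weight are skipped entirely.
    """
    w = _as_weights(weights, len(ctx))
    active = w > 0
    if not active.any():
        return 0.0
    sub = ctx.subset(np.nonzero(active)[0]) if not active.all() else ctx
    if isinstance(params, BivariateParams):
        zz = (np.asarray(z[0])[active], np.asarray(z[1])[active])
    else:
        zz = np.asarray(z)[active]
    logdens = _log_pdf(params, zz, sub, model, K, seed)
    if logdens is None or np.any(np.isnan(logdens)) or np.any(logdens == np.inf):
        return -np.inf
    return float(np.sum(w[active] * logdens))


def censored_loglik(
    params,
    z,
    ctx: SnpContext,
    weights,
    z_t: float = 5.45,
    model: str = "fast",
    K: int = 1000,
    seed: int = 0,
) -> float:
    """Right-censored weighted log-likelihood.

    SNPs whose |z| exceeds ``z_t`` contribute the log model tail mass
    P(|Z| > z_t) instead of the density, protecting the fit against
    misspecification in the extreme tail (e.g. a few very large effects).
    For bivariate params a SNP is censored when either trait exceeds ``z_t``.
    """
    if z_t <= 0:
        raise ValueError("z_t must be positive")
    w = _as_weights(weights, len(ctx))
    if isinstance(params, BivariateParams):
        exceed = (np.abs(z[0]) > z_t) | (np.abs(z[1]) > z_t)
    else:
        exceed = np.abs(np.asarray(z)) > z_t
    keep = ~exceed & (w > 0)
    cens = exceed & (w > 0)

    total = 0.0
    if keep.any():
        idx = np.nonzero(keep)[0]
        sub = ctx.subset(idx)
        zz = (
            (np.asarray(z[0])[idx], np.asarray(z[1])[idx])
            if isinstance(params, BivariateParams)
            else np.asarray(z)[idx]
        )
        logdens = _log_pdf(params, zz, sub, model, K, seed)
        if logdens is None or np.any(np.isnan(logdens)) or np.any(logdens == np.inf):
            return -np.inf
        total += float(np.sum(w[idx] * logdens))
    if cens.any():
        idx = np.nonzero(cens)[0]
        sub = ctx.subset(idx)
        if isinstance(params, BivariateParams):
            tail = fast_tail_biv(z_t, params, sub)
        else:
            tail = fast_tail_uni(z_t, params, sub)
        if np.any(tail <= 0):
            return -np.inf
        total += float(np.sum(w[idx] * np.log(tail)))
    return total
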
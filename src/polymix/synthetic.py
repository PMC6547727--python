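"""Synthetic GWAS generation: LD panels, causal architectures, z-scores.

Everything the estimator consumes can be generated offline at desk scale:

* ``make_panel`` builds a block-diagonal LD reference with a geometric
  within-block correlation profile (r = phi^|i-j|) and a configurable MAF
  spectrum -- a deliberately simple stand-in for population LD that still
  exposes the features the model uses (LD score spread, heterozygosity
  weighting, block structure);
* ``draw_effects`` draws per-SNP causal effects from the four-component
  mixture, optionally with MAF-dependent effect variance H^S (S = 0 is the
  model's own assumption, S = -1 the LD-score-regression convention) and
  per-SNP causal-probability enrichment multipliers;
* ``simulate_z`` pushes effects through the z-score convolution
  delta_j = sqrt(N) sum_i sqrt(H_i) r_ij beta_i and adds a correlated
  residual -- the exact generative counterpart of the likelihood;
* ``simulate_genotype_gwas`` runs a small-scale per-SNP regression GWAS on
  synthesized genotypes as an independent route to z-scores.

All randomness flows through named substreams of one seed so that panel,
labels, effects and residuals can be varied independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from .reference import LdMatrix, ReferencePanel
from .sumstats import SumStats

# named substreams
_PANEL, _LABELS, _EFFECTS, _RESIDUALS, _GENO, _PHENO = range(6)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class ArchitectureSpec:
    """Bivariate causal architecture for a synthetic study.

    When ``h2`` targets are given, effect variances are back-solved so each
    trait's realized heritability sum_j beta_j^2 H_j matches the target
    exactly (effects are rescaled by a common factor per trait).
    ``s`` is the MAF-dependence exponent of the effect variance H^s.
    """

    m: int
    pi1: float = 0.0
    pi2: float = 0.0
    pi12: float = 0.0
    sigma1_2: float = 1e-4
    sigma2_2: float = 1e-4
    rho12: float = 0.0
    h2: tuple | None = None  # (h2 trait 1, h2 trait 2); overrides sigma_c^2
    s: float = 0.0
    enrichment: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.s <= 0.0):
            raise ValueError("MAF-dependence exponent s must be in [-1, 0]")
        total = self.pi1 + self.pi2 + self.pi12
        if total > 1.0:
            raise ValueError("component weights exceed 1")

    @property
    def pi1u(self) -> float:
        return self.pi1 + self.pi12

    @property
    def pi2u(self) -> float:
        return self.pi2 + self.pi12


def _draw_maf(rng: np.random.Generator, m: int, spectrum: str, maf_min: float) -> np.ndarray:
    if spectrum == "uniform":
        return rng.uniform(maf_min, 0.5, size=m)
    if spectrum == "beta":
        # folded Beta(0.5, 0.5)-like spectrum, truncated at maf_min
        p = rng.beta(0.5, 0.5, size=m)
        maf = np.minimum(p, 1.0 - p)
        return np.clip(maf, maf_min, 0.5)
    if spectrum == "one_over_p":
        # density proportional to 1/p on [maf_min, 0.5]; inverse-CDF sampling
        u = rng.random(m)
        return maf_min * (0.5 / maf_min) ** u
    raise ValueError(f"unknown maf spectrum {spectrum!r}")


def make_panel(
    n_blocks: int,
    block_size: int,
    phi: float = 0.9,
    maf_spectrum: str = "one_over_p",
    maf_min: float = 0.05,
    r2_min: float = 0.05,
    seed: int = 0,
) -> tuple[ReferencePanel, LdMatrix]:
    """Block-diagonal LD panel with geometric correlation decay.

    Within a block, r between SNPs at index distance d is phi^d; pairs with
    r^2 below ``r2_min`` are not stored (matching how a real LD reference is
    thresholded).  MAF is drawn from the named spectrum.
    """
    if block_size < 1 or n_blocks < 1:
        raise ValueError("block sizes must be >= 1")
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must be in [0, 1]")
    m = n_blocks * block_size
    rng = _rng(seed, _PANEL)
    maf = _draw_maf(rng, m, maf_spectrum, maf_min)
    alleles = rng.choice(["A", "C", "G", "T"], size=(m, 2))
    # avoid degenerate same-allele pairs
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    panel = ReferencePanel(
        snp_id=np.array([f"rs{k:07d}" for k in range(m)]),
        chrom=np.ones(m, dtype=int).astype(str),
        pos=(np.arange(m) + 1) * 1000,
        allele_eff=alleles[:, 0],
        allele_oth=alleles[:, 1],
        maf=maf,
    )
    # stored pair distance: phi^(2d) >= r2_min
    if phi in (0.0, 1.0):
        d_max = block_size - 1 if phi == 1.0 else 0
    else:
        d_max = min(int(np.floor(np.log(r2_min) / (2.0 * np.log(phi)))), block_size - 1)
    rows, cols, vals = [], [], []
    for d in range(1, d_max + 1):
        r = phi**d
        i = np.arange(m - d)
        keep = (i // block_size) == ((i + d) // block_size)  # same block
        rows.append(i[keep])
        cols.append(i[keep] + d)
        vals.append(np.full(int(keep.sum()), r))
    if rows:
        i = np.concatenate(rows)
        j = np.concatenate(cols)
        r = np.concatenate(vals)
    else:
        i = j = np.empty(0, dtype=int)
        r = np.empty(0)
    mat = sparse.csr_matrix(
        (np.concatenate([r, r]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(m, m),
    )
    ld = LdMatrix(r=mat, window_snps=block_size, r2_min=r2_min)
    return panel, ld


def draw_effects(
    spec: ArchitectureSpec, panel: ReferencePanel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-SNP effects (beta1, beta2) and component labels.

    Labels: 0 null, 1 trait-1-only, 2 trait-2-only, 3 shared.  Enrichment
    multipliers modulate the per-SNP causal probability and are renormalized
    to preserve the expected number of causal variants per component.
    """
    m = len(panel)
    if m != spec.m:
        raise ValueError("panel size does not match spec.m")
    het = panel.het
    rng_l = _rng(spec.seed, _LABELS)
    rng_e = _rng(spec.seed, _EFFECTS)

    mult = np.ones(m) if spec.enrichment is None else np.asarray(spec.enrichment, dtype=float)
    if mult.shape[0] != m or np.any(mult < 0):
        raise ValueError("enrichment multipliers must be nonnegative, one per SNP")
    mult = mult / mult.mean()  # preserve expected causal counts

    probs = np.stack([spec.pi1 * mult, spec.pi2 * mult, spec.pi12 * mult])
    total = probs.sum(axis=0)
    over = total > 1.0
    if over.any():
        warnings.warn(
            f"enrichment pushed causal probability > 1 at {int(over.sum())} SNP(s); "
            "renormalized",
            stacklevel=2,
        )
        probs[:, over] /= total[over]
    u = rng_l.random(m)
    c1 = np.cumsum(probs, axis=0)
    labels = np.zeros(m, dtype=int)
    labels[u < c1[0]] = 1
    labels[(u >= c1[0]) & (u < c1[1])] = 2
    labels[(u >= c1[1]) & (u < c1[2])] = 3

    scale = het**spec.s  # MAF-dependent effect-variance multiplier
    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    g = rng_e.standard_normal((m, 2))
    # shared component: correlated pair
    rho = spec.rho12
    shared = labels == 3
    z1 = g[:, 0]
    z2 = rho * g[:, 0] + np.sqrt(max(1.0 - rho**2, 0.0)) * g[:, 1]

    s1 = np.sqrt(spec.sigma1_2 * scale)
    s2 = np.sqrt(spec.sigma2_2 * scale)
    beta1[labels == 1] = (z1 * s1)[labels == 1]
    beta2[labels == 2] = (z2 * s2)[labels == 2]
    beta1[shared] = (z1 * s1)[shared]
    beta2[shared] = (z2 * s2)[shared]

    if spec.h2 is not None:
        for beta, target in ((beta1, spec.h2[0]), (beta2, spec.h2[1])):
            realized = float((beta**2 * het).sum())
            if realized > 0 and target is not None:
                beta *= np.sqrt(target / realized)
    return beta1, beta2, labels


def simulate_z(
    effects: tuple[np.ndarray, np.ndarray],
    panel: ReferencePanel,
    ld: LdMatrix,
    n1: float,
    n2: float,
    sigma0s: tuple[float, float] = (1.0, 1.0),
    rho0: float = 0.0,
    seed: int = 0,
) -> tuple[SumStats, SumStats]:
    """GWAS z-scores via the convolution model.

    z_j = sqrt(N) sum_i sqrt(H_i) r_ij beta_i + residual, with the residual
    pair drawn from the correlated distortion N(0, [[s01^2, rho0 s01 s02],
    [., s02^2]]).  The LD sum runs over stored neighbours plus the self term.
    """
    beta1, beta2 = effects
    m = len(panel)
    root_h = np.sqrt(panel.het)
    rng = _rng(seed, _RESIDUALS)
    s01, s02 = np.sqrt(sigma0s[0]), np.sqrt(sigma0s[1])
    e1 = rng.standard_normal(m)
    e2 = rho0 * e1 + np.sqrt(max(1.0 - rho0**2, 0.0)) * rng.standard_normal(m)

    def one(beta, n, e, s0):
        v = root_h * beta
        delta = np.sqrt(n) * (v + ld.r @ v)
        return delta + s0 * e

    z1 = one(beta1, n1, e1, s01)
    z2 = one(beta2, n2, e2, s02)
    idx = np.arange(m)
    ss1 = SumStats(snp_id=panel.snp_id, z=z1, n=np.full(m, float(n1)), aligned_index=idx)
    ss2 = SumStats(snp_id=panel.snp_id, z=z2, n=np.full(m, float(n2)), aligned_index=idx)
    return ss1, ss2


def make_genotypes(
    panel: ReferencePanel,
    n_samples: int,
    block_size: int,
    phi: float = 0.9,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize 0/1/2 genotypes matching the panel's block-LD layout.

    Haplotypes come from a latent AR(1) Gaussian per block thresholded at the
    allele-frequency quantile; two independent haplotypes per individual give
    Hardy-Weinberg dosages with approximately the intended r profile.  This is
    a desk-scale construction and does not reproduce coalescent LD fine
    structure.
    """
    m = len(panel)
    rng = _rng(seed, _GENO)
    thresh = stats.norm.ppf(panel.maf)

    def haplotypes() -> np.ndarray:
        x = np.empty((n_samples, m))
        for start in range(0, m, block_size):
            end = min(start + block_size, m)
            e = rng.standard_normal((n_samples, end - start))
            x[:, start] = e[:, 0]
            for k in range(1, end - start):
                x[:, start + k] = phi * x[:, start + k - 1] + np.sqrt(1 - phi**2) * e[:, k]
        return (x < thresh).astype(np.int8)

    return (haplotypes() + haplotypes()).astype(float)


def simulate_genotype_gwas(
    genotypes: np.ndarray,
    beta: np.ndarray,
    h2_target: float,
    seed: int = 0,
    snp_id: np.ndarray | None = None,
) -> SumStats:
    """Per-SNP simple-regression GWAS on a synthesized quantitative phenotype.

    The phenotype is y = G beta + eps with the residual variance set so that
    var(G beta) / var(y) equals ``h2_target``; z-scores are Wald statistics of
    per-SNP simple regressions.
    """
    if not (0.0 < h2_target < 1.0):
        raise ValueError("h2_target must be in (0, 1)")
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    rng = _rng(seed, _PHENO)
    gb = g @ beta
    var_g = float(np.var(gb))
    if var_g == 0.0:
        raise ValueError("all effects are zero; h2_target unattainable")
    var_e = var_g * (1.0 - h2_target) / h2_target
    y = gb + rng.normal(0.0, np.sqrt(var_e), size=n)

    gz = g - g.mean(axis=0)
    sd = gz.std(axis=0)
    sd[sd == 0] = np.inf
    yz = (y - y.mean()) / y.std()
    r = (gz / sd).T @ yz / n
    r = np.clip(r, -0.999999, 0.999999)
    z = r * np.sqrt((n - 2) / (1.0 - r**2))
    ids = snp_id if snp_id is not None else np.array([f"rs{k:07d}" for k in range(m)])
    return SumStats(snp_id=ids, z=z, n=np.full(m, float(n)), aligned_index=np.arange(m))
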
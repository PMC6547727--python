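"""LD reference: panels, sparse allelic correlations, LD scores, pruning weights.

The mixture likelihood needs, for every GWAS SNP j, the local LD environment:
the allelic correlations r_ij with neighbouring variants i and the
heterozygosities H_i = 2 p_i (1 - p_i) that scale per-allele effects into
per-genotype variance.  This module builds that environment from genotype
dosages (or a PLINK bed/bim/fam fileset), stores it as a thresholded sparse
matrix, and derives the two per-SNP summaries the fast likelihood consumes:

* the heterozygosity-adjusted LD score  ell_j = sum_i H_i r_ij^2
* the fourth-moment sum                 m4_j  = sum_i H_i^2 r_ij^4

plus per-SNP random-pruning weights that down-weight large LD blocks in the
log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import h5py
from scipy import sparse

LD_FORMAT_VERSION = 1
_QUANT_SCALE = 32767  # int16 quantization of r; max abs error 1/65534


class AlignmentError(ValueError):
    """Raised when two per-SNP structures are not indexed over the same SNPs."""


@dataclass
class ReferencePanel:
    """Per-SNP reference metadata: ids, positions, alleles and allele frequency."""

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_eff: np.ndarray
    allele_oth: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_eff = np.asarray(self.allele_eff)
        self.allele_oth = np.asarray(self.allele_oth)
        self.maf = np.asarray(self.maf, dtype=float)
        if len(set(map(len, (self.snp_id, self.chrom, self.pos, self.allele_eff,
                             self.allele_oth, self.maf)))) != 1:
            raise ValueError("all panel columns must have equal length")
        if len(np.unique(self.snp_id)) != len(self.snp_id):
            raise ValueError("snp_id values must be unique")
        if np.any(self.maf <= 0.0) or np.any(self.maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def het(self) -> np.ndarray:
        """Heterozygosity H_j = 2 p_j (1 - p_j)."""
        return 2.0 * self.maf * (1.0 - self.maf)

    @property
    def h_total(self) -> float:
        """Sum of heterozygosity over the reference (used by heritability)."""
        return float(self.het.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_id,
                "CHR": self.chrom,
                "BP": self.pos,
                "A1": self.allele_eff,
                "A2": self.allele_oth,
                "MAF": self.maf,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
        return cls(
            snp_id=df["SNP"].to_numpy(),
            chrom=df["CHR"].to_numpy(),
            pos=df["BP"].to_numpy(),
            allele_eff=df["A1"].to_numpy(),
            allele_oth=df["A2"].to_numpy(),
            maf=df["MAF"].to_numpy(),
        )


@dataclass
class LdMatrix:
    """Sparse symmetric allelic-correlation matrix with storage metadata.

    Only off-diagonal pairs with r^2 >= ``r2_min`` inside a fixed SNP-count
    window are stored; the self-correlation r_jj = 1 is implicit and always
    accounted for by consumers.
    """

    r: sparse.csr_matrix  # off-diagonal entries only, both triangles stored
    window_snps: int
    r2_min: float

    def __post_init__(self) -> None:
        self.r = sparse.csr_matrix(self.r)
        self.r.sum_duplicates()

    @property
    def n_snps(self) -> int:
        return self.r.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of stored unordered off-diagonal pairs."""
        return self.r.nnz // 2

    def neighbors(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Stored neighbours (indices, r values) of SNP j, excluding j itself."""
        sl = slice(self.r.indptr[j], self.r.indptr[j + 1])
        return self.r.indices[sl], self.r.data[sl]

    def adjacency(self, r2_thresh: float) -> tuple[np.ndarray, np.ndarray]:
        """CSR (indptr, indices) of neighbours with r^2 >= r2_thresh."""
        coo = self.r.tocoo()
        keep = coo.data**2 >= r2_thresh
        adj = sparse.csr_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=self.r.shape
        )
        return adj.indptr, adj.indices

    def save(self, path) -> None:
        """Write triplets with int16-quantized r and a versioned header."""
        coo = sparse.triu(self.r, k=1).tocoo()
        rq = np.round(coo.data * _QUANT_SCALE).astype(np.int16)
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = LD_FORMAT_VERSION
            f.attrs["window_snps"] = self.window_snps
            f.attrs["r2_min"] = self.r2_min
            f.attrs["quant_scale"] = _QUANT_SCALE
            f.attrs["n_snps"] = self.r.shape[0]
            f.create_dataset("i", data=coo.row.astype(np.int32), chunks=True)
            f.create_dataset("j", data=coo.col.astype(np.int32), chunks=True)
            f.create_dataset("r_q", data=rq, chunks=True)

    @classmethod
    def load(cls, path) -> "LdMatrix":
        with h5py.File(path, "r") as f:
            version = int(f.attrs["format_version"])
            if version != LD_FORMAT_VERSION:
                raise ValueError(f"unsupported LD file version {version}")
            n = int(f.attrs["n_snps"])
            scale = float(f.attrs["quant_scale"])
            i = f["i"][:]
            j = f["j"][:]
            r = f["r_q"][:].astype(float) / scale
            window = int(f.attrs["window_snps"])
            r2_min = float(f.attrs["r2_min"])
        mat = sparse.csr_matrix(
            (np.concatenate([r, r]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )
        return cls(r=mat, window_snps=window, r2_min=r2_min)


@dataclass
class LdScores:
    """Heterozygosity-adjusted LD scores and fourth-moment sums per SNP."""

    ell: np.ndarray
    m4: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        """Shape term m4/ell entering the fast-model shape parameter eta."""
        return self.m4 / self.ell


@dataclass
class PruningWeights:
    """Per-SNP weights w_j = fraction of random-pruning iterations retaining j."""

    w: np.ndarray
    T: int
    r2_thresh: float
    seed: int

    @property
    def n_effective(self) -> float:
        """Effective number of SNPs, sum_j w_j."""
        return float(self.w.sum())


def _standardize(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages per SNP and z-standardize columns.

    Returns the standardized matrix and a boolean mask of monomorphic columns
    (zero variance after imputation), which cannot enter a correlation.
    """
    g = np.array(genotypes, dtype=float)
    col_mean = np.nanmean(g, axis=0)
    nan_idx = np.where(np.isnan(g))
    if nan_idx[0].size:
        g[nan_idx] = np.take(col_mean, nan_idx[1])
    g -= g.mean(axis=0)
    sd = g.std(axis=0)
    mono = sd == 0.0
    sd = np.where(mono, 1.0, sd)
    return g / sd, mono


def compute_ld(
    genotypes: np.ndarray,
    window_snps: int = 50_000,
    r2_min: float = 0.05,
    chunk: int = 1024,
) -> LdMatrix:
    """Pairwise Pearson allelic correlations within a fixed SNP-count window.

    Parameters
    ----------
    genotypes : (n_samples, n_snps) array
        0/1/2 dosage matrix (float dosages and NaN missing values accepted;
        missing values are mean-imputed per SNP).
    window_snps : int
        Maximum index distance |i - j| of a stored pair.
    r2_min : float
        Pairs with r^2 below this threshold are not stored.
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] < 2:
        raise ValueError("genotypes must be a 2-D matrix with at least 2 SNPs")
    n, m = g.shape
    z, mono = _standardize(g)
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNP(s) excluded from LD computation",
            stacklevel=2,
        )
        z[:, mono] = 0.0  # zero column => zero correlation with everything

    rows, cols, vals = [], [], []
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        hi = min(b + window_snps, m)
        corr = z[:, a:b].T @ z[:, a:hi] / n
        ii, jj = np.nonzero(corr**2 >= r2_min)
        gi = ii + a
        gj = jj + a
        keep = (gj > gi) & (gj - gi <= window_snps) & ~mono[gi] & ~mono[gj]
        rows.append(gi[keep])
        cols.append(gj[keep])
        vals.append(np.clip(corr[ii[keep], jj[keep]], -1.0, 1.0))
    i = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    j = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    r = np.concatenate(vals) if vals else np.empty(0)
    mat = sparse.csr_matrix(
        (np.concatenate([r, r]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(m, m),
    )
    return LdMatrix(r=mat, window_snps=window_snps, r2_min=r2_min)


def ld_scores(ld: LdMatrix, panel: ReferencePanel) -> LdScores:
    """Heterozygosity-adjusted LD scores ell_j and fourth-moment sums m4_j.

    The self term (r_jj = 1) is always included: a causal SNP tags itself, so
    ell_j >= H_j even for an isolated SNP.
    """
    if ld.n_snps != len(panel):
        raise AlignmentError(
            f"LD matrix covers {ld.n_snps} SNPs but panel has {len(panel)}"
        )
    het = panel.het
    r2 = ld.r.copy()
    r2.data = r2.data**2
    ell = het + r2 @ het
    r4 = ld.r.copy()
    r4.data = r4.data**4
    m4 = het**2 + r4 @ het**2
    return LdScores(ell=ell, m4=m4)


def random_pruning_weights(
    ld: LdMatrix,
    r2_thresh: float = 0.1,
    T: int = 64,
    seed: int = 0,
) -> PruningWeights:
    """Per-SNP weights from repeated random pruning of the LD matrix.

    Each iteration visits SNPs in an independently shuffled order and retains a
    SNP unless it is in LD (r^2 >= ``r2_thresh``) with an already-retained SNP,
    producing a maximal subset with all pairwise r^2 below the threshold.  The
    weight of SNP j is the fraction of iterations retaining it, so the sum of
    weights equals the mean retained-subset size exactly.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    m = ld.n_snps
    indptr, indices = ld.adjacency(r2_thresh)
    counts = np.zeros(m, dtype=np.int64)
    rng = np.random.default_rng(seed)
    retained = np.zeros(m, dtype=bool)
    for _ in range(T):
        retained[:] = False
        order = rng.permutation(m)
        for jj in order:
            nb = indices[indptr[jj] : indptr[jj + 1]]
            if nb.size == 0 or not retained[nb].any():
                retained[jj] = True
        counts += retained
    return PruningWeights(w=counts / T, T=T, r2_thresh=r2_thresh, seed=seed)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode
# 2-bit genotype codes -> count of A1 alleles (01 = missing)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str) -> tuple[ReferencePanel, np.ndarray]:
    """Read a PLINK bed/bim/fam fileset into a panel and dosage matrix.

    Dosages count A1 alleles (0/1/2, NaN for missing), with A1 taken from the
    bim file as the effect allele.  The panel MAF is computed from the
    genotypes themselves.
    """
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["CHR", "SNP", "CM", "BP", "A1", "A2"],
        dtype={"CHR": str},
    )
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise ValueError("bed file size inconsistent with bim/fam dimensions")
    raw = raw.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack(
        [(raw >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(m, -1)[:, :n]
    dosages = _BED_DECODE[codes].T  # (n, m)
    freq = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    panel = ReferencePanel(
        snp_id=bim["SNP"].to_numpy(),
        chrom=bim["CHR"].to_numpy(),
        pos=bim["BP"].to_numpy(),
        allele_eff=bim["A1"].to_numpy(),
        allele_oth=bim["A2"].to_numpy(),
        maf=np.clip(maf, 1e-12, 0.5),
    )
    return panel, dosages


def write_plink(prefix: str, panel: ReferencePanel, dosages: np.ndarray) -> None:
    """Write a bed/bim/fam fileset (used to round-trip synthetic panels)."""
    n, m = dosages.shape
    bim = pd.DataFrame(
        {
            "CHR": panel.chrom,
            "SNP": panel.snp_id,
            "CM": 0,
            "BP": panel.pos,
            "A1": panel.allele_eff,
            "A2": panel.allele_oth,
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "FID": [f"F{k}" for k in range(n)],
            "IID": [f"I{k}" for k in range(n)],
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENO": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    # map A1 dosage -> 2-bit code
    code = np.full(dosages.T.shape, 1, dtype=np.uint8)  # missing by default
    d = dosages.T
    code[d == 2.0] = 0b00
    code[d == 1.0] = 0b10
    code[d == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.concatenate(
            [code, np.full((m, pad), 0b01, dtype=np.uint8)], axis=1
        )
    packed = (
        code.reshape(m, -1, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
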
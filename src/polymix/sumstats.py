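"""Reading, harmonizing and QC of GWAS summary statistics.

Input files are LDSC-style whitespace/tab-delimited text with at least a SNP
id, effect and other allele, a signed statistic (Z, or BETA+SE, or P with a
signed BETA/OR), and a per-SNP sample size N.  Harmonization aligns each
record to the LD reference panel: z-scores are flipped when the effect/other
alleles are swapped relative to the panel, strand flips are resolved via
complement, strand-ambiguous (A/T, C/G) SNPs are dropped, and standard filters
(panel MAF, imputation INFO when present, exclusion regions such as the MHC)
are applied with per-rule accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import ReferencePanel

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: MHC plus flanking long-range LD, GRCh37, 0-based half-open.
DEFAULT_EXCLUSION_REGIONS = [("6", 26_000_000, 34_000_000)]

DEFAULT_COLUMN_MAP = {
    "snp": "SNP",
    "a1": "A1",
    "a2": "A2",
    "z": "Z",
    "n": "N",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "info": "INFO",
}


class ColumnConfigError(ValueError):
    """A mandatory summary-statistics column could not be located."""


class OrientationError(ValueError):
    """Allele mismatch rate implies the file is on a different build/strand."""


@dataclass
class SumStats:
    """Harmonized per-SNP z-scores aligned to a reference panel."""

    snp_id: np.ndarray
    z: np.ndarray
    n: np.ndarray
    aligned_index: np.ndarray  # position of each record in the panel

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.aligned_index = np.asarray(self.aligned_index, dtype=np.int64)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z-scores must be finite")
        if np.any(self.n <= 0):
            raise ValueError("sample sizes must be positive")
        if len(np.unique(self.aligned_index)) != len(self.aligned_index):
            raise ValueError("each record must map to exactly one panel SNP")

    def __len__(self) -> int:
        return len(self.z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"SNP": self.snp_id, "Z": self.z, "N": self.n, "INDEX": self.aligned_index}
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "SumStats":
        df = pd.read_csv(path, sep="\t")
        return cls(
            snp_id=df["SNP"].to_numpy(),
            z=df["Z"].to_numpy(),
            n=df["N"].to_numpy(),
            aligned_index=df["INDEX"].to_numpy(),
        )


def effective_n(n_case: float, n_control: float) -> float:
    """Effective sample size 4 / (1/N_case + 1/N_control) for case-control GWAS."""
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def read_sumstats(path, column_map: dict | None = None, n_default: float | None = None) -> pd.DataFrame:
    """Parse a summary-statistics text file into a raw table with a Z column.

    The signed statistic is resolved in priority order: an explicit Z column;
    BETA/SE; or a two-sided P with the sign of BETA.  A ``z_source`` column
    records which rule produced each z.  Rows that yield a non-finite z are
    dropped and counted in ``df.attrs["n_unparsable"]``.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(path, sep=r"\s+", dtype={cmap["snp"]: str})
    upper = {c.upper(): c for c in df.columns}

    def col(key: str):
        name = cmap[key]
        return upper.get(name.upper())

    for key in ("snp", "a1", "a2"):
        if col(key) is None:
            raise ColumnConfigError(f"missing mandatory column {cmap[key]!r}")

    out = pd.DataFrame(
        {
            "SNP": df[col("snp")].astype(str),
            "A1": df[col("a1")].astype(str).str.upper(),
            "A2": df[col("a2")].astype(str).str.upper(),
        }
    )

    if col("z") is not None:
        out["Z"] = pd.to_numeric(df[col("z")], errors="coerce")
        out["z_source"] = "z"
    elif col("beta") is not None and col("se") is not None:
        beta = pd.to_numeric(df[col("beta")], errors="coerce")
        se = pd.to_numeric(df[col("se")], errors="coerce")
        out["Z"] = beta / se
        out["z_source"] = "beta/se"
    elif col("pval") is not None and col("beta") is not None:
        p = pd.to_numeric(df[col("pval")], errors="coerce")
        beta = pd.to_numeric(df[col("beta")], errors="coerce")
        out["Z"] = np.sign(beta) * stats.norm.isf(np.clip(p / 2.0, 1e-320, 1.0))
        out["z_source"] = "signed-p"
    else:
        raise ColumnConfigError("no usable signed statistic (Z, BETA+SE, or P+BETA)")

    if col("n") is not None:
        out["N"] = pd.to_numeric(df[col("n")], errors="coerce")
    elif n_default is not None:
        out["N"] = float(n_default)
    else:
        raise ColumnConfigError("no N column and no scalar n_default supplied")

    if col("info") is not None:
        out["INFO"] = pd.to_numeric(df[col("info")], errors="coerce")

    ok = np.isfinite(out["Z"]) & np.isfinite(out["N"]) & (out["N"] > 0)
    out.attrs["n_unparsable"] = int((~ok).sum())
    return out.loc[ok].reset_index(drop=True)


def harmonize(
    raw: pd.DataFrame,
    panel: ReferencePanel,
    maf_min: float = 0.05,
    info_min: float = 0.9,
    exclusion_regions: list[tuple] | None = None,
    max_mismatch_rate: float = 0.5,
) -> tuple[SumStats, dict]:
    """Align raw records to the panel and apply QC filters.

    Returns the harmonized :class:`SumStats` and a report dict counting records
    dropped per rule.  Exclusion regions are (chrom, start, end) 0-based
    half-open intervals; the default is the extended MHC on GRCh37.  When the
    table has no INFO column the INFO filter is skipped.
    """
    if exclusion_regions is None:
        exclusion_regions = DEFAULT_EXCLUSION_REGIONS
    report: dict = {"input": len(raw)}

    pos_in_panel = pd.Series(np.arange(len(panel)), index=panel.snp_id)
    idx = pos_in_panel.reindex(raw["SNP"].astype(str))
    in_panel = np.isfinite(idx.to_numpy())
    report["not_in_panel"] = int((~in_panel).sum())
    df = raw.loc[in_panel].reset_index(drop=True)
    pidx = idx.to_numpy()[in_panel].astype(np.int64)

    # drop duplicate mappings to the same panel SNP (keep first)
    first = ~pd.Series(pidx).duplicated().to_numpy()
    report["duplicate"] = int((~first).sum())
    df = df.loc[first].reset_index(drop=True)
    pidx = pidx[first]

    a1 = df["A1"].to_numpy()
    a2 = df["A2"].to_numpy()
    ref_eff = np.char.upper(panel.allele_eff[pidx].astype(str))
    ref_oth = np.char.upper(panel.allele_oth[pidx].astype(str))

    ambiguous = np.array([(x, y) in _AMBIGUOUS for x, y in zip(a1, a2)])
    comp = np.vectorize(lambda b: _COMPLEMENT.get(b, "N"))
    a1c, a2c = comp(a1), comp(a2)

    same = (a1 == ref_eff) & (a2 == ref_oth)
    swapped = (a1 == ref_oth) & (a2 == ref_eff)
    strand = (a1c == ref_eff) & (a2c == ref_oth)
    strand_swapped = (a1c == ref_oth) & (a2c == ref_eff)

    matched = (same | swapped | strand | strand_swapped) & ~ambiguous
    mism = ~(same | swapped | strand | strand_swapped) & ~ambiguous
    if len(df) and mism.sum() / max(len(df), 1) > max_mismatch_rate:
        raise OrientationError(
            f"{int(mism.sum())}/{len(df)} allele mismatches; "
            "summary statistics likely on a different genome build"
        )
    report["ambiguous"] = int(ambiguous.sum())
    report["allele_mismatch"] = int(mism.sum())

    flip = np.where(swapped | strand_swapped, -1.0, 1.0)
    z = df["Z"].to_numpy() * flip

    keep = matched.copy()

    maf_fail = panel.maf[pidx] < maf_min
    report["maf"] = int((keep & maf_fail).sum())
    keep &= ~maf_fail

    if "INFO" in df.columns:
        info_fail = df["INFO"].to_numpy() < info_min
        report["info"] = int((keep & info_fail).sum())
        keep &= ~info_fail
    else:
        report["info"] = 0

    chrom = panel.chrom[pidx].astype(str)
    pos = panel.pos[pidx]
    in_region = np.zeros(len(df), dtype=bool)
    for c, start, end in exclusion_regions:
        in_region |= (chrom == str(c)) & (pos >= start) & (pos < end)
    report["excluded_region"] = int((keep & in_region).sum())
    keep &= ~in_region

    report["output"] = int(keep.sum())
    ss = SumStats(
        snp_id=df["SNP"].to_numpy()[keep],
        z=z[keep],
        n=df["N"].to_numpy()[keep],
        aligned_index=pidx[keep],
    )
    return ss, report
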
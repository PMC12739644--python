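"""Reading, writing, and cross-ancestry harmonization of standard inputs.

Conventions
-----------
* Summary statistics are tab-separated with a header row and columns
  ``snp_id, chr, pos, allele_effect, allele_other, z, n``; positions are
  1-based.
* LD blocks are BED-like (``chr  start  end  [block_id]``), 0-based
  half-open, non-overlapping within a chromosome.
* Regional LD is a dense numeric matrix (plain TSV, or a single-array
  ``.npy`` container) with a mandatory sidecar text file (same path plus
  ``.snps``) listing SNP ids in row order.
* Results are written as a TSV with one row per region; an undefined
  genetic correlation is serialized as ``NA`` while the genetic covariance
  stays numeric.

The harmonizer enforces allele logic only: strand-ambiguous (A/T, C/G)
SNPs are excluded, ancestry-2 effect alleles are aligned to ancestry-1
(flipping the Z sign on an allele swap, complement-matching across strand
flips), and the intersection of both summary-statistic tables and both LD
panels within a block is emitted in panel-1 row order.  MAF or imputation
quality control is the caller's responsibility upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .region import RegionData, decorrelate_region

__all__ = [
    "SUMSTATS_COLUMNS",
    "RESULT_COLUMNS",
    "LDPanel",
    "read_sumstats",
    "write_sumstats",
    "read_blocks",
    "write_blocks",
    "harmonize_region",
    "ld_from_genotypes",
    "save_ld",
    "load_ld",
    "results_to_frame",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["snp_id", "chr", "pos", "allele_effect", "allele_other", "z", "n"]
RESULT_COLUMNS = [
    "region_id", "chr", "start", "end", "m", "h1_sq", "h2_sq", "rho_g",
    "gamma_g", "p1", "p2", "p_composite", "p_composite_bh", "T_lrt",
    "p_rho", "p_rho_bh", "category", "flags",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class LDPanel:
    """One ancestry's regional LD matrix with its SNP-id sidecar."""

    snp_ids: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, float)
        object.__setattr__(self, "R", R)
        if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] != len(self.snp_ids):
            raise ValidationError("LD matrix shape must match SNP-id sidecar")


def read_sumstats(path) -> pd.DataFrame:
    """Parse a summary-statistics TSV.

    Rows with missing or non-finite Z, or with alleles outside {A,C,G,T},
    are dropped with a logged count.  Duplicated SNP ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chr": str},
                     na_values=["NA", "NaN", ""], keep_default_na=True)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df["z"] = pd.to_numeric(df["z"], errors="coerce")
    n0 = len(df)
    ok_alleles = (df["allele_effect"].isin(_COMPLEMENT)
                  & df["allele_other"].isin(_COMPLEMENT))
    df = df[np.isfinite(df["z"]) & ok_alleles].reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        logger.info("%s: dropped %d row(s) with missing Z or invalid alleles",
                    path, dropped)
    dups = df["snp_id"][df["snp_id"].duplicated()].unique()
    if dups.size:
        raise ValidationError(f"{path}: duplicated snp_id(s): {list(dups[:10])}")
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SUMSTATS_COLUMNS,
              float_format="%.17g")


def read_blocks(path) -> pd.DataFrame:
    """Parse a BED-like block-definition file (0-based half-open), sorted and
    validated for non-overlap within each chromosome."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need at least 3 columns (chr, start, end)")
    out = pd.DataFrame({
        "chr": df[0].astype(str),
        "start": pd.to_numeric(df[1], errors="raise").astype(int),
        "end": pd.to_numeric(df[2], errors="raise").astype(int),
    })
    out["block_id"] = (df[3].astype(str) if df.shape[1] > 3
                       else [f"block_{i:04d}" for i in range(len(df))])
    bad = out[out["start"] >= out["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"{path}: block {row.block_id} has start >= end "
            f"({row.start} >= {row.end})")
    out = out.sort_values(["chr", "start"], kind="mergesort").reset_index(drop=True)
    for _, grp in out.groupby("chr", sort=False):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        overlap = np.flatnonzero(starts[1:] < ends[:-1])
        if overlap.size:
            i = overlap[0]
            raise ValidationError(
                f"{path}: overlapping blocks {grp.iloc[i].block_id} and "
                f"{grp.iloc[i + 1].block_id}")
    return out


def write_blocks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=["chr", "start", "end", "block_id"])


def _align_allele(e1: str, o1: str, e2: str, o2: str) -> int | None:
    """Sign for ancestry-2 Z after aligning to ancestry-1 alleles; None if
    the allele pairs cannot be reconciled."""
    if (e2, o2) == (e1, o1):
        return 1
    if (e2, o2) == (o1, e1):
        return -1
    ce, co = _COMPLEMENT[e1], _COMPLEMENT[o1]
    if (e2, o2) == (ce, co):
        return 1
    if (e2, o2) == (co, ce):
        return -1
    return None


def harmonize_region(
    s1: pd.DataFrame,
    s2: pd.DataFrame,
    block,
    panel1: LDPanel,
    panel2: LDPanel,
    *,
    trunc_tol: float = 1e-4,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
) -> RegionData | None:
    """Intersect and allele-align one block's data across both ancestries.

    ``block`` is a mapping/row with ``chr``, ``start``, ``end``, ``block_id``.
    Returns ``None`` (logged) when no SNP survives the intersection; the
    caller should skip the region rather than abort.
    """
    chrom = str(block["chr"])
    start, end = int(block["start"]), int(block["end"])
    in1 = s1[(s1["chr"] == chrom) & (s1["pos"] - 1 >= start) & (s1["pos"] - 1 < end)]
    in2 = s2[(s2["chr"] == chrom) & (s2["pos"] - 1 >= start) & (s2["pos"] - 1 < end)]
    t1 = in1.set_index("snp_id")
    t2 = in2.set_index("snp_id")
    panel1_order = [s for s in panel1.snp_ids]
    panel2_index = {s: i for i, s in enumerate(panel2.snp_ids)}
    panel1_index = {s: i for i, s in enumerate(panel1.snp_ids)}

    keep: list[str] = []
    signs: list[int] = []
    n_ambiguous = n_mismatch = 0
    for snp in panel1_order:
        if snp not in t1.index or snp not in t2.index or snp not in panel2_index:
            continue
        e1, o1 = t1.at[snp, "allele_effect"], t1.at[snp, "allele_other"]
        e2, o2 = t2.at[snp, "allele_effect"], t2.at[snp, "allele_other"]
        if frozenset((e1, o1)) in _AMBIGUOUS or frozenset((e2, o2)) in _AMBIGUOUS:
            n_ambiguous += 1
            continue
        sign = _align_allele(e1, o1, e2, o2)
        if sign is None:
            n_mismatch += 1
            continue
        keep.append(snp)
        signs.append(sign)
    if n_ambiguous or n_mismatch:
        logger.info("block %s: excluded %d strand-ambiguous and %d "
                    "allele-mismatched SNP(s)", block["block_id"],
                    n_ambiguous, n_mismatch)
    if not keep:
        logger.warning("block %s: empty after harmonization; skipped",
                       block["block_id"])
        return None

    idx1 = [panel1_index[s] for s in keep]
    idx2 = [panel2_index[s] for s in keep]
    R1 = panel1.R[np.ix_(idx1, idx1)]
    R2 = panel2.R[np.ix_(idx2, idx2)]
    z1 = t1.loc[keep, "z"].to_numpy(float)
    z2 = t2.loc[keep, "z"].to_numpy(float) * np.asarray(signs, float)
    n1 = float(np.median(t1.loc[keep, "n"]))
    n2 = float(np.median(t2.loc[keep, "n"]))
    return RegionData(
        region_id=str(block["block_id"]), z1=z1, z2=z2, n1=n1, n2=n2,
        fac1=decorrelate_region(R1, trunc_tol),
        fac2=decorrelate_region(R2, trunc_tol),
        snp_ids=keep, lambda1=lambda1, lambda2=lambda2,
        chrom=chrom, start=start, end=end)


def ld_from_genotypes(G: np.ndarray) -> np.ndarray:
    """SNP-SNP correlation ``G'G / n`` from a column-standardized genotype
    matrix, symmetrized with unit diagonal."""
    G = np.asarray(G, float)
    sd = G.std(axis=0)
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        raise ValidationError(f"zero-variance genotype column(s): {list(zero[:10])}")
    n = G.shape[0]
    R = G.T @ G / n
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def save_ld(path, panel: LDPanel) -> None:
    """Write an LD matrix (TSV, or .npy if the path ends in .npy) plus the
    mandatory ``<path>.snps`` sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, panel.R)
    else:
        np.savetxt(path, panel.R, delimiter="\t", fmt="%.10g")
    Path(str(path) + ".snps").write_text("\n".join(panel.snp_ids) + "\n")


def load_ld(path) -> LDPanel:
    path = Path(path)
    sidecar = Path(str(path) + ".snps")
    if not sidecar.exists():
        raise FormatError(f"missing LD sidecar SNP list: {sidecar}")
    snp_ids = sidecar.read_text().split()
    R = np.load(path) if path.suffix == ".npy" else np.loadtxt(path, delimiter="\t")
    R = np.atleast_2d(R)
    return LDPanel(snp_ids=snp_ids, R=R)


def results_to_frame(results) -> pd.DataFrame:
    """Convert RegionTestResult rows to the canonical results table."""
    rows = []
    for r in results:
        rows.append({
            "region_id": r.region_id, "chr": r.chrom, "start": r.start,
            "end": r.end, "m": r.m, "h1_sq": r.h1_sq, "h2_sq": r.h2_sq,
            "rho_g": r.rho_g, "gamma_g": r.gamma_g, "p1": r.p1, "p2": r.p2,
            "p_composite": r.p_composite, "p_composite_bh": r.p_composite_bh,
            "T_lrt": r.T_lrt, "p_rho": r.p_rho, "p_rho_bh": r.p_rho_bh,
            "category": r.category, "flags": ";".join(r.flags) or ".",
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results, path) -> None:
    """Write the results TSV (lossless at 17 significant digits; undefined
    genetic correlations become ``NA``)."""
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                       dtype={"region_id": str, "chr": str, "flags": str})
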
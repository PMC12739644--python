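"""Evaluation harness: empirical FDR, power, and estimation accuracy
against simulator ground truth.

Definitions (per the standard convention for region-level discovery):
power is the proportion of truly genetically correlated regions (both
heritabilities positive and gamma > 0) that are detected; FDR is the
proportion of falsely detected regions among all detected regions (0 when
nothing is detected).  Mean squared errors are reported for heritability,
genetic covariance, and — restricted to both-heritable truths, where it is
defined — genetic correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["EvalSummary", "evaluate_scan", "fdr_power_curve"]


@dataclass
class EvalSummary:
    """Scenario-level evaluation of one scan against truth."""

    n_regions: int
    fdr_corr: float
    power_corr: float
    fdr_herit: float
    power_herit: float
    mse_h1: float
    mse_h2: float
    mse_rho: float
    mse_gamma: float  # both-heritable truths only
    n_gamma_undefined: int  # estimates undefined on both-heritable truths
    curve: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if k != "curve"}


def _fdr_power(called: np.ndarray, true_pos: np.ndarray) -> tuple[float, float]:
    n_called = int(called.sum())
    fdr = float((called & ~true_pos).sum() / n_called) if n_called else 0.0
    n_true = int(true_pos.sum())
    power = float((called & true_pos).sum() / n_true) if n_true else float("nan")
    return fdr, power


def fdr_power_curve(p_adj: np.ndarray, true_pos: np.ndarray,
                    thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Empirical (threshold, FDR, power) table over BH-adjusted p cutoffs."""
    if thresholds is None:
        thresholds = np.concatenate([np.linspace(0.001, 0.1, 34),
                                     np.linspace(0.12, 1.0, 23)])
    rows = []
    p = np.asarray(p_adj, float)
    for t in thresholds:
        called = np.isfinite(p) & (p < t)
        fdr, power = _fdr_power(called, true_pos)
        rows.append({"threshold": float(t), "fdr": fdr, "power": power})
    return pd.DataFrame(rows)


def evaluate_scan(results: pd.DataFrame, truth: pd.DataFrame,
                  alpha: float = 0.05) -> EvalSummary:
    """Join a results table with simulator truth and summarize.

    ``truth`` needs columns ``region_id, category, h1_sq, h2_sq, gamma,
    rho_g``; ``results`` is the scan output table.  Detection of genetic
    correlation uses BH-adjusted LRT p-values at ``alpha``; detection of
    joint heritability uses the BH-adjusted composite p-value.
    """
    unmatched = sorted(set(results["region_id"]) ^ set(truth["region_id"]))
    if unmatched:
        raise ValidationError(f"region ids do not match: {unmatched[:10]}")
    df = results.merge(truth, on="region_id", suffixes=("", "_true"))

    # scan output's "category" is integer-coded; truth's is the label column
    cat = df["category_true"] if "category_true" in df.columns else df["category_y"]
    truly_corr = (cat == "both") & (df["gamma"] > 0)
    truly_both = (cat == "both")

    p_rho = pd.to_numeric(df["p_rho_bh"], errors="coerce").to_numpy()
    called_corr = np.isfinite(p_rho) & (p_rho < alpha)
    p_comp = pd.to_numeric(df["p_composite_bh"], errors="coerce").to_numpy()
    called_both = np.isfinite(p_comp) & (p_comp < alpha)

    fdr_c, pow_c = _fdr_power(called_corr, truly_corr.to_numpy())
    fdr_h, pow_h = _fdr_power(called_both, truly_both.to_numpy())

    h1 = pd.to_numeric(df["h1_sq"], errors="coerce")
    h2 = pd.to_numeric(df["h2_sq"], errors="coerce")
    rho = pd.to_numeric(df["rho_g"], errors="coerce")
    gam = pd.to_numeric(df["gamma_g"], errors="coerce")
    mse_h1 = float(np.nanmean((h1 - df["h1_sq_true"]) ** 2))
    mse_h2 = float(np.nanmean((h2 - df["h2_sq_true"]) ** 2))
    mse_rho = float(np.nanmean((rho - df["rho_g_true"]) ** 2))
    both = truly_both.to_numpy()
    if both.any():
        err = (gam[both] - df.loc[both, "gamma"]) ** 2
        mse_gamma = float(np.nanmean(err)) if np.isfinite(err).any() else float("nan")
        n_undef = int((~np.isfinite(gam[both])).sum())
    else:
        mse_gamma, n_undef = float("nan"), 0
    curve = fdr_power_curve(p_rho, truly_corr.to_numpy())
    return EvalSummary(
        n_regions=len(df), fdr_corr=fdr_c, power_corr=pow_c,
        fdr_herit=fdr_h, power_herit=pow_h, mse_h1=mse_h1, mse_h2=mse_h2,
        mse_rho=mse_rho, mse_gamma=mse_gamma, n_gamma_undefined=n_undef,
        curve=curve)
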
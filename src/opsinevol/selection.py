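"""Likelihood-ratio tests and BIC comparison of fitted codon models.

The LRT statistic is twice the log-likelihood difference of a nested
model pair, referred to a chi-square with df equal to the difference in
free parameter counts.  BIC is -2l + K log n with n the sample size in
codons; the log base defaults to 10, which is what reconciles the
package's published-table worked examples, and natural log is available
by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

#: default df for the standard nested comparisons; the branch-site
#: Model A vs null comparison defaults to df=2 (see compare_models).
DEFAULT_DF = {
    ("2w", "1w"): 1,
    ("3w", "2w"): 1,
    ("4w", "3w"): 1,
    ("4w-activity", "3w"): 1,
    ("M3", "M0"): 4,
    ("M2a", "M1a"): 2,
    ("M8", "M7"): 2,
    ("ModelA", "ModelA-null"): 2,
}

LRT_CLAMP_TOL = 1e-4  # optimizer noise allowance for tiny negative stats


@dataclass
class LrtResult:
    """2*Delta(lnL), its df and the chi-square upper-tail p-value."""

    comparison: str
    stat: float
    df: int
    p: float

    def formatted_stat(self) -> str:
        """Report convention: nearest integer when >= 10, else 1 decimal."""
        return f"{self.stat:.0f}" if self.stat >= 10 else f"{self.stat:.1f}"

    def formatted_p(self) -> str:
        return "<1e-05" if self.p < 1e-5 else f"{self.p:.3g}"


def lrt(lnl0: float, lnl1: float, df: int, comparison: str = "", tol: float = LRT_CLAMP_TOL) -> LrtResult:
    """Likelihood-ratio test of the richer model (lnl1) against the
    nested one (lnl0).  Tiny negative statistics (within ``tol``) are
    clamped to 0; larger ones signal mis-ordered models."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not (np.isfinite(lnl0) and np.isfinite(lnl1)):
        raise ValueError("log-likelihoods must be finite")
    stat = 2.0 * (lnl1 - lnl0)
    if stat < 0:
        if stat < -2 * tol:
            raise ValueError(
                f"lnl1 ({lnl1}) is below lnl0 ({lnl0}) beyond tolerance; "
                "models are mis-ordered or the rich fit did not converge"
            )
        stat = 0.0
    p = float(scipy.stats.chi2.sf(stat, df))
    return LrtResult(comparison=comparison, stat=stat, df=df, p=p)


def bic(lnl: float, K: int, n: float, log_base: float = 10.0) -> float:
    """Bayesian information criterion -2*lnl + K*log_base(n)."""
    if not np.isfinite(lnl) or not np.isfinite(n):
        raise ValueError("non-finite inputs to BIC")
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if K < 0:
        raise ValueError(f"parameter count must be >= 0, got {K}")
    return -2.0 * lnl + K * math.log(n, log_base)


def infer_sample_size(rows, log_base: float = 10.0):
    """Back-solve the BIC sample size from printed (lnL, K, BIC) rows.

    Each row pins log(n) to (BIC + 2*lnL)/K; with rows rounded to print
    precision the estimates disagree slightly, so the Chebyshev center
    (minimizing the worst absolute BIC discrepancy, which scales with
    K) is returned as (n, worst_row_error).
    """
    rows = list(rows)
    r = np.array([(b + 2 * l) / k for l, k, b in rows])
    K = np.array([k for _, k, _ in rows], dtype=float)
    lo, hi = r.min(), r.max()
    # minimize max_i K_i |x - r_i| over x in [lo, hi]; piecewise-linear
    xs = np.linspace(lo, hi, 20001)
    err = np.max(K[:, None] * np.abs(xs[None, :] - r[:, None]), axis=0)
    i = int(np.argmin(err))
    x = float(xs[i])
    return log_base**x, float(err[i])


@dataclass
class ModelComparisonTable:
    """Table-of-fits (model, lnL, K, BIC, estimates) plus LRT rows."""

    table: pd.DataFrame
    lrts: list
    n: float
    best_model: str

    def to_tsv(self, path, metadata: dict | None = None):
        with open(path, "w") as fh:
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}: {v}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    def lrt_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison": r.comparison,
                    "stat": r.stat,
                    "stat_printed": r.formatted_stat(),
                    "df": r.df,
                    "p": r.p,
                    "p_printed": r.formatted_p(),
                }
                for r in self.lrts
            ]
        )


def compare_models(
    fits,
    comparisons=None,
    n: float | None = None,
    log_base: float = 10.0,
) -> ModelComparisonTable:
    """Build the model-comparison table and LRT list from fitted models.

    ``fits`` is a list of FitResult (or any object with .model, .lnl,
    .K, .estimates).  ``comparisons`` lists (rich, nested) or (rich,
    nested, df) tuples; df defaults come from DEFAULT_DF, or the K
    difference for pairs not listed there (e.g. free vs 1w).
    """
    by_name = {f.model: f for f in fits}
    rows = []
    for f in fits:
        row = {"model": f.model, "lnL": f.lnl, "K": f.K}
        if n is not None:
            row["BIC"] = bic(f.lnl, f.K, n, log_base)
        for k, v in f.estimates.items():
            row[k] = v
        rows.append(row)
    table = pd.DataFrame(rows)
    best = ""
    if n is not None and len(table):
        best = str(table.loc[table["BIC"].idxmin(), "model"])
        table["best_bic"] = table["model"] == best

    lrts = []
    for comp in comparisons or []:
        rich, nested, *rest = comp
        if rich not in by_name or nested not in by_name:
            raise KeyError(f"comparison {rich} x {nested} references an absent fit")
        f1, f0 = by_name[rich], by_name[nested]
        df = rest[0] if rest else DEFAULT_DF.get((rich, nested), f1.K - f0.K)
        lrts.append(lrt(f0.lnl, f1.lnl, df, comparison=f"{rich} x {nested}"))
    return ModelComparisonTable(table=table, lrts=lrts, n=n or float("nan"), best_model=best)
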
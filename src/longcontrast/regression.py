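"""Per-gene ordinary least squares of expression contrast on age.

For each gene ``j`` in group ``i`` the model is

    Y[:, j] = slope * age + intercept + noise,

fitted by least squares with centered sums of squares (numerically stable at
this problem scale, no normal-equation inversion).  The quantity of interest
downstream is the intercept — the expected contrast at age zero — together
with its standard error

    SE(intercept) = s * sqrt(1/n + abar^2 / S_aa),  s^2 = RSS / (n - 2),

where ``abar`` is the mean age and ``S_aa`` the centered age sum of squares.

Degenerate inputs (a constant response column, hence TSS = 0, or a constant
age vector) are flagged rather than raised: one flat gene must not abort a
multi-hundred-gene analysis, and flagged fits propagate p-values of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import ContrastMatrix

__all__ = ["RegressionFit", "fit_gene_regression", "fit_all_genes", "fits_to_frame"]


@dataclass(frozen=True)
class RegressionFit:
    """Everything the downstream intercept tests need from one gene's OLS fit."""

    slope: float
    intercept: float
    intercept_se: float
    t_intercept: float
    r_squared: float
    rss: float
    tss: float
    n: int
    df: int
    degenerate: bool = False


def fit_gene_regression(y: np.ndarray, a: np.ndarray) -> RegressionFit:
    """Least-squares fit of one gene's contrasts ``y`` on ages ``a``.

    Requires ``n >= 3`` finite observations.  If the age vector is constant
    the fit is degenerate: slope 0, intercept ``mean(y)``, ``r_squared`` 0.
    A constant response (TSS = 0) is likewise flagged degenerate.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise ValueError("y and a must be 1-d vectors of equal length")
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 observations (got {n}); df = n - 2 >= 1")
    if not (np.isfinite(y).all() and np.isfinite(a).all()):
        raise ValueError("non-finite values in response or ages")

    df = n - 2
    abar = a.mean()
    ybar = y.mean()
    ac = a - abar
    yc = y - ybar
    s_aa = float(ac @ ac)
    tss = float(yc @ yc)

    if s_aa == 0.0 or tss == 0.0:
        # Constant ages: slope unidentifiable, fall back to the mean model
        # (rss = tss).  Constant response: the mean model fits exactly
        # (rss = 0).  Either way the fit carries no test signal.
        rss = tss if s_aa == 0.0 else 0.0
        return RegressionFit(
            slope=0.0,
            intercept=float(ybar),
            intercept_se=0.0,
            t_intercept=0.0,
            r_squared=0.0,
            rss=float(rss),
            tss=float(tss),
            n=n,
            df=df,
            degenerate=True,
        )

    slope = float(ac @ yc) / s_aa
    intercept = ybar - slope * abar
    resid = yc - slope * ac
    rss = float(resid @ resid)
    r_squared = 1.0 - rss / tss
    s2 = rss / df
    intercept_se = math.sqrt(s2 * (1.0 / n + abar * abar / s_aa))
    if intercept_se > 0.0:
        t_intercept = intercept / intercept_se
    else:
        # Perfect fit (rss = 0): the t statistic degenerates to +/-inf unless
        # the intercept itself is exactly zero.
        t_intercept = 0.0 if intercept == 0.0 else math.copysign(math.inf, intercept)
    return RegressionFit(
        slope=slope,
        intercept=float(intercept),
        intercept_se=intercept_se,
        t_intercept=float(t_intercept),
        r_squared=float(r_squared),
        rss=rss,
        tss=float(tss),
        n=n,
        df=df,
        degenerate=False,
    )


def fit_all_genes(contrasts: ContrastMatrix) -> list[RegressionFit]:
    """Fit the per-gene regression to every column; order follows gene_names."""
    fits: list[RegressionFit] = []
    for j, gene in enumerate(contrasts.gene_names):
        try:
            fits.append(fit_gene_regression(contrasts.values[:, j], contrasts.ages))
        except ValueError as exc:
            raise ValueError(f"gene {gene!r}: {exc}") from exc
    return fits


def fits_to_frame(gene_names: list[str], fits: list[RegressionFit]):
    """Tabulate fits for export (gene, slope, intercept, se, t, R^2, df, flag)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": gene_names,
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "intercept_se": [f.intercept_se for f in fits],
            "t_intercept": [f.t_intercept for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "df": [f.df for f in fits],
            "degenerate": [f.degenerate for f in fits],
        }
    )
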
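"""The two p-value families, dual multiple-testing correction, and reporting.

Per gene ``j`` the pipeline tests two hypotheses:

* group A (null family):   H_j : intercept_1j = 0   against a two-sided
  complement, with p_j = 2 * F_df(-|t_j|) where ``F_df`` is the CDF of the
  t-distribution with ``n_1 - 2`` degrees of freedom and ``t_j`` the fitted
  intercept's t statistic;
* group B (alternative family): a one-sided upper-tail test at the calibrated
  level ``lambda_j``, with p~_j = 1 - F_df(t_shift) and
  ``t_shift = (intercept - lambda_j) / SE(intercept)`` — the standard
  t statistic for testing intercept = lambda_j, since testing
  ``intercept > lambda`` is equivalent to testing ``intercept - lambda > 0``.

Each family of ``m`` p-values is corrected separately at level ``alpha / 2``
(Bonferroni for FWER control, or Benjamini-Hochberg for FDR control), and the
reported findings are exactly the genes rejected in *both* families.

Degenerate regression fits contribute p = 1 in both families.  The
``tail`` option of :func:`alternative_pvalue` flips the one-sided direction
for users who prefer the lower tail; the default follows the upper-tail
formula above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calibration import CalibrationResult
from .regression import RegressionFit

__all__ = [
    "GeneTestTable",
    "RejectionSets",
    "Findings",
    "null_intercept_pvalue",
    "alternative_pvalue",
    "bonferroni_reject",
    "bh_reject",
    "build_test_table",
    "evaluate_hypotheses",
    "report_findings",
]

Correction = Literal["bonferroni", "bh"]
_PROCEDURE_LABEL = {"bonferroni": "FWER", "bh": "FDR"}


@dataclass
class GeneTestTable:
    """Per-gene p-value pairs: ``p_null`` for group A, ``p_alt`` for group B."""

    gene_names: list[str]
    p_null: np.ndarray
    p_alt: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.p_null = np.asarray(self.p_null, dtype=float)
        self.p_alt = np.asarray(self.p_alt, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        m = len(self.gene_names)
        if not (self.p_null.shape == self.p_alt.shape == self.lam.shape == (m,)):
            raise ValueError("gene_names, p_null, p_alt and lam must share length m")
        for name, p in (("p_null", self.p_null), ("p_alt", self.p_alt)):
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"{name} contains values outside [0, 1]")

    @property
    def m(self) -> int:
        return len(self.gene_names)


@dataclass(frozen=True)
class RejectionSets:
    """Rejected indices (0-based) per family under one correction procedure."""

    correction: Correction
    alpha: float
    rejected_null: frozenset[int]
    rejected_alt: frozenset[int]


@dataclass(frozen=True)
class Findings:
    """Genes rejected in both families, sorted by gene name."""

    genes: tuple[str, ...]
    correction: Correction
    procedure_label: str
    alpha: float
    p_null: tuple[float, ...]
    p_alt: tuple[float, ...]


def null_intercept_pvalue(fit: RegressionFit) -> float:
    """Two-sided p-value for a zero intercept in a group-A fit."""
    if fit.degenerate:
        return 1.0
    return float(2.0 * stats.t.cdf(-abs(fit.t_intercept), df=fit.df))


def alternative_pvalue(
    fit: RegressionFit, lam: float, tail: Literal["upper", "lower"] = "upper"
) -> float:
    """One-sided p-value of the shifted intercept test at level ``lam``.

    Upper tail (default): ``1 - F_df((intercept - lam) / SE)``, small when the
    fitted intercept sits far above the calibrated level.
    """
    if not np.isfinite(lam):
        raise ValueError("lam must be finite")
    if fit.degenerate:
        return 1.0
    if fit.intercept_se == 0.0:
        # Perfect fit: the statistic is +/-inf unless the level is hit exactly.
        if fit.intercept == lam:
            t_shift = 0.0
        else:
            t_shift = np.inf if fit.intercept > lam else -np.inf
    else:
        t_shift = (fit.intercept - lam) / fit.intercept_se
    p = stats.t.sf(t_shift, df=fit.df)
    if tail == "lower":
        p = stats.t.cdf(t_shift, df=fit.df)
    return float(p)


def bonferroni_reject(pvals: Sequence[float], level: float) -> frozenset[int]:
    """Indices with ``p <= level / m`` (0-based); FWER control at ``level``."""
    _check_level(level)
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return frozenset()
    return frozenset(np.flatnonzero(p <= level / p.size).tolist())


def bh_reject(pvals: Sequence[float], level: float) -> frozenset[int]:
    """Benjamini-Hochberg step-up at ``level`` (0-based indices; ties share fate)."""
    _check_level(level)
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return frozenset()
    reject, *_ = multipletests(p, alpha=level, method="fdr_bh")
    return frozenset(np.flatnonzero(reject).tolist())


def _check_level(level: float) -> None:
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level!r}")


def build_test_table(
    gene_names: Sequence[str],
    fits_A: Sequence[RegressionFit],
    fits_B: Sequence[RegressionFit],
    calibrations: Sequence[CalibrationResult],
    tail: Literal["upper", "lower"] = "upper",
) -> GeneTestTable:
    """Assemble both families of per-gene p-values into one table."""
    if not (len(gene_names) == len(fits_A) == len(fits_B) == len(calibrations)):
        raise ValueError("gene_names, fits and calibrations must share length m")
    p_null = np.array([null_intercept_pvalue(f) for f in fits_A])
    p_alt = np.array(
        [alternative_pvalue(f, c.lam, tail=tail) for f, c in zip(fits_B, calibrations)]
    )
    lam = np.array([c.lam for c in calibrations])
    return GeneTestTable(list(gene_names), p_null, p_alt, lam)


def evaluate_hypotheses(
    table: GeneTestTable, alpha: float, correction: Correction = "bh"
) -> RejectionSets:
    """Correct each family separately at ``alpha / 2`` with the chosen procedure.

    Splitting the overall level evenly between the null and alternative
    families keeps the total type-I error under ``alpha``.
    """
    _check_level(alpha)
    reject = {"bonferroni": bonferroni_reject, "bh": bh_reject}.get(correction)
    if reject is None:
        raise ValueError(f"correction must be 'bonferroni' or 'bh', got {correction!r}")
    return RejectionSets(
        correction=correction,
        alpha=alpha,
        rejected_null=reject(table.p_null, alpha / 2.0),
        rejected_alt=reject(table.p_alt, alpha / 2.0),
    )


def report_findings(sets: RejectionSets, table: GeneTestTable) -> Findings:
    """Report the genes rejected in both families, sorted by gene name.

    An empty intersection is a valid (and, under a global null, the expected)
    outcome.  The procedure label records whether the reported significances
    are with respect to FWER (Bonferroni) or FDR (Benjamini-Hochberg) control.
    """
    both = sorted(sets.rejected_null & sets.rejected_alt, key=lambda j: table.gene_names[j])
    return Findings(
        genes=tuple(table.gene_names[j] for j in both),
        correction=sets.correction,
        procedure_label=_PROCEDURE_LABEL[sets.correction],
        alpha=sets.alpha,
        p_null=tuple(float(table.p_null[j]) for j in both),
        p_alt=tuple(float(table.p_alt[j]) for j in both),
    )
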
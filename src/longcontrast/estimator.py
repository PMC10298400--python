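"""Scikit-learn style front end for the dual-family contrast test.

:class:`ContrastInterceptSelector` behaves like a feature selector: ``fit``
takes the stacked contrast matrix ``X`` (samples x genes), the ages ``y`` and
a per-sample ``groups`` vector of ``"A"``/``"B"`` labels, runs the per-gene
regressions, calibrates the alternative levels on group B, computes both
p-value families and the dual multiple-testing correction, and exposes the
reported genes through ``get_support`` / ``transform``.  It therefore drops
into sklearn pipelines and utilities (``clone``, ``get_params``) unchanged.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import calibrate_all
from .data_model import ContrastMatrix, StudyDesign
from .regression import fit_all_genes
from .testing import build_test_table, evaluate_hypotheses, report_findings

__all__ = ["ContrastInterceptSelector"]


class ContrastInterceptSelector(SelectorMixin, BaseEstimator):
    """Select genes whose contrast intercept departs from baseline in group A
    but tests significant against the calibrated level in group B.

    Parameters
    ----------
    alpha : float, default=0.05
        Overall significance budget; each p-value family is corrected at
        ``alpha / 2``.
    pi : float, default=0.35
        Fraction of each group-B gene's R^2 the misspecified intercept is
        allowed to retain when calibrating its level.
    correction : {"bh", "bonferroni"}, default="bh"
        Benjamini-Hochberg (FDR) or Bonferroni (FWER) per family.
    direction : {"below", "above"}, default="below"
        Which root of the calibration quadratic becomes the level.
    method : {"closed_form", "binary_search"}, default="closed_form"
        How the calibration root is computed.
    tail : {"upper", "lower"}, default="upper"
        Tail of the one-sided alternative-family test.

    Attributes
    ----------
    gene_names_ : list of str
        Column names used in the fit (``g0001`` ... if none supplied).
    fits_A_, fits_B_ : list of RegressionFit
        Per-gene regression results per group.
    calibrations_ : list of CalibrationResult
    lambda_ : ndarray of shape (m,)
        Calibrated alternative levels.
    pvalues_null_, pvalues_alt_ : ndarray of shape (m,)
        The two p-value families.
    rejections_ : RejectionSets
    findings_ : Findings
        Genes rejected in both families.
    support_mask_ : ndarray of bool, shape (m,)

    Examples
    --------
    >>> from longcontrast.simulate import SimulationConfig, generate_parametric
    >>> design, truth, _ = generate_parametric(SimulationConfig(m=20, seed=7))
    >>> sel = ContrastInterceptSelector().fit_design(design)
    >>> sel.pvalues_null_.shape
    (20,)
    """

    def __init__(
        self,
        alpha: float = 0.05,
        pi: float = 0.35,
        correction: str = "bh",
        direction: str = "below",
        method: str = "closed_form",
        tail: str = "upper",
    ) -> None:
        self.alpha = alpha
        self.pi = pi
        self.correction = correction
        self.direction = direction
        self.method = method
        self.tail = tail

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, groups=None, gene_names=None):
        """Fit from a stacked samples-x-genes contrast matrix.

        Parameters
        ----------
        X : array-like of shape (n1 + n2, m)
            Contrast values for all individuals of both groups.
        y : array-like of shape (n1 + n2,)
            Ages in years, aligned with the rows of ``X``.
        groups : array-like of "A"/"B" labels, shape (n1 + n2,)
            Group membership per row; required.
        gene_names : sequence of str, optional
            Column labels; synthesized if omitted.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (samples x genes)")
        if y.shape != (X.shape[0],):
            raise ValueError("y (ages) must have one entry per row of X")
        if groups is None:
            raise ValueError("groups ('A'/'B' per sample) is required")
        groups = np.asarray(groups, dtype=object).astype(str)
        if groups.shape != (X.shape[0],):
            raise ValueError("groups must have one entry per row of X")
        unknown = set(groups) - {"A", "B"}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if gene_names is None:
            gene_names = [f"g{j + 1:04d}" for j in range(X.shape[1])]
        gene_names = [str(g) for g in gene_names]

        parts = {}
        for label in ("A", "B"):
            idx = np.flatnonzero(groups == label)
            parts[label] = ContrastMatrix(
                values=X[idx],
                group=label,
                sample_ids=[f"{label}{k + 1:03d}" for k in range(idx.size)],
                gene_names=gene_names,
                ages=y[idx],
            )
        return self.fit_design(StudyDesign(parts["A"], parts["B"]))

    def fit_design(self, design: StudyDesign):
        """Fit directly from a :class:`~longcontrast.data_model.StudyDesign`."""
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha!r}")
        self.gene_names_ = list(design.gene_names)
        self.n_features_in_ = design.m
        self.fits_A_ = fit_all_genes(design.contrast_A)
        self.fits_B_ = fit_all_genes(design.contrast_B)
        self.calibrations_ = calibrate_all(
            self.fits_B_,
            pi=self.pi,
            direction=self.direction,
            method=self.method,
            gene_names=self.gene_names_,
        )
        self.lambda_ = np.array([c.lam for c in self.calibrations_])
        table = build_test_table(
            self.gene_names_, self.fits_A_, self.fits_B_, self.calibrations_,
            tail=self.tail,
        )
        self.test_table_ = table
        self.pvalues_null_ = table.p_null
        self.pvalues_alt_ = table.p_alt
        self.rejections_ = evaluate_hypotheses(table, self.alpha, self.correction)
        self.findings_ = report_findings(self.rejections_, table)
        mask = np.zeros(design.m, dtype=bool)
        mask[sorted(self.rejections_.rejected_null & self.rejections_.rejected_alt)] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
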
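"""Calibration of the per-gene alternative level lambda.

The alternative-family test for group B asks whether the fitted intercept
exceeds a gene-specific level ``lambda_j``.  That level is defined by
*degrading* the fit: holding the slope at its least-squares estimate, the
intercept is moved away from its estimate ``b_hat`` until the resulting
R-squared drops to a fraction ``pi`` (default 0.35) of the original value.

Because the least-squares residuals sum to zero, the R-squared of a
misspecified intercept ``b`` has the closed quadratic form

    R2(b) = 1 - (RSS + n * (b - b_hat)^2) / TSS,

which decreases monotonically in ``|b - b_hat|``.  Setting R2(b) = pi * R2
gives the exact root

    lambda = b_hat -/+ sqrt((1 - pi) * R2 * TSS / n),

one root on either side of the fitted intercept.  The closed form is the
default; a bracketing bisection over the same quadratic is retained as the
verification path (tolerance ``|delta R2| <= 1e-10``).

The default direction is ``below`` (the smaller root), which makes the
shifted statistic ``(b_hat - lambda) / SE`` positive for every calibrated
gene and produces the characteristic near-0/1 step shape of the sorted
alternative p-values.  Genes whose fit is degenerate or has non-positive
R-squared cannot be calibrated; they keep ``lambda = b_hat`` with
``converged=False`` so the downstream test sees a zero shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .regression import RegressionFit

__all__ = ["CalibrationResult", "r2_at_intercept", "calibrate_lambda", "calibrate_all"]

Direction = Literal["below", "above"]
Method = Literal["closed_form", "binary_search"]

#: Bisection stopping tolerance on |R2(b) - pi * R2|.
BISECT_TOL = 1e-10


@dataclass(frozen=True)
class CalibrationResult:
    """The calibrated level for one gene, with convergence diagnostics."""

    lam: float
    pi: float
    direction: Direction
    achieved_r2_fraction: float
    method: Method
    converged: bool


def r2_at_intercept(fit: RegressionFit, b: float) -> float:
    """R-squared of the fit with the intercept forced to ``b``, slope held.

    Equals ``1 - (RSS + n * (b - b_hat)^2) / TSS``; may be negative for a
    badly misspecified intercept.  Raises on degenerate fits (TSS = 0).
    """
    if fit.degenerate or fit.tss <= 0.0:
        raise ValueError("R2 is undefined for a degenerate fit (tss == 0)")
    delta = b - fit.intercept
    return 1.0 - (fit.rss + fit.n * delta * delta) / fit.tss


def _closed_form(fit: RegressionFit, pi: float, direction: Direction) -> float:
    offset = math.sqrt((1.0 - pi) * fit.r_squared * fit.tss / fit.n)
    return fit.intercept - offset if direction == "below" else fit.intercept + offset


def _binary_search(fit: RegressionFit, pi: float, direction: Direction) -> float:
    target = pi * fit.r_squared
    sign = -1.0 if direction == "below" else 1.0
    # Expand the far bound geometrically until R2 falls below the target.
    step = max(abs(fit.intercept), 1.0)
    near = fit.intercept
    far = fit.intercept + sign * step
    while r2_at_intercept(fit, far) > target:
        step *= 2.0
        far = fit.intercept + sign * step
    # R2 is monotone between near (R2 = r_squared >= target) and far.  Run
    # until both the R2 gap and the bracket width are tight, so the returned
    # root matches the closed form well below 1e-8 even when R2 is tiny.
    mid = 0.5 * (near + far)
    for _ in range(200):
        mid = 0.5 * (near + far)
        r2 = r2_at_intercept(fit, mid)
        if abs(r2 - target) <= BISECT_TOL and abs(far - near) <= 1e-12:
            return mid
        if r2 > target:
            near = mid
        else:
            far = mid
    return mid


def calibrate_lambda(
    fit: RegressionFit,
    pi: float = 0.35,
    direction: Direction = "below",
    method: Method = "closed_form",
) -> CalibrationResult:
    """Level ``lambda`` with ``r2_at_intercept(fit, lambda) = pi * R2``.

    ``pi`` must lie strictly in (0, 1).  Degenerate fits and fits with
    ``r_squared <= 0`` return ``lambda = b_hat`` with ``converged=False``.
    """
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must be in (0, 1), got {pi!r}")
    if direction not in ("below", "above"):
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    if fit.degenerate or fit.r_squared <= 0.0 or fit.tss <= 0.0:
        return CalibrationResult(
            lam=fit.intercept,
            pi=pi,
            direction=direction,
            achieved_r2_fraction=math.nan,
            method=method,
            converged=False,
        )
    if method == "closed_form":
        lam = _closed_form(fit, pi, direction)
    elif method == "binary_search":
        lam = _binary_search(fit, pi, direction)
    else:
        raise ValueError(f"unknown method {method!r}")
    achieved = r2_at_intercept(fit, lam) / fit.r_squared
    return CalibrationResult(
        lam=lam,
        pi=pi,
        direction=direction,
        achieved_r2_fraction=achieved,
        method=method,
        converged=True,
    )


def calibrate_all(
    fits_B: Sequence[RegressionFit],
    pi: float = 0.35,
    direction: Direction = "below",
    method: Method = "closed_form",
    gene_names: Sequence[str] | None = None,
) -> list[CalibrationResult]:
    """Calibrate every group-B gene; calibration never uses group-A fits."""
    results = []
    for j, fit in enumerate(fits_B):
        try:
            results.append(calibrate_lambda(fit, pi=pi, direction=direction, method=method))
        except ValueError as exc:
            gene = gene_names[j] if gene_names is not None else f"#{j}"
            raise ValueError(f"gene {gene!r}: {exc}") from exc
    return results
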
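"""Synthetic two-timepoint studies with known ground truth, and the pooled
bootstrap resampling scheme used to build showcase datasets.

The parametric generator emulates the study design the method targets: two
groups of n1 = 22 and n2 = 23 children with ages uniform on (0, 16) years and
a panel of m = 469 genes, each gene's contrast following

    contrast = intercept_group + slope_group * age + Normal(0, noise_sd^2).

Genes outside ``signal_genes`` have a group-A intercept of exactly zero, so
the generator provides an exact null for calibration of type-I error and an
exact alternative for power.  Paired timepoint matrices are emitted as well
(S is a synthetic baseline, R = S + contrast) so the full pipeline, including
contrast construction from raw matrices, can be exercised end to end.

The bootstrap scheme deliberately destroys per-gene structure: within each
group, all n_i x m contrast values are pooled and n_i x m values are redrawn
i.i.d. with replacement; ages are likewise resampled with replacement from
the group's original ages.  The result is a null-like dataset with the
marginal value distribution of the source.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .calibration import calibrate_all
from .data_model import ContrastMatrix, ExpressionMatrix, SampleMetadata, StudyDesign
from .regression import fit_all_genes
from .testing import build_test_table, evaluate_hypotheses, report_findings

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_parametric",
    "bootstrap_dataset",
    "estimate_type1_and_power",
]

DistSpec = tuple  # ("normal", mean, sd) | ("point", value) | ("uniform", lo, hi)


def _draw(spec: DistSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample from a small distribution-spec vocabulary."""
    family = spec[0]
    if family == "normal":
        _, mean, sd = spec
        return rng.normal(mean, sd, size=size)
    if family == "point":
        return np.full(size, float(spec[1]))
    if family == "uniform":
        _, lo, hi = spec
        return rng.uniform(lo, hi, size=size)
    raise ValueError(f"unknown distribution family {family!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the parametric generator.

    Defaults mirror the motivating design: group sizes 22 and 23, 469 genes,
    ages uniform on the open interval (0, 16) years.  Distribution specs are
    small tuples: ``("normal", mean, sd)``, ``("point", value)`` or
    ``("uniform", lo, hi)``.
    """

    n1: int = 22
    n2: int = 23
    m: int = 469
    age_range: tuple[float, float] = (0.0, 16.0)
    slope_dist: DistSpec = ("normal", 0.0, 0.5)
    intercept_dist_A: DistSpec = ("point", 0.0)
    intercept_dist_B: DistSpec = ("point", 0.0)
    signal_intercept_dist: DistSpec = ("normal", 2.0, 0.5)
    noise_sd: float = 1.0
    signal_genes: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 3 or self.n2 < 3:
            raise ValueError("group sizes must be at least 3")
        if self.m < 1:
            raise ValueError("need at least one gene")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be an increasing interval")
        bad = [j for j in self.signal_genes if not 0 <= j < self.m]
        if bad:
            raise ValueError(f"signal_genes indices out of range: {bad}")
        # Validate distribution specs eagerly so config errors fail fast.
        probe = np.random.default_rng(0)
        for spec in (
            self.slope_dist,
            self.intercept_dist_A,
            self.intercept_dist_B,
            self.signal_intercept_dist,
        ):
            _draw(spec, 1, probe)


@dataclass(frozen=True)
class GroundTruth:
    """True per-gene parameters underlying a generated study."""

    slope_A: np.ndarray
    slope_B: np.ndarray
    intercept_A: np.ndarray
    intercept_B: np.ndarray
    signal_genes: frozenset[int]


def _ages(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Ages strictly inside the open interval (lo, hi)."""
    ages = rng.uniform(lo, hi, size=n)
    while np.any(ages <= lo) or np.any(ages >= hi):  # pragma: no cover - p ~ 0
        redo = (ages <= lo) | (ages >= hi)
        ages[redo] = rng.uniform(lo, hi, size=int(redo.sum()))
    return ages


def generate_parametric(
    config: SimulationConfig,
) -> tuple[StudyDesign, GroundTruth, dict]:
    """Generate a study with known truth; identical seed, identical output.

    Returns the :class:`StudyDesign` of contrasts, the :class:`GroundTruth`,
    and a dict of raw pieces (timepoint matrices ``R``/``S`` per group and
    metadata rows) for pipelines that start from files.  One root seed feeds
    independent substreams for ages/parameters and each group's noise, so
    enlarging the panel does not perturb the age draws.
    """
    root = np.random.SeedSequence(config.seed)
    ss_ages, ss_params, ss_A, ss_B, ss_base = root.spawn(5)
    rng_ages = np.random.default_rng(ss_ages)
    rng_params = np.random.default_rng(ss_params)
    rng = {"A": np.random.default_rng(ss_A), "B": np.random.default_rng(ss_B)}
    rng_base = np.random.default_rng(ss_base)

    lo, hi = config.age_range
    ages = {
        "A": _ages(rng_ages, config.n1, lo, hi),
        "B": _ages(rng_ages, config.n2, lo, hi),
    }

    m = config.m
    slope = {
        "A": _draw(config.slope_dist, m, rng_params),
        "B": _draw(config.slope_dist, m, rng_params),
    }
    intercept = {
        "A": _draw(config.intercept_dist_A, m, rng_params),
        "B": _draw(config.intercept_dist_B, m, rng_params),
    }
    signal = sorted(config.signal_genes)
    if signal:
        intercept["A"][signal] = _draw(
            config.signal_intercept_dist, len(signal), rng_params
        )
    # Genes outside signal_genes carry an exactly-zero group-A intercept.
    nonsignal = np.setdiff1d(np.arange(m), np.array(signal, dtype=int))
    intercept["A"][nonsignal] = 0.0

    gene_names = [f"gene{j + 1:04d}" for j in range(m)]
    contrasts: dict[str, ContrastMatrix] = {}
    raw: dict = {"meta": [], "R": {}, "S": {}}
    sizes = {"A": config.n1, "B": config.n2}
    for group in ("A", "B"):
        n_i = sizes[group]
        ids = [f"{group}{k + 1:03d}" for k in range(n_i)]
        noise = rng[group].normal(0.0, config.noise_sd, size=(n_i, m))
        values = intercept[group][None, :] + ages[group][:, None] * slope[group][None, :] + noise
        contrasts[group] = ContrastMatrix(
            values=values,
            group=group,
            sample_ids=ids,
            gene_names=gene_names,
            ages=ages[group],
        )
        # Synthetic baseline expression; R - S reproduces the contrast exactly.
        baseline = rng_base.normal(8.0, 2.0, size=(n_i, m))
        raw["S"][group] = ExpressionMatrix(baseline, ids, gene_names, "t1")
        raw["R"][group] = ExpressionMatrix(baseline + values, ids, gene_names, "t2")
        raw["meta"].extend(
            SampleMetadata(sid, group, float(age)) for sid, age in zip(ids, ages[group])
        )

    truth = GroundTruth(
        slope_A=slope["A"],
        slope_B=slope["B"],
        intercept_A=intercept["A"],
        intercept_B=intercept["B"],
        signal_genes=frozenset(config.signal_genes),
    )
    return StudyDesign(contrasts["A"], contrasts["B"]), truth, raw


def bootstrap_dataset(design: StudyDesign, seed: int) -> StudyDesign:
    """Pooled within-group bootstrap of a contrast design.

    For each group independently, all ``n_i * m`` contrast values are
    flattened into one pool and ``n_i * m`` values are redrawn i.i.d. with
    replacement — gene identity is deliberately destroyed.  Group sizes and
    the gene panel are kept fixed; ages are resampled with replacement from
    the group's original ages.
    """
    root = np.random.SeedSequence(seed)
    ss_A, ss_B = root.spawn(2)
    streams = {"A": np.random.default_rng(ss_A), "B": np.random.default_rng(ss_B)}
    out: dict[str, ContrastMatrix] = {}
    for group, source in (("A", design.contrast_A), ("B", design.contrast_B)):
        rng = streams[group]
        pool = source.values.ravel()
        values = rng.choice(pool, size=source.values.shape, replace=True)
        ages = rng.choice(source.ages, size=source.ages.shape, replace=True)
        out[group] = ContrastMatrix(
            values=values,
            group=group,
            sample_ids=list(source.sample_ids),
            gene_names=list(source.gene_names),
            ages=ages,
        )
    return StudyDesign(out["A"], out["B"])


def estimate_type1_and_power(
    config: SimulationConfig,
    alpha: float = 0.05,
    correction: Literal["bonferroni", "bh"] = "bh",
    reps: int = 10,
    pi: float = 0.35,
) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of the full pipeline.

    Runs ``reps`` independent replicates of the generator + pipeline and
    returns one summary row with the raw per-gene null-family rejection rate
    at level ``alpha`` among non-signal genes (type I), among signal genes
    (power), and the rate at which non-signal genes enter the reported
    findings (false reporting rate).
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    signal = np.zeros(config.m, dtype=bool)
    signal[sorted(config.signal_genes)] = True
    null_rej = sig_rej = null_reported = 0
    n_null = int((~signal).sum()) * reps
    n_sig = int(signal.sum()) * reps
    for r in range(reps):
        rep_cfg = replace(config, seed=int((config.seed + 1_000_003 * r) % 2**31))
        design, _, _ = generate_parametric(rep_cfg)
        fits_A = fit_all_genes(design.contrast_A)
        fits_B = fit_all_genes(design.contrast_B)
        calib = calibrate_all(fits_B, pi=pi)
        table = build_test_table(design.gene_names, fits_A, fits_B, calib)
        raw_reject = table.p_null <= alpha
        null_rej += int(raw_reject[~signal].sum())
        sig_rej += int(raw_reject[signal].sum())
        findings = report_findings(evaluate_hypotheses(table, alpha, correction), table)
        reported = np.isin(np.array(design.gene_names), np.array(findings.genes))
        null_reported += int(reported[~signal].sum())
    return pd.DataFrame(
        {
            "reps": [reps],
            "alpha": [alpha],
            "correction": [correction],
            "type1_rate": [null_rej / n_null if n_null else np.nan],
            "power": [sig_rej / n_sig if n_sig else np.nan],
            "false_reporting_rate": [null_reported / n_null if n_null else np.nan],
        }
    )
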
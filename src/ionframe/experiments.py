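"""Validation experiments on synthetic cohorts with known ground truth.

These are the package's quantitative self-checks: each function simulates
data under the study design emulated by :mod:`ionframe.synthdata`, runs the
relevant pipeline stage(s), and measures recovery of the planted truth or
the calibration of a test statistic.  They are used by the test suite and
by ``scripts/acceptance.py``.

The reference experiment sizes (a 5-group x 4-replicate cohort of 200
proteins with 5 peptides each, 20 planted proteins at |log2 FC| >= 1,
1% outlier peptides, per-run bias in [0.5, 2], linear RT drift up to
+/- 60 s, noise CV 0.15) match the generator defaults; seeds are passed in
so every quantity is recomputed from scratch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, kstest

from . import align as _align
from .differential import intragroup_cv
from .patterns import Pattern, assign_pattern
from .pipeline import PipelineConfig, run_pipeline
from .survival import logrank_median_split
from .synthdata import (
    CohortDesign,
    GroundTruth,
    planted_fold_change_spec,
    protein_ids,
    simulate_cohort,
    simulate_survival,
)
from .types import SpectrumRun


def reference_design(seed: int, n_proteins: int = 200, n_planted: int = 20) -> CohortDesign:
    """The reference planted-truth cohort design used by the experiments."""
    rng = np.random.default_rng(seed)
    spec = planted_fold_change_spec(
        protein_ids(n_proteins), CohortDesign().groups, n_planted, rng
    )
    return CohortDesign(
        n_proteins=n_proteins,
        peptides_per_protein=(5, 5),
        fold_change_spec=spec,
        noise_cv=0.15,
        outlier_fraction=0.01,
        seed=seed,
    )


def _default_config(design: CohortDesign, runs: list[SpectrumRun], seed: int) -> PipelineConfig:
    return PipelineConfig(
        group_map={r.run_id: design.group_of_run(r.run_id) for r in runs}, seed=seed
    )


@dataclass
class RecoveryResult:
    sensitivity: float
    fdp: float
    n_missing_cells: int
    n_proteins: int
    mean_cv_percent: float


def altered_recovery(seed: int, n_proteins: int = 200, n_planted: int = 20) -> RecoveryResult:
    """Run the full pipeline on one planted cohort; score the altered set."""
    design = reference_design(seed, n_proteins=n_proteins, n_planted=n_planted)
    runs, psm, truth = simulate_cohort(design)
    cfg = _default_config(design, runs, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(runs, psm, cfg)
    called = set(res.differential.index[res.differential["altered"]])
    tp = len(called & truth.true_altered)
    fp = len(called - truth.true_altered)
    pm = res.protein_matrix
    return RecoveryResult(
        sensitivity=tp / len(truth.true_altered),
        fdp=fp / max(len(called), 1),
        n_missing_cells=int(pm.data.isna().sum().sum()),
        n_proteins=int(pm.data.shape[0]),
        mean_cv_percent=float(intragroup_cv(pm).mean()),
    )


def altered_recovery_experiment(
    n_seeds: int = 50, seed0: int = 1000, n_proteins: int = 200, n_planted: int = 20
) -> pd.DataFrame:
    """Average altered-set recovery over ``n_seeds`` independent cohorts."""
    rows = [
        altered_recovery(seed0 + s, n_proteins=n_proteins, n_planted=n_planted)
        for s in range(n_seeds)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def bias_recovery(seed: int, n_proteins: int = 60, noise_cv: float = 0.1) -> float:
    """Pearson r between injected per-run log biases and recovered log factors."""
    design = CohortDesign(
        n_proteins=n_proteins,
        peptides_per_protein=(5, 5),
        noise_cv=noise_cv,
        outlier_fraction=0.0,
        seed=seed,
    )
    runs, psm, truth = simulate_cohort(design)
    cfg = _default_config(design, runs, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(runs, psm, cfg)
    factors = res.normalization_factors
    bias = pd.Series(truth.bias).reindex(factors.index)
    return float(np.corrcoef(np.log(factors.to_numpy()), np.log(bias.to_numpy()))[0, 1])


def warp_shift_recovery(
    seed: int,
    slope: float = 1.02,
    offset_s: float = 10.0,
    n_proteins: int = 60,
) -> float:
    """Max |RT recovery error| (s) over the central 80% of the gradient.

    Two runs share a noise-free cohort; one carries the injected linear
    drift ``rt' = slope * rt + offset``.  The estimated warp is evaluated at
    the drifted positions of a grid of true reference times; the error is
    the difference from those true times.
    """
    run_ids = CohortDesign().run_ids()
    design = CohortDesign(
        n_proteins=n_proteins,
        peptides_per_protein=(5, 5),
        noise_cv=0.0,
        outlier_fraction=0.0,
        seed=seed,
        rt_drift_spec={
            rid: ((slope, offset_s) if rid == run_ids[1] else (1.0, 0.0)) for rid in run_ids
        },
    )
    runs, _, _ = simulate_cohort(design)
    ref = next(r for r in runs if r.run_id == run_ids[0])
    drifted = next(r for r in runs if r.run_id == run_ids[1])
    warp = _align.estimate_warp(drifted, ref)
    span = design.gradient_length_s
    ts = np.linspace(0.1 * span, 0.9 * span, 81)
    est = np.asarray(warp(slope * ts + offset_s))
    return float(np.abs(est - ts).max())


def anova_null_calibration(seed: int, n_null: int = 1000, n_groups: int = 5, n_rep: int = 4) -> tuple[float, float]:
    """KS test of ANOVA p-value uniformity under the global null.

    Simulates ``n_null`` null proteins (equal group means, log-normal
    measurement noise) and returns ``(KS statistic, KS p-value)`` for the
    one-way ANOVA p-values against Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_null, n_groups, n_rep))
    pvals = f_oneway(*(x[:, g, :] for g in range(n_groups)), axis=1).pvalue
    ks = kstest(pvals, "uniform")
    return float(ks.statistic), float(ks.pvalue)


def logrank_type1_experiment(
    n_seeds: int = 1000, seed0: int = 0, n_subjects: int = 200, alpha: float = 0.05
) -> float:
    """Empirical type-I error of the median-split log-rank screen.

    Cohorts are simulated with ``marker_effect = 0`` (exchangeable arms);
    returns the fraction of seeds rejecting at ``alpha``.
    """
    rejections = 0
    for s in range(n_seeds):
        cohort = simulate_survival(n_subjects, marker_effect=0.0, censor_rate=0.2, seed=seed0 + s)
        res = logrank_median_split(cohort, "marker")
        rejections += res.p < alpha
    return rejections / n_seeds


#: Noiseless archetype z-profiles (NM, P, K, L) for each pattern label.
PATTERN_ARCHETYPES: dict[Pattern, tuple[float, float, float, float]] = {
    Pattern.NON_METASTATIC: (1.5, -0.5, -0.5, -0.5),
    Pattern.METASTATIC: (-1.5, 0.5, 0.5, 0.5),
    Pattern.PRIMARY_SITE: (-0.5, 1.5, -0.5, -0.5),
    Pattern.KIDNEY_LUNG: (-0.8, -0.6, 0.7, 0.7),
    Pattern.KIDNEY: (-0.5, -0.5, 1.5, -0.5),
    Pattern.LUNG: (-0.5, -0.5, -0.5, 1.5),
}


def archetype_accuracy(margin: float = 0.5) -> float:
    """Classification accuracy on the noiseless per-pattern archetypes."""
    correct = sum(
        assign_pattern(np.array(z), margin=margin) is label
        for label, z in PATTERN_ARCHETYPES.items()
    )
    return correct / len(PATTERN_ARCHETYPES)
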
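"""Synthetic LC-MS cohorts and survival cohorts with known ground truth.

The generator emulates a five-group exosome proteomics study design — one
non-tumorigenic control line plus four tumorigenic lines (a non-metastatic
line, a primary-site metastatic line, and kidney- and lung-metastasis
derivatives), four biological replicates each — at the level of centroided
MS1 peak lists plus stochastic DDA MS2 sampling.  Every nuisance parameter
that the downstream pipeline must undo (per-run retention-time drift,
per-run global intensity bias, decoupled "outlier" peptides, missing MS2
identifications) is planted explicitly and recorded in :class:`GroundTruth`
so that recovery can be tested quantitatively.

Peptides elute as Gaussians (sigma 6 s) sampled on a 2 s MS1 cycle; base
intensities are log-normal (mean 20, sd 1.5 on the natural-log scale) so a
cohort spans several orders of magnitude of ion current, as real exosome
datasets do.  One multiplicative log-normal noise factor of coefficient of
variation ``noise_cv`` is applied per peptide-run measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import Ms2Event, Scan, SpectrumRun

DEFAULT_GROUPS = ("control", "nonmet", "primary", "kidney", "lung")

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class CohortDesign:
    """Full specification of a simulated cohort.

    Parameters
    ----------
    groups
        Ordered group labels; the first is the control.  The remaining four
        default to the non-metastatic / primary / kidney / lung tumor lines.
    fold_change_spec
        Mapping ``protein -> {group: true linear fold change vs control}``.
        Missing groups default to 1; the control is always 1.
    rt_drift_spec
        Mapping ``run_id -> (slope, offset_s)``: observed RT =
        slope * reference RT + offset.  ``None`` draws slopes within
        ``1 ± drift_slope_jitter`` and offsets uniform in
        ``± drift_max_offset_s``.
    intensity_bias_spec
        Mapping ``run_id -> multiplicative factor``; ``None`` draws
        log-uniform in ``bias_range``.
    """

    groups: Sequence[str] = DEFAULT_GROUPS
    replicates_per_group: int = 4
    n_proteins: int = 50
    peptides_per_protein: tuple[int, int] = (3, 6)
    fold_change_spec: Mapping[str, Mapping[str, float]] | None = None
    rt_drift_spec: Mapping[str, tuple[float, float]] | None = None
    intensity_bias_spec: Mapping[str, float] | None = None
    ms2_sampling_rate: float = 0.7
    outlier_fraction: float = 0.01
    noise_cv: float = 0.15
    seed: int = 0
    # chromatography / instrument geometry
    gradient_length_s: float = 1200.0
    ms1_cycle_s: float = 2.0
    peak_sigma_s: float = 6.0
    mz_range: tuple[float, float] = (400.0, 1200.0)
    drift_max_offset_s: float = 60.0
    drift_slope_jitter: float = 0.02
    bias_range: tuple[float, float] = (0.5, 2.0)

    def validate(self) -> None:
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2 (ANOVA needs within-group variance)")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        lo, hi = self.peptides_per_protein
        if lo < 2 or hi < lo:
            raise ValueError("peptides_per_protein range must satisfy 2 <= min <= max")
        if not 0.0 < self.ms2_sampling_rate <= 1.0:
            raise ValueError("ms2_sampling_rate must be in (0, 1]")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.fold_change_spec is not None:
            control = self.groups[0]
            for prot, per_group in self.fold_change_spec.items():
                for grp, fc in per_group.items():
                    if fc <= 0:
                        raise ValueError(f"fold change for {prot}/{grp} must be > 0, got {fc}")
                    if grp == control and fc != 1.0:
                        raise ValueError(f"control-group fold change must be 1 (protein {prot})")
        if self.rt_drift_spec is not None:
            for rid, (slope, _) in self.rt_drift_spec.items():
                if slope <= 0:
                    raise ValueError(f"drift slope for run {rid!r} must be > 0 (monotone drift)")
        if self.intensity_bias_spec is not None:
            for rid, b in self.intensity_bias_spec.items():
                if b <= 0:
                    raise ValueError(f"intensity bias for run {rid!r} must be > 0")

    def run_ids(self) -> list[str]:
        return [
            f"{g}_{r + 1}"
            for g in self.groups
            for r in range(self.replicates_per_group)
        ]

    def group_of_run(self, run_id: str) -> str:
        return run_id.rsplit("_", 1)[0]


@dataclass
class GroundTruth:
    """The simulator's record of everything the pipeline must recover."""

    fold_changes: pd.DataFrame  # proteins x groups, linear scale
    outlier_peptides: frozenset[str]
    drift: dict[str, tuple[float, float]]  # run -> (slope, offset)
    bias: dict[str, float]  # run -> multiplicative factor
    true_altered: frozenset[str]
    true_metastasis_specific: frozenset[str]
    peptide_to_protein: dict[str, str] = field(default_factory=dict)


def true_altered_set(
    fold_changes: pd.DataFrame,
    tumor_groups: Sequence[str],
    up: float = 1.5,
    down: float = 0.67,
) -> frozenset[str]:
    """Proteins whose planted tumor-vs-control fold change passes the ratio gate."""
    sub = fold_changes[list(tumor_groups)]
    mask = ((sub > up) | (sub < down)).any(axis=1)
    return frozenset(fold_changes.index[mask])


def true_metastasis_specific_set(
    fold_changes: pd.DataFrame,
    nonmet_group: str,
    metastatic_groups: Sequence[str],
    altered: frozenset[str],
    up: float = 1.5,
    down: float = 0.67,
) -> frozenset[str]:
    """Altered proteins whose planted metastatic/non-metastatic ratio passes the gate."""
    ratios = fold_changes[list(metastatic_groups)].div(fold_changes[nonmet_group], axis=0)
    mask = ((ratios > up) | (ratios < down)).any(axis=1)
    return frozenset(fold_changes.index[mask]) & altered


def planted_fold_change_spec(
    protein_ids: Sequence[str],
    groups: Sequence[str],
    n_altered: int,
    rng: np.random.Generator,
    log2fc_range: tuple[float, float] = (1.0, 2.0),
) -> dict[str, dict[str, float]]:
    """Plant ``n_altered`` proteins with |log2 FC| in ``log2fc_range``.

    Each planted protein gets a random non-empty subset of the tumor groups,
    a shared sign, and per-group magnitudes drawn independently; the rest of
    the matrix stays at 1.
    """
    tumor = list(groups[1:])
    chosen = rng.choice(len(protein_ids), size=n_altered, replace=False)
    spec: dict[str, dict[str, float]] = {}
    for idx in chosen:
        k = int(rng.integers(1, len(tumor) + 1))
        which = rng.choice(len(tumor), size=k, replace=False)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        per_group = {}
        for gi in which:
            mag = rng.uniform(*log2fc_range)
            per_group[tumor[gi]] = float(2.0 ** (sign * mag))
        spec[protein_ids[idx]] = per_group
    return spec


def protein_ids(n: int) -> list[str]:
    return [f"PROT{i + 1:04d}" for i in range(n)]


def _random_peptide(rng: np.random.Generator, length: int = 10) -> str:
    return "".join(rng.choice(_AMINO, size=length))


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[SpectrumRun], pd.DataFrame, GroundTruth]:
    """Simulate a full LC-MS cohort.

    Returns the runs (in their native, drifted timescale), the PSM table of
    stochastically sampled identifications, and the :class:`GroundTruth`.
    Bit-identical output for identical designs (including the seed).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    groups = list(design.groups)
    control = groups[0]
    run_ids = design.run_ids()
    n_runs = len(run_ids)

    # --- peptide catalogue -------------------------------------------------
    prots = protein_ids(design.n_proteins)
    lo, hi = design.peptides_per_protein
    pep_counts = rng.integers(lo, hi + 1, size=design.n_proteins)
    peptides: list[str] = []
    pep_protein: list[str] = []
    seen: set[str] = set()
    for prot, k in zip(prots, pep_counts):
        for _ in range(int(k)):
            pep = _random_peptide(rng)
            while pep in seen:  # vanishingly rare at 20^10
                pep = _random_peptide(rng)
            seen.add(pep)
            peptides.append(pep)
            pep_protein.append(prot)
    n_pep = len(peptides)
    pep_protein_arr = np.array(pep_protein)

    charge = rng.choice([2, 3], size=n_pep, p=[0.7, 0.3])
    mz = rng.uniform(*design.mz_range, size=n_pep)
    margin = 4 * design.peak_sigma_s + 10.0
    rt_ref = rng.uniform(margin, design.gradient_length_s - margin, size=n_pep)
    base = rng.lognormal(mean=20.0, sigma=1.5, size=n_pep)

    # --- true fold-change matrix (proteins x groups) -----------------------
    fc = pd.DataFrame(1.0, index=prots, columns=groups)
    if design.fold_change_spec is not None:
        for prot, per_group in design.fold_change_spec.items():
            for grp, val in per_group.items():
                if grp not in fc.columns:
                    raise ValueError(f"fold_change_spec references unknown group {grp!r}")
                fc.loc[prot, grp] = val
    fc[control] = 1.0

    # peptide-level group profile: protein profile, except planted outliers
    pep_fc = fc.loc[pep_protein_arr, :].to_numpy()  # n_pep x n_groups
    n_outliers = int(round(design.outlier_fraction * n_pep))
    outlier_idx = (
        rng.choice(n_pep, size=n_outliers, replace=False) if n_outliers else np.array([], dtype=int)
    )
    for i in outlier_idx:
        profile = 2.0 ** rng.uniform(-2.0, 2.0, size=len(groups))
        profile[0] = 1.0
        pep_fc[i] = profile
    outlier_peptides = frozenset(peptides[i] for i in outlier_idx)

    # --- per-run nuisance parameters --------------------------------------
    if design.rt_drift_spec is not None:
        drift = {rid: tuple(map(float, design.rt_drift_spec[rid])) for rid in run_ids}
    else:
        drift = {}
        for rid in run_ids:
            slope = 1.0 + rng.uniform(-design.drift_slope_jitter, design.drift_slope_jitter)
            offset = rng.uniform(-design.drift_max_offset_s, design.drift_max_offset_s)
            drift[rid] = (float(slope), float(offset))
    if design.intensity_bias_spec is not None:
        bias = {rid: float(design.intensity_bias_spec[rid]) for rid in run_ids}
    else:
        lb, ub = np.log(design.bias_range[0]), np.log(design.bias_range[1])
        bias = {rid: float(np.exp(rng.uniform(lb, ub))) for rid in run_ids}

    # measurement noise and MS2 sampling, drawn run-major for determinism
    noise = _lognormal_noise(rng, design.noise_cv, n_runs * n_pep).reshape(n_runs, n_pep)
    sampled = rng.random((n_runs, n_pep)) < design.ms2_sampling_rate

    # --- assemble runs -----------------------------------------------------
    grid = np.arange(0.0, design.gradient_length_s + 1e-9, design.ms1_cycle_s)
    n_scan = grid.size
    sigma = design.peak_sigma_s
    half_support = 3.5 * sigma
    group_index = {g: j for j, g in enumerate(groups)}

    runs: list[SpectrumRun] = []
    psm_rows: list[tuple] = []
    psm_counter = 0
    for r, rid in enumerate(run_ids):
        gj = group_index[design.group_of_run(rid)]
        slope, offset = drift[rid]
        apex = slope * rt_ref + offset
        amp = base * pep_fc[:, gj] * bias[rid] * noise[r]

        lo_idx = np.searchsorted(grid, apex - half_support, side="left")
        hi_idx = np.searchsorted(grid, apex + half_support, side="right")
        chunks_scan, chunks_mz, chunks_int = [], [], []
        apex_scan = np.clip(np.round(apex / design.ms1_cycle_s).astype(int), 0, n_scan - 1)
        for p in range(n_pep):
            a, b = lo_idx[p], hi_idx[p]
            if b <= a:
                continue
            t = grid[a:b]
            inten = amp[p] * np.exp(-0.5 * ((t - apex[p]) / sigma) ** 2)
            chunks_scan.append(np.arange(a, b))
            chunks_mz.append(np.full(b - a, mz[p]))
            chunks_int.append(inten)
        scan_idx = np.concatenate(chunks_scan) if chunks_scan else np.array([], dtype=int)
        mz_all = np.concatenate(chunks_mz) if chunks_mz else np.array([])
        int_all = np.concatenate(chunks_int) if chunks_int else np.array([])
        order = np.lexsort((mz_all, scan_idx))
        scan_idx, mz_all, int_all = scan_idx[order], mz_all[order], int_all[order]
        bounds = np.searchsorted(scan_idx, np.arange(n_scan + 1))

        scans = [
            Scan(f"{rid}:MS1:{k:05d}", float(grid[k]), mz_all[bounds[k]:bounds[k + 1]], int_all[bounds[k]:bounds[k + 1]])
            for k in range(n_scan)
        ]

        ms2_events: list[Ms2Event] = []
        for p in np.flatnonzero(sampled[r]):
            k = apex_scan[p]
            ms2_id = f"{rid}:MS2:{p:05d}"
            apex_int = amp[p] * math.exp(-0.5 * ((grid[k] - apex[p]) / sigma) ** 2)
            ms2_events.append(
                Ms2Event(
                    scan_id=ms2_id,
                    rt=float(grid[k]) + 0.4 * design.ms1_cycle_s,
                    precursor_mz=float(mz[p]),
                    precursor_intensity=float(apex_int),
                    precursor_scan_id=scans[k].scan_id,
                )
            )
            psm_rows.append(
                (
                    f"PSM{psm_counter:07d}",
                    rid,
                    ms2_id,
                    peptides[p],
                    int(charge[p]),
                    pep_protein[p],
                    True,
                )
            )
            psm_counter += 1
        runs.append(SpectrumRun(rid, scans, ms2_events))

    psm_table = pd.DataFrame(
        psm_rows,
        columns=["psm_id", "run_id", "ms2_scan_id", "peptide", "charge", "protein_accession", "is_unique"],
    )

    tumor = groups[1:]
    altered = true_altered_set(fc, tumor)
    met_specific = true_metastasis_specific_set(fc, tumor[0], tumor[1:], altered)
    truth = GroundTruth(
        fold_changes=fc,
        outlier_peptides=outlier_peptides,
        drift=drift,
        bias=bias,
        true_altered=altered,
        true_metastasis_specific=met_specific,
        peptide_to_protein=dict(zip(peptides, pep_protein)),
    )
    return runs, psm_table, truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------


def simulate_survival(
    n_subjects: int,
    marker_effect: float,
    censor_rate: float,
    seed: int,
    gene: str = "marker",
    median_months: float = 60.0,
) -> pd.DataFrame:
    """Simulate an overall-survival cohort tied to one marker gene.

    Survival times are exponential with per-subject rate
    ``lambda_i = lambda_0 * exp(marker_effect * z_i)`` where ``z_i`` is the
    standard-normal expression of the marker; ``lambda_0`` is set so the
    baseline median survival is ``median_months``.  Censoring is uniform
    over a follow-up horizon chosen so the expected censored fraction under
    the baseline hazard equals ``censor_rate``; ``censor_rate = 0`` means
    every subject has an observed event.

    Returns a DataFrame with columns ``subject``, ``time_months``, ``event``
    and ``expr_<gene>``.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_subjects)
    lam0 = math.log(2.0) / median_months
    lam = lam0 * np.exp(marker_effect * z)
    t_event = rng.exponential(1.0 / lam)

    if censor_rate == 0.0:
        time, event = t_event, np.ones(n_subjects, dtype=int)
    else:
        # P(censored) for C ~ U(0, F), T ~ Exp(lam0): (1 - exp(-lam0 F)) / (lam0 F)
        def pc(f: float) -> float:
            return (1.0 - math.exp(-lam0 * f)) / (lam0 * f) - censor_rate

        horizon = brentq(pc, 1e-6, 1e7)
        c = rng.uniform(0.0, horizon, size=n_subjects)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {
            "subject": [f"S{i + 1:04d}" for i in range(n_subjects)],
            "time_months": time,
            "event": event,
            f"expr_{gene}": z,
        }
    )


def simulate_survival_cohort(
    n_subjects: int,
    marker_effects: Mapping[str, float],
    censor_rate: float,
    seed: int,
    median_months: float = 60.0,
) -> pd.DataFrame:
    """Multi-gene survival cohort: independent expression per gene, hazard
    driven by the sum of per-gene log-linear effects."""
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    rng = np.random.default_rng(seed)
    genes = list(marker_effects)
    z = rng.standard_normal((n_subjects, len(genes)))
    eta = z @ np.array([marker_effects[g] for g in genes])
    lam0 = math.log(2.0) / median_months
    lam = lam0 * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    if censor_rate == 0.0:
        time, event = t_event, np.ones(n_subjects, dtype=int)
    else:
        def pc(f: float) -> float:
            return (1.0 - math.exp(-lam0 * f)) / (lam0 * f) - censor_rate

        horizon = brentq(pc, 1e-6, 1e7)
        c = rng.uniform(0.0, horizon, size=n_subjects)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    out = pd.DataFrame({"subject": [f"S{i + 1:04d}" for i in range(n_subjects)],
                        "time_months": np.maximum(time, 1e-6), "event": event})
    for j, g in enumerate(genes):
        out[f"expr_{g}"] = z[:, j]
    return out
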
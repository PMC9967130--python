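"""Normalization, PC-based peptide outlier removal, protein roll-up."""

import numpy as np
import pandas as pd
import pytest

from ionframe.frames import build_frame_targets, extract_frames
from ionframe.quant import (
    aggregate_protein,
    annotate_frames,
    detect_peptide_outliers,
    flag_outliers,
    normalize,
    peptide_matrix,
    quantify,
)
from ionframe.synthdata import CohortDesign, simulate_cohort
from ionframe.differential import compare_ratios


def _frame_matrix(values, runs=None):
    values = np.asarray(values, dtype=float)
    runs = runs or [f"r{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])], columns=runs)


# --- normalization ---------------------------------------------------------


def test_identical_runs_get_unit_factors():
    m = _frame_matrix(np.tile([[10.0], [20.0], [400.0]], (1, 3)))
    with pytest.warns(UserWarning, match="frames"):
        normalized, factors = normalize(m)
    np.testing.assert_allclose(factors, 1.0, atol=1e-12)
    pd.testing.assert_frame_equal(normalized, m)


def test_doubled_run_split_factors_closed_form():
    rng = np.random.default_rng(1)
    a = rng.lognormal(10, 1, size=50)
    m = _frame_matrix(np.column_stack([a, 2 * a]), runs=["A", "B"])
    normalized, factors = normalize(m)
    assert factors["A"] == pytest.approx(2 ** -0.5, rel=1e-12)
    assert factors["B"] == pytest.approx(2 ** 0.5, rel=1e-12)
    np.testing.assert_allclose(normalized["A"], normalized["B"], rtol=1e-12)


def test_normalization_is_idempotent():
    rng = np.random.default_rng(2)
    m = _frame_matrix(rng.lognormal(10, 1, size=(80, 5)) * rng.uniform(0.5, 2, size=5))
    normalized, _ = normalize(m)
    _, factors2 = normalize(normalized)
    np.testing.assert_allclose(factors2, 1.0, atol=1e-9)


def test_scale_equivariance_single_run():
    rng = np.random.default_rng(3)
    base = rng.lognormal(10, 1, size=(60, 4))
    m1 = _frame_matrix(base.copy())
    scaled = base.copy()
    scaled[:, 2] *= 3.0
    m2 = _frame_matrix(scaled)
    _, f1 = normalize(m1)
    _, f2 = normalize(m2)
    # only run r2's factor changes, by 3 up to the global geometric recentering
    correction = (f2 / f1).to_numpy()
    assert correction[2] / correction[0] == pytest.approx(3.0, rel=1e-9)
    assert correction[0] == pytest.approx(correction[1], rel=1e-9)
    assert correction[0] == pytest.approx(correction[3], rel=1e-9)


def test_all_zero_run_is_a_named_error():
    m = _frame_matrix(np.ones((20, 3)))
    m["r1"] = 0.0
    with pytest.raises(ValueError, match="r1"):
        normalize(m)


def test_injected_bias_recovered():
    from ionframe.experiments import bias_recovery

    assert bias_recovery(seed=17) >= 0.99


# --- outlier detection -----------------------------------------------------


def _protein_block(profiles, n_samples=8, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x = np.asarray(profiles, dtype=float)
    if noise:
        x = x + rng.normal(0, noise, size=x.shape)
    return pd.DataFrame(x, index=[f"pep{i}" for i in range(x.shape[0])])


def test_parallel_profiles_are_never_flagged():
    base = np.linspace(10, 12, 8)
    block = _protein_block([base + c for c in (0.0, 1.0, -2.0, 0.5)])
    assert not detect_peptide_outliers(block).any()


def test_two_peptide_proteins_are_guarded():
    block = _protein_block([np.zeros(8), np.linspace(-3, 3, 8)])
    assert not detect_peptide_outliers(block).any()
    with pytest.raises(ValueError):
        detect_peptide_outliers(block.iloc[:1])


def test_at_least_two_peptides_survive():
    rng = np.random.default_rng(5)
    block = _protein_block(rng.normal(size=(4, 8)) * 5)
    flags = detect_peptide_outliers(block)
    assert (~flags).sum() >= 2


def test_injected_anticorrelated_outlier_is_flagged():
    """5 concordant peptides + 1 anti-correlated: the injected peptide is
    the one flagged in >= 95% of 200 seeds."""
    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        shape = rng.normal(0, 1, size=8)
        profiles = [shape + rng.normal(0, 0.15, size=8) for _ in range(5)]
        profiles.append(-shape + rng.normal(0, 0.15, size=8))
        flags = detect_peptide_outliers(_protein_block(profiles))
        if flags.iloc[5] and flags.iloc[:5].sum() == 0:
            hits += 1
    assert hits / n_seeds >= 0.95


def test_false_flag_rate_on_clean_proteins_below_five_percent():
    flagged = total = 0
    for seed in range(200):
        rng = np.random.default_rng(10_000 + seed)
        shape = rng.normal(0, 1, size=8)
        profiles = [shape + rng.normal(0, 0.2, size=8) for _ in range(5)]
        flags = detect_peptide_outliers(_protein_block(profiles))
        flagged += int(flags.sum())
        total += 5
    assert flagged / total <= 0.05


# --- aggregation -----------------------------------------------------------


def _mini_annotated():
    runs = ["s1", "s2"]
    rows = [
        ("f0", "AAA", 2, "P1", True, 10.0, 11.0),
        ("f1", "BBB", 2, "P1", True, 20.0, 19.0),
        ("f2", "CCC", 2, "P2", True, 5.0, 5.0),
        ("f3", "DDD", 2, "P2", True, 7.0, 7.0),
        ("f4", "EEE", 2, "P3", False, 9.0, 9.0),  # shared peptide
        ("f5", "FFF", 2, "P3", True, 3.0, 3.0),
    ]
    df = pd.DataFrame(
        rows, columns=["frame_id", "peptide", "charge", "protein_accession", "is_unique", "s1", "s2"]
    ).set_index("frame_id")
    return df, runs


def test_rollup_sums_peptides_and_enforces_two_peptide_rule():
    ann, runs = _mini_annotated()
    pep = peptide_matrix(ann, runs)
    flags = pd.Series(False, index=pep.index)
    # P3 has one unique peptide only -> dropped; P1, P2 remain
    pm = aggregate_protein(pep, flags, pd.Series({"s1": "g1", "s2": "g1"}))
    assert list(pm.proteins) == ["P1", "P2"]
    assert pm.data.loc["P1", "s1"] == pytest.approx(30.0)
    assert pm.data.loc["P2", "s2"] == pytest.approx(12.0)


def test_protein_dropped_when_outliers_leave_one_peptide():
    ann, runs = _mini_annotated()
    pep = peptide_matrix(ann, runs)
    flags = pd.Series(False, index=pep.index)
    flags.loc[("P2", "CCC")] = True
    pm = aggregate_protein(pep, flags, pd.Series({"s1": "g1", "s2": "g1"}))
    assert list(pm.proteins) == ["P1"]


def test_zero_cells_are_floored_positive():
    ann, runs = _mini_annotated()
    ann.loc["f2", "s1"] = 0.0
    pep = peptide_matrix(ann, runs)
    pm = aggregate_protein(pep, pd.Series(False, index=pep.index), pd.Series({"s1": "g", "s2": "g"}))
    assert (pm.data.to_numpy() > 0).all()


# --- annotation ------------------------------------------------------------


def test_annotation_joins_every_frame(small_cohort):
    runs, psm, _ = small_cohort
    targets = build_frame_targets(psm, runs)
    areas, _ = extract_frames(runs, targets)
    ann = annotate_frames(targets, areas, psm)
    assert len(ann) == len(targets)
    # exhaustive join oracle: frame -> peptide -> accession via the PSM table
    lookup = psm.drop_duplicates("peptide").set_index("peptide")["protein_accession"]
    for t in targets:
        assert ann.loc[t.frame_id, "protein_accession"] == lookup[t.peptide]
        assert ann.loc[t.frame_id, "peptide"] == t.peptide


def test_shared_peptides_are_flagged_and_excluded():
    runs_cols = ["s1", "s2"]
    psm = pd.DataFrame(
        [
            {"psm_id": "1", "run_id": "s1", "ms2_scan_id": "a", "peptide": "AAA",
             "charge": 2, "protein_accession": "P1", "is_unique": True},
            {"psm_id": "2", "run_id": "s1", "ms2_scan_id": "b", "peptide": "SHARED",
             "charge": 2, "protein_accession": "P1", "is_unique": False},
            {"psm_id": "3", "run_id": "s2", "ms2_scan_id": "c", "peptide": "SHARED",
             "charge": 2, "protein_accession": "P2", "is_unique": False},
        ]
    )
    from ionframe.frames import FrameTarget

    targets = [
        FrameTarget("f0", "AAA", 2, 500.0, 100.0),
        FrameTarget("f1", "SHARED", 2, 600.0, 100.0),
    ]
    areas = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["f0", "f1"], columns=runs_cols)
    areas.index.name = "frame_id"
    ann = annotate_frames(targets, areas, psm)
    assert not ann.loc["f1", "is_unique"]
    assert ann.loc["f0", "is_unique"]
    with pytest.raises(ValueError, match="unique"):
        peptide_matrix(ann[ann["peptide"] == "SHARED"], runs_cols)


# --- end-to-end identity ---------------------------------------------------


def test_noise_free_pipeline_recovers_exact_fold_changes(clean_cohort, clean_design):
    """Noise-free, bias-free simulation: protein-level ratios equal the
    planted fold changes to floating-point accuracy."""
    runs, psm, truth = clean_cohort
    targets = build_frame_targets(psm, runs)
    areas, _ = extract_frames(runs, targets)
    ann = annotate_frames(targets, areas, psm)
    run_ids = [r.run_id for r in runs]
    groups = pd.Series({rid: clean_design.group_of_run(rid) for rid in run_ids})
    pm, factors, flags = quantify(ann, run_ids, groups)
    np.testing.assert_allclose(factors, 1.0, atol=1e-9)
    assert not flags.any()
    ratios = compare_ratios(pm, "control", ["nonmet", "primary", "kidney", "lung"])
    for prot in pm.proteins:
        for g in ("nonmet", "primary", "kidney", "lung"):
            assert ratios.loc[prot, f"{g}/control"] == pytest.approx(
                truth.fold_changes.loc[prot, g], rel=1e-9
            )
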
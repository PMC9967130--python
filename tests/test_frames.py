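"""Frame targets and ion-current extraction against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_run
from ionframe.frames import (
    FrameTarget,
    build_frame_targets,
    extract_frame,
    extract_frames,
)
from ionframe.synthdata import CohortDesign, simulate_cohort
from ionframe.types import Ms2Event


def _psm_row(i, run_id, scan_id, peptide="PEPTIDEK", charge=2, protein="P1", unique=True):
    return {
        "psm_id": f"psm{i}",
        "run_id": run_id,
        "ms2_scan_id": scan_id,
        "peptide": peptide,
        "charge": charge,
        "protein_accession": protein,
        "is_unique": unique,
    }


def _run_with_events(run_id, events):
    run = make_run(run_id, [100.0, 102.0], {0: [(500.0, 10.0)], 1: [(500.0, 10.0)]})
    run.ms2_events = events
    return run


def test_close_psms_merge_into_one_target():
    mz = 500.0
    mz2 = mz * (1 + 2e-6)  # 2 ppm away
    r1 = _run_with_events("r1", [Ms2Event("s1", 100.0, mz, 5.0, "m1")])
    r2 = _run_with_events("r2", [Ms2Event("s2", 110.0, mz2, 5.0, "m1")])
    psm = pd.DataFrame([_psm_row(1, "r1", "s1"), _psm_row(2, "r2", "s2")])
    targets = build_frame_targets(psm, [r1, r2])
    assert len(targets) == 1
    assert targets[0].ms2_scan_ids == {"r1": ["s1"], "r2": ["s2"]}


def test_distant_rt_psms_stay_separate_targets():
    r1 = _run_with_events("r1", [Ms2Event("s1", 100.0, 500.0, 5.0, "m1")])
    r2 = _run_with_events("r2", [Ms2Event("s2", 220.0, 500.0, 5.0, "m1")])
    psm = pd.DataFrame([_psm_row(1, "r1", "s1"), _psm_row(2, "r2", "s2")])
    assert len(build_frame_targets(psm, [r1, r2])) == 2


def test_unresolvable_scan_id_names_the_psm():
    r1 = _run_with_events("r1", [])
    psm = pd.DataFrame([_psm_row(7, "r1", "missing_scan")])
    with pytest.raises(ValueError, match="psm7"):
        build_frame_targets(psm, [r1])


def _oracle_single_linkage(events, ppm, rt_win):
    """Exhaustive single-linkage clustering oracle (repeat-merge to fixpoint)."""
    clusters = [[e] for e in events]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                link = any(
                    abs(a[1] - b[1]) <= rt_win
                    and abs(a[0] - b[0]) / ((a[0] + b[0]) / 2) * 1e6 <= ppm
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if link:
                    clusters[i] += clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return len(clusters)


def test_target_count_matches_clustering_oracle():
    design = CohortDesign(
        n_proteins=15, peptides_per_protein=(3, 3), ms2_sampling_rate=0.6,
        gradient_length_s=400.0, seed=9,
    )
    runs, psm, _ = simulate_cohort(design)
    targets = build_frame_targets(psm, runs)
    # oracle: cluster per (peptide, charge) over resolved events
    ev = {}
    for r in runs:
        for e in r.ms2_events:
            ev[(r.run_id, e.scan_id)] = (e.precursor_mz, e.rt)
    n_oracle = 0
    for (pep, z), grp in psm.groupby(["peptide", "charge"]):
        events = [ev[(r.run_id, sid)] for r, sid in zip(
            [next(rr for rr in runs if rr.run_id == rid) for rid in grp["run_id"]],
            grp["ms2_scan_id"],
        )]
        n_oracle += _oracle_single_linkage(events, 10.0, 60.0)
    assert len(targets) == n_oracle
    # every PSM maps to exactly one target
    all_psms = [p for t in targets for p in t.psm_ids]
    assert sorted(all_psms) == sorted(psm["psm_id"])


def test_empty_window_yields_zero_area():
    run = make_run("r", [100.0, 102.0, 104.0], {i: [] for i in range(3)})
    t = FrameTarget("f", "PEP", 2, 500.0, 102.0)
    area, apex = extract_frame(run, t)
    assert area == 0.0
    assert np.isnan(apex)


def test_single_scan_window_uses_cycle_time_rule():
    run = make_run("r", [10.0, 100.0, 190.0], {1: [(500.0, 1000.0)]})
    t = FrameTarget("f", "PEP", 2, 500.0, 100.0, rt_window_s=60.0)
    area, apex = extract_frame(run, t)
    assert area == pytest.approx(1000.0 * 90.0)  # cycle time = 90 s here
    assert apex == 100.0


def _brute_force_area(run, target):
    """Independent loop over every peak of every scan."""
    half_rt = target.rt_window_s / 2
    dm = target.mz_center * target.ppm * 1e-6
    rts, vals = [], []
    for scan in run.scans:
        if abs(scan.rt - target.rt_center) <= half_rt:
            best = 0.0
            for mz, inten in zip(scan.mz, scan.intensity):
                if abs(mz - target.mz_center) <= dm and inten > best:
                    best = inten
            rts.append(scan.rt)
            vals.append(best)
    if len(rts) < 2:
        return vals[0] * run.cycle_time() if rts else 0.0
    return float(np.trapezoid(vals, rts))


def test_gaussian_peak_area_matches_bruteforce(small_cohort):
    runs, psm, _ = small_cohort
    targets = build_frame_targets(psm, runs)[:25]
    areas, _ = extract_frames(runs[:4], targets)
    for run in runs[:4]:
        for t in targets:
            expected = _brute_force_area(run, t)
            got = areas.loc[t.frame_id, run.run_id]
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)


def test_area_invariant_to_peak_permutation_within_scans(small_cohort):
    runs, psm, _ = small_cohort
    run = runs[0]
    targets = build_frame_targets(psm, runs)[:10]
    shuffled = run.copy()
    rng = np.random.default_rng(0)
    for s in shuffled.scans:
        perm = rng.permutation(s.mz.size)
        s.mz, s.intensity = s.mz[perm], s.intensity[perm]
    for t in targets:
        assert extract_frame(run, t) == extract_frame(shuffled, t)


def test_doubling_intensities_doubles_areas(small_cohort):
    runs, psm, _ = small_cohort
    run = runs[0]
    targets = build_frame_targets(psm, runs)[:10]
    doubled = run.copy()
    for s in doubled.scans:
        s.intensity = s.intensity * 2.0
    for t in targets:
        a1, _ = extract_frame(run, t)
        a2, _ = extract_frame(doubled, t)
        assert a2 == pytest.approx(2.0 * a1, rel=1e-12)


def test_noise_free_area_ratio_equals_fc_times_bias():
    """Pre-normalization, the area ratio between runs equals the injected
    fold change x bias ratio exactly (noise-free regime)."""
    ids = CohortDesign().run_ids()
    design = CohortDesign(
        n_proteins=6, peptides_per_protein=(2, 2),
        fold_change_spec={"PROT0002": {"primary": 2.0}},
        noise_cv=0.0, outlier_fraction=0.0, ms2_sampling_rate=1.0,
        rt_drift_spec={rid: (1.0, 0.0) for rid in ids},
        intensity_bias_spec={rid: (1.5 if rid.startswith("primary") else 1.0) for rid in ids},
        gradient_length_s=400.0, seed=4,
    )
    runs, psm, truth = simulate_cohort(design)
    targets = build_frame_targets(psm, runs)
    areas, _ = extract_frames(runs, targets)
    pep2prot = truth.peptide_to_protein
    for t in targets:
        fc = truth.fold_changes.loc[pep2prot[t.peptide], "primary"]
        ratio = areas.loc[t.frame_id, "primary_1"] / areas.loc[t.frame_id, "control_1"]
        assert ratio == pytest.approx(fc * 1.5, rel=1e-9)


def test_every_frame_run_pair_has_an_area(small_cohort):
    runs, psm, _ = small_cohort
    targets = build_frame_targets(psm, runs)
    areas, apex = extract_frames(runs, targets)
    assert areas.shape == (len(targets), len(runs))
    assert not areas.isna().any().any()
    assert (areas.to_numpy() >= 0).all()
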
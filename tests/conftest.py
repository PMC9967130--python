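import numpy as np
import pandas as pd
import pytest

from ionframe.synthdata import CohortDesign, simulate_cohort
from ionframe.types import Ms2Event, Scan, SpectrumRun


def make_run(run_id, scan_rts, peaks, ms2=()):
    """Build a small run; ``peaks`` maps scan index -> list of (mz, intensity)."""
    scans = []
    for i, rt in enumerate(scan_rts):
        plist = peaks.get(i, [])
        mz = np.array([p[0] for p in plist], dtype=float)
        inten = np.array([p[1] for p in plist], dtype=float)
        scans.append(Scan(f"{run_id}:MS1:{i:04d}", float(rt), mz, inten))
    return SpectrumRun(run_id, scans, list(ms2))


@pytest.fixture(scope="session")
def small_design():
    """A small but complete 5-group x 4-replicate cohort design."""
    return CohortDesign(
        n_proteins=12,
        peptides_per_protein=(3, 5),
        fold_change_spec={
            "PROT0001": {"primary": 2.0},
            "PROT0002": {"nonmet": 0.4, "primary": 0.4, "kidney": 0.4, "lung": 0.4},
            "PROT0003": {"kidney": 3.0, "lung": 3.0},
        },
        noise_cv=0.1,
        ms2_sampling_rate=0.8,
        outlier_fraction=0.0,
        gradient_length_s=600.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def clean_design():
    """Noise-free, bias-free, drift-free design: the exact-identity regime."""
    return CohortDesign(
        n_proteins=8,
        peptides_per_protein=(3, 4),
        fold_change_spec={"PROT0001": {"primary": 2.0}, "PROT0005": {"lung": 0.25}},
        noise_cv=0.0,
        ms2_sampling_rate=1.0,
        outlier_fraction=0.0,
        rt_drift_spec={rid: (1.0, 0.0) for rid in CohortDesign().run_ids()},
        intensity_bias_spec={rid: 1.0 for rid in CohortDesign().run_ids()},
        gradient_length_s=600.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_design):
    return simulate_cohort(clean_design)


def area_by_mz_oracle(run):
    """Brute-force integrated area per distinct m/z value in a run.

    The simulator emits exact per-peptide m/z values, so the trapezoidal
    integral of the per-scan max trace at each m/z is an independent area
    oracle keyed by (rounded) m/z.
    """
    rts = run.scan_rts()
    by_mz = {}
    for k, scan in enumerate(run.scans):
        for mz, inten in zip(scan.mz, scan.intensity):
            key = round(float(mz), 9)
            trace = by_mz.setdefault(key, np.zeros(len(run.scans)))
            trace[k] = max(trace[k], inten)
    return {mz: float(np.trapezoid(trace, rts)) for mz, trace in by_mz.items()}
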
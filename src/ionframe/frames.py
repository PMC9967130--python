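"""MS1 frame generation and ion-current extraction — the quantitative core.

A *frame* is an m/z-RT window on the aligned (reference) timescale, seeded
by the MS2 identification events of one peptide+charge.  MS2 events whose
precursor m/z agree within the ppm tolerance and whose aligned RTs agree
within the RT window are merged (single linkage) into one target.  Ion
current is then extracted for every target in **every** run, whether or not
that run produced an identification — this is what removes structural
missingness from the downstream protein matrix.

Per scan inside the RT window the most intense peak within the ppm window
forms the trace (robust to neighboring isotopes drifting in); the area is
the trapezoidal integral of that trace over RT.  A window holding a single
MS1 scan integrates as intensity x MS1 cycle time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SpectrumRun, validate_psm_table

DEFAULT_PPM = 10.0
DEFAULT_RT_WINDOW_S = 60.0


@dataclass
class FrameTarget:
    """One quantification target: an m/z-RT window on the reference timescale."""

    frame_id: str
    peptide: str
    charge: int
    mz_center: float
    rt_center: float
    ppm: float = DEFAULT_PPM
    rt_window_s: float = DEFAULT_RT_WINDOW_S
    ms2_scan_ids: dict[str, list[str]] = field(default_factory=dict)  # run -> scans
    psm_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mz_center <= 0:
            raise ValueError("frame m/z center must be positive")


def _ppm_diff(a: float, b: float) -> float:
    return abs(a - b) / ((a + b) / 2.0) * 1e6


def _single_linkage(mzs: np.ndarray, rts: np.ndarray, ppm: float, rt_window_s: float) -> np.ndarray:
    """Single-linkage clusters under the joint (ppm, RT) merge condition."""
    n = mzs.size
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(rts[i] - rts[j]) <= rt_window_s and _ppm_diff(mzs[i], mzs[j]) <= ppm:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return np.array([find(i) for i in range(n)])


def build_frame_targets(
    psm_table: pd.DataFrame,
    runs: list[SpectrumRun],
    ppm: float = DEFAULT_PPM,
    rt_window_s: float = DEFAULT_RT_WINDOW_S,
) -> list[FrameTarget]:
    """Merge MS2 identification events into frame targets.

    ``runs`` must already be aligned to the reference timescale.  Every PSM
    maps to exactly one target; an MS2 scan id that cannot be resolved in
    its run raises ``ValueError`` naming the PSM row.
    """
    validate_psm_table(psm_table)
    ev_index: dict[tuple[str, str], tuple[float, float, float]] = {}
    for run in runs:
        for ev in run.ms2_events:
            ev_index[(run.run_id, ev.scan_id)] = (ev.precursor_mz, ev.rt, ev.precursor_intensity)

    cols = psm_table[["psm_id", "run_id", "ms2_scan_id", "peptide", "charge"]]
    resolved = []
    for row in cols.itertuples(index=False):
        key = (row.run_id, row.ms2_scan_id)
        if key not in ev_index:
            raise ValueError(
                f"PSM {row.psm_id!r}: MS2 scan {row.ms2_scan_id!r} not found in run {row.run_id!r}"
            )
        mz, rt, inten = ev_index[key]
        resolved.append((row.peptide, int(row.charge), row.run_id, row.ms2_scan_id, row.psm_id, mz, rt, inten))
    df = pd.DataFrame(
        resolved,
        columns=["peptide", "charge", "run_id", "ms2_scan_id", "psm_id", "mz", "rt", "intensity"],
    )

    targets: list[FrameTarget] = []
    counter = 0
    for (pep, z), grp in df.groupby(["peptide", "charge"], sort=True):
        labels = _single_linkage(
            grp["mz"].to_numpy(), grp["rt"].to_numpy(), ppm, rt_window_s
        )
        for lab in np.unique(labels):
            sub = grp.iloc[np.flatnonzero(labels == lab)]
            w = sub["intensity"].to_numpy()
            mzs = sub["mz"].to_numpy()
            center = float(np.average(mzs, weights=w)) if w.sum() > 0 else float(mzs.mean())
            rt_center = float(np.median(sub["rt"].to_numpy()))
            per_run: dict[str, list[str]] = {}
            for rid, sid in zip(sub["run_id"], sub["ms2_scan_id"]):
                per_run.setdefault(rid, []).append(sid)
            targets.append(
                FrameTarget(
                    frame_id=f"F{counter:06d}",
                    peptide=pep,
                    charge=int(z),
                    mz_center=center,
                    rt_center=rt_center,
                    ppm=ppm,
                    rt_window_s=rt_window_s,
                    ms2_scan_ids=per_run,
                    psm_ids=list(sub["psm_id"]),
                )
            )
            counter += 1
    return targets


class _RunIndex:
    """Flat, m/z-sorted peak arrays of one aligned run for fast extraction."""

    def __init__(self, run: SpectrumRun):
        self.run_id = run.run_id
        self.scan_rts = run.scan_rts()
        self.cycle = run.cycle_time()
        sizes = [s.mz.size for s in run.scans]
        if sum(sizes) == 0:
            self.mz = np.array([])
            self.intensity = np.array([])
            self.scan_of_peak = np.array([], dtype=int)
        else:
            mz = np.concatenate([s.mz for s in run.scans])
            inten = np.concatenate([s.intensity for s in run.scans])
            scan_of_peak = np.repeat(np.arange(len(run.scans)), sizes)
            order = np.argsort(mz, kind="stable")
            self.mz = mz[order]
            self.intensity = inten[order]
            self.scan_of_peak = scan_of_peak[order]

    def trace(self, target: FrameTarget) -> tuple[np.ndarray, np.ndarray]:
        """(rt, intensity) trace over MS1 scans inside the target window."""
        half_rt = target.rt_window_s / 2.0
        s_lo = int(np.searchsorted(self.scan_rts, target.rt_center - half_rt, side="left"))
        s_hi = int(np.searchsorted(self.scan_rts, target.rt_center + half_rt, side="right"))
        rts = self.scan_rts[s_lo:s_hi]
        trace = np.zeros(s_hi - s_lo)
        if self.mz.size:
            dm = target.mz_center * target.ppm * 1e-6
            p_lo = int(np.searchsorted(self.mz, target.mz_center - dm, side="left"))
            p_hi = int(np.searchsorted(self.mz, target.mz_center + dm, side="right"))
            scans = self.scan_of_peak[p_lo:p_hi]
            inten = self.intensity[p_lo:p_hi]
            keep = (scans >= s_lo) & (scans < s_hi)
            np.maximum.at(trace, scans[keep] - s_lo, inten[keep])
        return rts, trace


def integrate_trace(rts: np.ndarray, trace: np.ndarray, cycle: float) -> tuple[float, float]:
    """(area, apex RT) of an extracted trace; degenerate cases documented.

    Empty window -> area 0; a single scan cannot support a trapezoid, so its
    area is intensity x cycle time.  Apex RT is the RT of the most intense
    point (nan when the trace is all-zero).
    """
    if rts.size == 0:
        return 0.0, float("nan")
    if rts.size == 1:
        return float(trace[0] * cycle), float(rts[0]) if trace[0] > 0 else float("nan")
    area = float(np.trapezoid(trace, rts))
    if trace.max() <= 0:
        return area, float("nan")
    return area, float(rts[int(np.argmax(trace))])


def extract_frame(run: SpectrumRun, target: FrameTarget) -> tuple[float, float]:
    """Integrated ion-current area and apex RT of one target in one run."""
    idx = _RunIndex(run)
    rts, trace = idx.trace(target)
    return integrate_trace(rts, trace, idx.cycle)


def extract_frames(
    runs: list[SpectrumRun], targets: list[FrameTarget]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract every target in every run.

    Returns ``(areas, apex_rts)``: DataFrames indexed by frame id with one
    column per run.  Structurally complete by construction — every
    (frame, run) cell holds a number (areas may be 0).
    """
    run_ids = [r.run_id for r in runs]
    areas = np.zeros((len(targets), len(runs)))
    apex = np.full((len(targets), len(runs)), np.nan)
    for j, run in enumerate(runs):
        idx = _RunIndex(run)
        for i, tgt in enumerate(targets):
            rts, trace = idx.trace(tgt)
            areas[i, j], apex[i, j] = integrate_trace(rts, trace, idx.cycle)
    frame_ids = [t.frame_id for t in targets]
    area_df = pd.DataFrame(areas, index=pd.Index(frame_ids, name="frame_id"), columns=run_ids)
    apex_df = pd.DataFrame(apex, index=area_df.index.copy(), columns=run_ids)
    assert not area_df.isna().any().any(), "frame areas must be structurally complete"
    return area_df, apex_df


def targets_table(targets: list[FrameTarget]) -> pd.DataFrame:
    """Flat table view of frame targets (for serialization and reports)."""
    return pd.DataFrame(
        {
            "frame_id": [t.frame_id for t in targets],
            "peptide": [t.peptide for t in targets],
            "charge": [t.charge for t in targets],
            "mz_center": [t.mz_center for t in targets],
            "rt_center": [t.rt_center for t in targets],
        }
    ).set_index("frame_id")
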
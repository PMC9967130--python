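"""Retention-time alignment onto a common reference timescale.

Runs are aligned pairwise against a reference run chosen from the cohort.
The warp for each run is estimated by dynamic time warping (DTW) of
base-peak chromatograms (BPCs) binned at 5 s, constrained to a Sakoe-Chiba
band of +/-120 s, and then condensed into a monotone piecewise-linear map
through anchors spaced every 60 s.  The alignment score of a warp is the
Pearson correlation of the warped, binned (log-compressed) BPCs, a bounded
quantity comparable across run pairs; reference selection combines the
rank of each candidate's mean pairwise score with the rank of its total
BPC intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, rankdata

from .types import SpectrumRun


@dataclass
class BasePeakChromatogram:
    """Per-MS1-scan maximum peak intensity versus retention time."""

    run_id: str
    rt: np.ndarray
    intensity: np.ndarray

    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class WarpFunction:
    """Monotone piecewise-linear map from run RT to reference RT (seconds)."""

    run_id: str
    anchors_from: np.ndarray  # run timescale, strictly increasing
    anchors_to: np.ndarray  # reference timescale, strictly increasing
    score: float = 1.0
    is_identity: bool = False

    def __post_init__(self) -> None:
        self.anchors_from = np.asarray(self.anchors_from, dtype=float)
        self.anchors_to = np.asarray(self.anchors_to, dtype=float)
        if self.anchors_from.size < 2:
            raise ValueError("a warp needs at least two anchors")
        if np.any(np.diff(self.anchors_from) <= 0) or np.any(np.diff(self.anchors_to) <= 0):
            raise ValueError("warp anchors must be strictly increasing (monotone warp)")

    def __call__(self, rt: np.ndarray | float) -> np.ndarray | float:
        rt_arr = np.asarray(rt, dtype=float)
        lo, hi = self.anchors_from[0], self.anchors_from[-1]
        if np.any(rt_arr < lo - 1e-9) or np.any(rt_arr > hi + 1e-9):
            warnings.warn(
                f"RT outside warp domain for run {self.run_id!r}; clamping to domain edge",
                stacklevel=2,
            )
        out = np.interp(rt_arr, self.anchors_from, self.anchors_to)
        return float(out) if np.isscalar(rt) else out

    def inverse(self) -> "WarpFunction":
        return WarpFunction(
            self.run_id, self.anchors_to.copy(), self.anchors_from.copy(),
            score=self.score, is_identity=self.is_identity,
        )

    @classmethod
    def identity(cls, run_id: str, lo: float, hi: float, score: float = 1.0) -> "WarpFunction":
        pts = np.array([lo, hi], dtype=float)
        return cls(run_id, pts, pts.copy(), score=score, is_identity=True)


def base_peak_chromatogram(run: SpectrumRun) -> BasePeakChromatogram:
    """Max peak intensity per MS1 scan; empty scans contribute intensity 0."""
    if run.n_ms1 == 0:
        raise ValueError(f"run {run.run_id!r} has no MS1 scans")
    rt = run.scan_rts()
    inten = np.array([s.intensity.max() if s.intensity.size else 0.0 for s in run.scans])
    return BasePeakChromatogram(run.run_id, rt, inten)


def _binned(bpc: BasePeakChromatogram, grid: np.ndarray, bin_s: float) -> np.ndarray:
    """Max-pool a BPC onto a regular grid (log1p-compressed)."""
    idx = np.clip(np.floor(bpc.rt / bin_s).astype(int), 0, grid.size - 1)
    out = np.zeros(grid.size)
    np.maximum.at(out, idx, bpc.intensity)
    return np.log1p(out)


_BIG = 1e18


def _dtw_path(a: np.ndarray, b: np.ndarray, band: int) -> tuple[np.ndarray, np.ndarray]:
    """Banded DTW between equal-length signals; returns matched index pairs.

    The DP is stored in band coordinates: cell (i, k) is (i, j = i - band + k),
    k in [0, 2*band].  Within-row "left" chains (j-1 steps) are resolved by a
    prefix-scan, so each row is a handful of vectorized operations:
    row[k] = C[k] + min_{m<=k} (best[m] - C[m-1]) with C the cost cumsum.
    """
    n = a.size
    width = 2 * band + 1
    ks = np.arange(width)
    # steps[i, k]: 0 = diag from (i-1, j-1), 1 = up from (i-1, j),
    # >= 2 encodes a left chain whose start sits at k = steps[i, k] - 2.
    steps = np.zeros((n, width), dtype=np.int32)
    # row 0 is reachable only by left steps from (0, 0)
    js0 = ks - band
    valid0 = (js0 >= 0) & (js0 < n)
    cost0 = np.where(valid0, (a[0] - b[np.clip(js0, 0, n - 1)]) ** 2, 0.0)
    prev = np.where(valid0, np.cumsum(cost0), _BIG)
    steps[0] = 2 + band  # chain back to j = 0 (k = band)
    for i in range(1, n):
        js = i - band + ks
        valid = (js >= 0) & (js < n)
        cost = np.where(valid, (a[i] - b[np.clip(js, 0, n - 1)]) ** 2, 0.0)
        diag = prev  # (i-1, j-1) sits at the same k in the previous row
        up = np.concatenate([prev[1:], [_BIG]])  # (i-1, j) sits at k+1
        best = np.minimum(diag, up)
        vertical_choice = (up < diag).astype(np.int32)  # 1 if up, else 0 (diag)
        C = np.cumsum(cost)
        Cm1 = np.concatenate([[0.0], C[:-1]])
        # invalid cells lie contiguously at the band edges, so a chain between
        # valid cells never crosses one; their (zeroed) costs cancel in C - Cm1
        G = np.where(valid, best - Cm1, _BIG)
        M = np.minimum.accumulate(G)
        mstar = np.maximum.accumulate(np.where(G <= M, ks, -1))
        row = np.where(valid & (M < _BIG / 2), C + M, _BIG)
        steps[i] = np.where(mstar < ks, 2 + mstar, vertical_choice)
        prev = row
    # backtrack from (n-1, j = n-1), i.e. k = band
    i, k = n - 1, band
    path_i: list[int] = []
    path_j: list[int] = []
    guard = 0
    while guard < 6 * n + 8:
        guard += 1
        path_i.append(i)
        path_j.append(i - band + k)
        if i == 0 and i - band + k == 0:
            break
        s = steps[i, k]
        if s >= 2:  # walk the left chain down to its start
            start = s - 2
            while k > start:
                k -= 1
                path_i.append(i)
                path_j.append(i - band + k)
            if i == 0:
                break
            s = steps[i, k]  # 0 or 1 at the chain start
        if s == 1:
            i, k = i - 1, k + 1
        else:
            i, k = i - 1, k
    return np.array(path_i[::-1]), np.array(path_j[::-1])


def estimate_warp(
    run: SpectrumRun,
    reference: SpectrumRun,
    bin_s: float = 5.0,
    band_s: float = 120.0,
    anchor_spacing_s: float = 60.0,
) -> WarpFunction:
    """Estimate the monotone warp mapping ``run`` RTs onto ``reference`` RTs."""
    ref_lo, ref_hi = reference.rt_span()
    run_lo, run_hi = run.rt_span()
    if run_hi < ref_lo or ref_hi < run_lo:
        raise ValueError(
            f"runs {run.run_id!r} and {reference.run_id!r} do not overlap in RT"
        )
    if run.run_id == reference.run_id:
        # pad the domain so MS2 events just past the last MS1 scan stay inside
        return WarpFunction.identity(run.run_id, min(ref_lo, 0.0) - bin_s, ref_hi + bin_s, score=1.0)

    bpc_run = base_peak_chromatogram(run)
    bpc_ref = base_peak_chromatogram(reference)
    t_max = max(ref_hi, run_hi) + bin_s
    grid = np.arange(0.0, t_max, bin_s)
    a = _binned(bpc_ref, grid, bin_s)  # reference signal (index i)
    b = _binned(bpc_run, grid, bin_s)  # run signal (index j)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    band = max(1, int(round(band_s / bin_s)))
    path_i, path_j = _dtw_path(z(a), z(b), band)

    # anchors: for each reference-time segment, mean matched run time
    centers = grid + bin_s / 2.0
    seg = np.floor(centers[path_i] / anchor_spacing_s).astype(int)
    run_t = centers[path_j]
    ref_t = centers[path_i]
    anchors_from, anchors_to = [], []
    for s in np.unique(seg):
        m = seg == s
        # medians resist path stalls in locally flat chromatogram regions
        anchors_from.append(float(np.median(run_t[m])))
        anchors_to.append(float(np.median(ref_t[m])))
    af = np.array(anchors_from)
    at = np.array(anchors_to)
    # running-median smoothing of anchor shifts: isolated anchors can land a
    # few bins off where the chromatogram is locally flat and the DTW path
    # wanders inside the band
    if af.size >= 3:
        shifts = af - at
        smoothed = np.array(
            [np.median(shifts[max(0, k - 2): k + 3]) for k in range(shifts.size)]
        )
        at = af - smoothed
    # enforce strict monotonicity in the run coordinate (merge stalls)
    keep_f, keep_t = [af[0]], [at[0]]
    for f, t in zip(af[1:], at[1:]):
        if f > keep_f[-1] + 1e-6 and t > keep_t[-1] + 1e-6:
            keep_f.append(f)
            keep_t.append(t)
    if len(keep_f) < 2:
        keep_f = [run_lo, run_hi]
        keep_t = [run_lo, run_hi]
    af, at = np.array(keep_f), np.array(keep_t)
    # extend to cover the full run domain by edge-slope extrapolation
    lo_pt = min(run_lo, 0.0) - bin_s
    hi_pt = run_hi + bin_s
    inside = (af > lo_pt + 1e-6) & (af < hi_pt - 1e-6)
    if inside.sum() >= 2:
        af, at = af[inside], at[inside]
    s0 = (at[1] - at[0]) / (af[1] - af[0])
    s1 = (at[-1] - at[-2]) / (af[-1] - af[-2])
    first_f, last_f = af[0], af[-1]
    af = np.concatenate([[lo_pt], af, [hi_pt]])
    at = np.concatenate([[at[0] - s0 * (first_f - lo_pt)], at, [at[-1] + s1 * (hi_pt - last_f)]])

    warp = WarpFunction(run.run_id, af, at, score=0.0)
    warp.score = alignment_score(run, reference, warp, bin_s=bin_s)
    return warp


def alignment_score(
    run: SpectrumRun,
    reference: SpectrumRun,
    warp: WarpFunction,
    bin_s: float = 5.0,
) -> float:
    """Pearson correlation of warped, binned, log-compressed BPCs (in [-1, 1])."""
    bpc_run = base_peak_chromatogram(run)
    bpc_ref = base_peak_chromatogram(reference)
    ref_hi = reference.rt_span()[1]
    grid = np.arange(0.0, ref_hi + bin_s, bin_s)
    warped = BasePeakChromatogram(run.run_id, np.asarray(warp(bpc_run.rt)), bpc_run.intensity)
    x = _binned(warped, grid, bin_s)
    y = _binned(bpc_ref, grid, bin_s)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(pearsonr(x, y).statistic)


def pairwise_scores(runs: list[SpectrumRun], bin_s: float = 5.0, band_s: float = 120.0) -> np.ndarray:
    """Symmetric matrix of pairwise alignment scores (diagonal = 1)."""
    n = len(runs)
    scores = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = estimate_warp(runs[j], runs[i], bin_s=bin_s, band_s=band_s).score
            scores[i, j] = scores[j, i] = s
    return scores


def select_reference(
    runs: list[SpectrumRun], bin_s: float = 5.0, band_s: float = 120.0
) -> str:
    """Pick the alignment reference run.

    The reference maximizes the sum of (a) the rank of its mean pairwise
    alignment score against all other runs and (b) the rank of its total
    BPC intensity; ties break to the lexicographically smallest run id.
    """
    if len(runs) == 0:
        raise ValueError("no runs given")
    if len(runs) == 1:
        warnings.warn("single run: returning it as its own reference", stacklevel=2)
        return runs[0].run_id
    order = np.argsort([r.run_id for r in runs])  # permutation-invariant processing order
    runs_sorted = [runs[i] for i in order]
    scores = pairwise_scores(runs_sorted, bin_s=bin_s, band_s=band_s)
    n = len(runs_sorted)
    mean_score = (scores.sum(axis=1) - 1.0) / (n - 1)
    total_bpc = np.array([base_peak_chromatogram(r).total_intensity() for r in runs_sorted])
    # scores compared at 0.01 resolution so near-identical alignments tie and
    # total BPC intensity breaks the tie
    rank_sum = rankdata(np.round(mean_score, 2)) + rankdata(np.round(total_bpc, 6))
    best = rank_sum.max()
    candidates = [runs_sorted[i].run_id for i in np.flatnonzero(rank_sum >= best - 1e-9)]
    return min(candidates)


def apply_warp(run: SpectrumRun, warp: WarpFunction) -> SpectrumRun:
    """Map all scan and MS2-event RTs through the warp; peak lists unchanged."""
    out = run.copy()
    rts = np.asarray(warp(out.scan_rts()))
    for scan, t in zip(out.scans, rts):
        scan.rt = float(t)
    for ev in out.ms2_events:
        ev.rt = float(warp(ev.rt))
    return out


def align_cohort(
    runs: list[SpectrumRun],
    reference_id: str | None = None,
    bin_s: float = 5.0,
    band_s: float = 120.0,
) -> tuple[list[SpectrumRun], dict[str, WarpFunction], str]:
    """Align every run onto the chosen (or given) reference timescale."""
    if reference_id is None:
        reference_id = select_reference(runs, bin_s=bin_s, band_s=band_s)
    ref = next(r for r in runs if r.run_id == reference_id)
    warps: dict[str, WarpFunction] = {}
    aligned: list[SpectrumRun] = []
    for r in runs:
        w = estimate_warp(r, ref, bin_s=bin_s, band_s=band_s)
        warps[r.run_id] = w
        aligned.append(apply_warp(r, w))
    return aligned, warps, reference_id
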
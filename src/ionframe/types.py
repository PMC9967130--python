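"""Core in-memory containers shared across the pipeline.

A cohort is a list of :class:`SpectrumRun` objects (one per LC-MS injection)
plus a PSM table (a pandas DataFrame with the columns listed in
:data:`PSM_COLUMNS`).  All retention times are seconds, all m/z values are
Thomson, intensities are arbitrary ion-current units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Required columns of a PSM table (one row per peptide-spectrum match).
PSM_COLUMNS = (
    "psm_id",
    "run_id",
    "ms2_scan_id",
    "peptide",
    "charge",
    "protein_accession",
    "is_unique",
)


@dataclass
class Scan:
    """One centroided MS1 scan: a retention time and a peak list."""

    scan_id: str
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")


@dataclass
class Ms2Event:
    """A fragmentation event: the precursor selected for an MS2 scan."""

    scan_id: str
    rt: float
    precursor_mz: float
    precursor_intensity: float
    precursor_scan_id: str


@dataclass
class SpectrumRun:
    """One LC-MS run: MS1 scans (RT-sorted) plus MS2 precursor events."""

    run_id: str
    scans: list[Scan] = field(default_factory=list)
    ms2_events: list[Ms2Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.rt)

    @property
    def n_ms1(self) -> int:
        return len(self.scans)

    def rt_span(self) -> tuple[float, float]:
        if not self.scans:
            raise ValueError(f"run {self.run_id!r} has no MS1 scans")
        return self.scans[0].rt, self.scans[-1].rt

    def scan_rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=float)

    def cycle_time(self) -> float:
        """Median spacing between consecutive MS1 scans (seconds)."""
        rts = self.scan_rts()
        if rts.size < 2:
            return 1.0
        return float(np.median(np.diff(rts)))

    def copy(self) -> "SpectrumRun":
        return SpectrumRun(
            self.run_id,
            [replace(s, mz=s.mz.copy(), intensity=s.intensity.copy()) for s in self.scans],
            [replace(e) for e in self.ms2_events],
        )


def validate_psm_table(psm: pd.DataFrame) -> pd.DataFrame:
    """Validate a PSM table against the documented schema.

    Raises ``ValueError`` naming the first missing column, or on duplicated
    ``psm_id``.  Returns the (unmodified) table for chaining.
    """
    for col in PSM_COLUMNS:
        if col not in psm.columns:
            raise ValueError(f"PSM table is missing required column {col!r}")
    if psm["psm_id"].duplicated().any():
        dup = psm.loc[psm["psm_id"].duplicated(), "psm_id"].iloc[0]
        raise ValueError(f"duplicate psm_id {dup!r} in PSM table")
    return psm


@dataclass
class ProteinMatrix:
    """Proteins x samples normalized abundance matrix with group labels.

    Structurally complete: every cell holds a positive abundance (zeros are
    floored during roll-up), mirroring the zero protein-level missingness
    property of frame-based MS1 quantification.
    """

    data: pd.DataFrame  # rows = protein accessions, columns = sample ids
    groups: pd.Series  # sample id -> group label
    peptide_counts: pd.Series  # protein accession -> surviving unique peptides

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.data.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        if self.data.isna().any().any():
            raise ValueError("ProteinMatrix must not contain missing cells")
        if (self.data.to_numpy() <= 0).any():
            raise ValueError("ProteinMatrix values must be positive (floored)")

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def group_columns(self, group: str) -> pd.DataFrame:
        cols = self.groups.index[self.groups == group]
        if len(cols) == 0:
            raise KeyError(f"unknown group label {group!r}")
        return self.data[cols]
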
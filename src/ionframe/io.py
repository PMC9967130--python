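"""Readers and writers for the pipeline's on-disk formats.

Spectra are read from centroided mzML (a compact lxml-based reader) or
from a documented TSV peak-list dialect that round-trips losslessly:

========== ======== ========== ===== ========= ============ =================
scan_id    ms_level rt_seconds mz    intensity precursor_mz precursor_scan_id
========== ======== ========== ===== ========= ============ =================
MS1 rows carry one peak per row (``mz``/``intensity``; an empty scan has a
single row with both fields blank).  MS2 rows carry the precursor m/z, the
precursor's MS1 scan id, and the precursor peak intensity in ``intensity``.

PSM tables are TSV with the columns documented in
:data:`ionframe.types.PSM_COLUMNS`.  Gene sets are standard GMT (parsed by
gseapy).  Protein matrices are CSV with a second header row of group labels.
"""

from __future__ import annotations

import base64
import csv
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .align import WarpFunction
from .types import Ms2Event, ProteinMatrix, Scan, SpectrumRun, validate_psm_table

_RUN_COLUMNS = ["scan_id", "ms_level", "rt_seconds", "mz", "intensity", "precursor_mz", "precursor_scan_id"]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def write_run_tsv(run: SpectrumRun, path: str | Path) -> None:
    """Serialize one run in the TSV peak-list dialect (lossless)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RUN_COLUMNS)
        for scan in run.scans:
            rt = repr(float(scan.rt))
            if scan.mz.size == 0:
                w.writerow([scan.scan_id, 1, rt, "", "", "", ""])
            for mz, inten in zip(scan.mz, scan.intensity):
                w.writerow([scan.scan_id, 1, rt, repr(float(mz)), repr(float(inten)), "", ""])
        for ev in run.ms2_events:
            w.writerow(
                [ev.scan_id, 2, repr(float(ev.rt)), "", repr(float(ev.precursor_intensity)),
                 repr(float(ev.precursor_mz)), ev.precursor_scan_id]
            )


def read_run_tsv(path: str | Path, run_id: str | None = None) -> SpectrumRun:
    """Read a run from the TSV peak-list dialect."""
    path = Path(path)
    if run_id is None:
        run_id = path.stem
    df = pd.read_csv(
        path, sep="\t", dtype={"scan_id": str, "precursor_scan_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _RUN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column {missing[0]!r}")
    scans: list[Scan] = []
    ms1 = df[df["ms_level"] == 1]
    if ms1.empty:
        raise ValueError(f"{path}: no MS1 scans")
    for sid, grp in ms1.groupby("scan_id", sort=False):
        rt = float(grp["rt_seconds"].iloc[0])
        mz = grp["mz"].dropna().to_numpy(dtype=float)
        inten = grp["intensity"].dropna().to_numpy(dtype=float)
        scans.append(Scan(str(sid), rt, mz, inten))
    events = [
        Ms2Event(
            scan_id=str(r.scan_id),
            rt=float(r.rt_seconds),
            precursor_mz=float(r.precursor_mz),
            precursor_intensity=float(r.intensity) if pd.notna(r.intensity) else 0.0,
            precursor_scan_id=str(r.precursor_scan_id),
        )
        for r in df[df["ms_level"] == 2].itertuples(index=False)
    ]
    return SpectrumRun(run_id, scans, events)


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (64/32-bit float, zlib or none)."""
    ns = "{http://psi.hupo.org/ms/mzml}"
    accessions = {c.get("accession") for c in bda.findall(f"{ns}cvParam")}
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    node = bda.find(f"{ns}binary")
    raw = base64.b64decode((node.text or "").strip() or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_run_mzml(path: str | Path, run_id: str | None = None) -> SpectrumRun:
    """Read a centroided run from mzML (MS1 peak lists + MS2 precursor events).

    A compact reader for the fixed layout this pipeline consumes: per
    spectrum, the ms level, the scan start time (minutes or seconds), the
    m/z + intensity arrays, and for MS2 the selected-ion m/z / intensity and
    the precursor spectrum reference.
    """
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    path = Path(path)
    if run_id is None:
        run_id = path.stem
    scans: list[Scan] = []
    events: list[Ms2Event] = []
    last_ms1_id = ""
    for _, spec in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        sid = spec.get("id", f"index={spec.get('index')}")
        params = {c.get("accession"): c for c in spec.findall(f"{ns}cvParam")}
        ms_level = int(params["MS:1000511"].get("value")) if "MS:1000511" in params else 1
        rt = 0.0
        scan_node = spec.find(f"{ns}scanList/{ns}scan")
        if scan_node is not None:
            for c in scan_node.findall(f"{ns}cvParam"):
                if c.get("accession") == "MS:1000016":
                    rt = float(c.get("value"))
                    unit = (c.get("unitName") or "minute").lower()
                    if unit.startswith("min"):
                        rt *= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            acc = {c.get("accession") for c in bda.findall(f"{ns}cvParam")}
            if "MS:1000514" in acc:
                arrays["mz"] = _decode_binary_array(bda)
            elif "MS:1000515" in acc:
                arrays["intensity"] = _decode_binary_array(bda)
        if ms_level == 1:
            scans.append(
                Scan(sid, rt, arrays.get("mz", np.array([])), arrays.get("intensity", np.array([])))
            )
            last_ms1_id = sid
        elif ms_level == 2:
            prec = spec.find(f"{ns}precursorList/{ns}precursor")
            if prec is None:
                raise ValueError(f"{path}: MS2 spectrum {sid!r} lacks a precursor element")
            ion = prec.find(f"{ns}selectedIonList/{ns}selectedIon")
            ion_params = {c.get("accession"): c for c in ion.findall(f"{ns}cvParam")}
            events.append(
                Ms2Event(
                    scan_id=sid,
                    rt=rt,
                    precursor_mz=float(ion_params["MS:1000744"].get("value")),
                    precursor_intensity=float(ion_params["MS:1000042"].get("value"))
                    if "MS:1000042" in ion_params
                    else 0.0,
                    precursor_scan_id=prec.get("spectrumRef", last_ms1_id),
                )
            )
        spec.clear()
    if not scans:
        raise ValueError(f"{path}: no MS1 scans")
    return SpectrumRun(run_id, scans, events)


def read_spectra(paths: list[str | Path]) -> list[SpectrumRun]:
    """Read a cohort of runs; format chosen by file extension (.mzML or .tsv)."""
    runs = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() == ".mzml":
            runs.append(read_run_mzml(p))
        else:
            runs.append(read_run_tsv(p))
    return runs


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a PSM table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str, "run_id": str, "ms2_scan_id": str, "peptide": str})
    validate_psm_table(df)
    df["is_unique"] = df["is_unique"].astype(bool)
    df["charge"] = df["charge"].astype(int)
    return df


def write_psm_table(psm: pd.DataFrame, path: str | Path) -> None:
    validate_psm_table(psm).to_csv(path, sep="\t", index=False)


def write_protein_matrix(pm: ProteinMatrix, path: str | Path) -> None:
    """CSV with a first header row of sample ids and a second of group labels."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["protein_accession"] + list(pm.samples))
        w.writerow(["__group__"] + [pm.groups[s] for s in pm.samples])
        for acc, row in pm.data.iterrows():
            w.writerow([acc] + [repr(float(v)) for v in row])


def read_protein_matrix(path: str | Path) -> ProteinMatrix:
    raw = pd.read_csv(path, header=None, dtype=str)
    samples = list(raw.iloc[0, 1:])
    groups = pd.Series(list(raw.iloc[1, 1:]), index=samples)
    data = raw.iloc[2:].copy()
    data.index = data.pop(0)
    data.index.name = "protein_accession"
    data.columns = samples
    data = data.astype(float)
    counts = pd.Series(2, index=data.index)  # peptide counts are not serialized
    return ProteinMatrix(data=data, groups=groups, peptide_counts=counts)


def write_warps(warps: dict[str, WarpFunction], path: str | Path) -> None:
    """Serialize warps as a CSV anchor table (run_id, rt_from, rt_to)."""
    rows = []
    for rid, w in warps.items():
        for f, t in zip(w.anchors_from, w.anchors_to):
            rows.append({"run_id": rid, "rt_from": f, "rt_to": t, "score": w.score})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_warps(path: str | Path) -> dict[str, WarpFunction]:
    df = pd.read_csv(path)
    out = {}
    for rid, grp in df.groupby("run_id"):
        out[str(rid)] = WarpFunction(
            str(rid),
            grp["rt_from"].to_numpy(float),
            grp["rt_to"].to_numpy(float),
            score=float(grp["score"].iloc[0]),
        )
    return out


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    """Survival cohort CSV: subject, time_months, event, expr_<gene>..."""
    df = pd.read_csv(path)
    for col in ("subject", "time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (df["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return df


def survival_genes(cohort: pd.DataFrame) -> list[str]:
    return [c[len("expr_"):] for c in cohort.columns if c.startswith("expr_")]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    return {name: list(members) for name, members in _gseapy_read_gmt(str(path)).items()}


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", newline="") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, descriptions.get(name, "na")] + list(members)) + "\n")


def write_ground_truth(truth, path_prefix: str | Path) -> None:
    """Ground truth as CSVs: <prefix>_foldchanges.csv, <prefix>_nuisance.csv."""
    prefix = str(path_prefix)
    truth.fold_changes.to_csv(prefix + "_foldchanges.csv")
    rows = [
        {
            "run_id": rid,
            "drift_slope": truth.drift[rid][0],
            "drift_offset_s": truth.drift[rid][1],
            "bias": truth.bias[rid],
        }
        for rid in truth.drift
    ]
    pd.DataFrame(rows).to_csv(prefix + "_nuisance.csv", index=False)
    pd.DataFrame({"outlier_peptide": sorted(truth.outlier_peptides)}).to_csv(
        prefix + "_outliers.csv", index=False
    )
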
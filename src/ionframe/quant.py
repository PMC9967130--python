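"""Annotation merge, dataset-wide normalization, principal-component-based
peptide outlier removal and protein-level aggregation.

Normalization is median-of-log-ratios against the frame-wise geometric-mean
run: a per-run factor is the exponentiated median over frames of
``log(area) - mean_over_runs(log area)``, recentred so the factors average
to 1 in log space.  Only frames observed (> 0) in every run inform the
factors; every frame is then divided by its run's factor.

The peptide outlier rule: within one protein's peptide x sample matrix of
log2 normalized areas (row-centred so only profile shape matters), each
peptide is fitted against the first principal component oriented with the
peptide consensus (negative projections clamp to zero, so an
anti-correlated peptide scores its full profile norm); a peptide is flagged
when its residual exceeds median + 3 x scaled MAD of the residuals.
Proteins with fewer than three peptides are never flagged, and at least two
peptides always survive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .frames import FrameTarget
from .types import ProteinMatrix


def annotate_frames(
    targets: list[FrameTarget], areas: pd.DataFrame, psm_table: pd.DataFrame
) -> pd.DataFrame:
    """Attach peptide/protein annotation to every frame.

    Returns one row per frame: peptide, charge, protein accession,
    ``is_unique`` flag and the per-run areas.  A peptide that maps to more
    than one accession in the PSM table (or whose PSMs are flagged
    non-unique upstream) is marked non-unique and excluded from roll-up.
    """
    if len(targets) == 0:
        raise ValueError("no frame targets to annotate")
    pep_info = (
        psm_table.groupby("peptide")
        .agg(
            n_accessions=("protein_accession", "nunique"),
            protein_accession=("protein_accession", "first"),
            all_unique=("is_unique", "all"),
        )
    )
    rows = []
    for t in targets:
        info = pep_info.loc[t.peptide]
        rows.append(
            {
                "frame_id": t.frame_id,
                "peptide": t.peptide,
                "charge": t.charge,
                "protein_accession": info["protein_accession"],
                "is_unique": bool(info["all_unique"]) and int(info["n_accessions"]) == 1,
            }
        )
    ann = pd.DataFrame(rows).set_index("frame_id")
    missing = ann.index.difference(areas.index)
    if len(missing):
        raise ValueError(f"frames without extracted areas: {list(missing)[:5]}")
    out = ann.join(areas, how="left")
    assert len(out) == len(targets)
    return out


def normalize(area_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-log-ratios normalization against the geometric-mean run.

    Returns ``(normalized areas, per-run factors)``; the normalized matrix is
    ``area / factor`` and the factors have geometric mean 1.
    """
    if area_matrix.shape[1] < 2:
        raise ValueError("normalization needs at least 2 runs")
    if area_matrix.shape[0] < 10:
        warnings.warn(
            f"only {area_matrix.shape[0]} frames available for normalization; "
            "factors may be unstable",
            stacklevel=2,
        )
    values = area_matrix.to_numpy(dtype=float)
    all_zero = (values <= 0).all(axis=0)
    if all_zero.any():
        bad = area_matrix.columns[all_zero][0]
        raise ValueError(f"run {bad!r} has no positive frame areas; cannot normalize")
    complete = (values > 0).all(axis=1)
    if not complete.any():
        raise ValueError("no frame is observed in every run; cannot normalize")
    logs = np.log(values[complete])
    log_ratio = logs - logs.mean(axis=1, keepdims=True)
    log_factors = np.median(log_ratio, axis=0)
    log_factors = log_factors - log_factors.mean()
    factors = pd.Series(np.exp(log_factors), index=area_matrix.columns, name="factor")
    normalized = area_matrix.div(factors, axis=1)
    return normalized, factors


def detect_peptide_outliers(protein_block: pd.DataFrame, n_mads: float = 3.0) -> pd.Series:
    """Flag outlier peptides within one protein's log2 peptide x sample block.

    Returns a boolean Series over the peptide index.  Requires >= 2 peptides;
    with exactly 2 nothing is ever flagged (a disagreement cannot be
    attributed), and at least 2 peptides always survive.
    """
    n = protein_block.shape[0]
    if n < 2:
        raise ValueError("outlier detection needs a protein with >= 2 peptides")
    flags = pd.Series(False, index=protein_block.index)
    if n == 2:
        return flags
    x = protein_block.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)  # profile shape only
    # first principal component of the peptide-profile matrix, oriented with
    # the consensus so that a sign-flipped (anti-correlated) peptide cannot
    # hide inside the PC1 subspace
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc1 = vt[0]
    proj = x @ pc1
    if np.median(proj) < 0:
        pc1, proj = -pc1, -proj
    fitted = np.clip(proj, 0.0, None)[:, None] * pc1[None, :]
    resid = np.linalg.norm(x - fitted, axis=1)
    med = np.median(resid)
    mad = 1.4826 * np.median(np.abs(resid - med))  # normal-consistent MAD
    cutoff = med + n_mads * mad
    candidate = resid > cutoff + 1e-12
    max_flags = n - 2
    if candidate.sum() > max_flags:
        worst = np.argsort(resid)[::-1][:max_flags]
        candidate = np.zeros(n, dtype=bool)
        candidate[worst] = True
    flags[:] = candidate
    return flags


def peptide_matrix(annotated: pd.DataFrame, run_ids: list[str]) -> pd.DataFrame:
    """Sum frame areas (charge states) to peptide level, unique peptides only."""
    unique = annotated[annotated["is_unique"]]
    if unique.empty:
        raise ValueError("no unique peptides available for roll-up")
    return unique.groupby(["protein_accession", "peptide"])[run_ids].sum()


def flag_outliers(
    pep_matrix: pd.DataFrame, n_mads: float = 3.0
) -> pd.Series:
    """Apply the PC outlier rule per protein over the peptide matrix.

    ``pep_matrix`` is indexed by (protein, peptide) and holds normalized
    linear areas; blocks are log2-transformed (zeros floored to half the
    block's smallest positive value) before the rule is applied.
    """
    flags = pd.Series(False, index=pep_matrix.index)
    for prot, block in pep_matrix.groupby(level=0, sort=False):
        vals = block.to_numpy(dtype=float)
        pos = vals[vals > 0]
        floor = (pos.min() / 2.0) if pos.size else 1.0
        logs = pd.DataFrame(
            np.log2(np.maximum(vals, floor)), index=block.index, columns=block.columns
        )
        if len(block) >= 2:
            flags.loc[block.index] = detect_peptide_outliers(logs, n_mads=n_mads).to_numpy()
    return flags


def aggregate_protein(
    pep_matrix: pd.DataFrame,
    outlier_flags: pd.Series,
    groups: pd.Series,
    min_peptides: int = 2,
) -> ProteinMatrix:
    """Roll surviving unique peptides up to protein level (by sum).

    Proteins retaining fewer than ``min_peptides`` peptides after outlier
    removal are dropped; remaining zero cells are floored to half the
    smallest positive value of the matrix so every cell is positive and
    ratios stay computable.
    """
    if pep_matrix.empty:
        raise ValueError("empty peptide matrix")
    surviving = pep_matrix[~outlier_flags.reindex(pep_matrix.index, fill_value=False)]
    counts = surviving.groupby(level=0).size()
    keep = counts[counts >= min_peptides].index
    data = surviving.loc[keep].groupby(level=0).sum()
    data.index.name = "protein_accession"
    values = data.to_numpy()
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("protein matrix has no positive values")
    floor = pos.min() / 2.0
    data = data.mask(data <= 0, floor)
    return ProteinMatrix(data=data, groups=groups, peptide_counts=counts.loc[keep])


def quantify(
    annotated: pd.DataFrame,
    run_ids: list[str],
    groups: pd.Series,
    n_mads: float = 3.0,
    min_peptides: int = 2,
) -> tuple[ProteinMatrix, pd.Series, pd.Series]:
    """Normalization -> outlier removal -> roll-up, in one call.

    Returns ``(protein_matrix, normalization_factors, outlier_flags)``.
    """
    normalized, factors = normalize(annotated[run_ids])
    ann_norm = annotated.copy()
    ann_norm[run_ids] = normalized
    pep = peptide_matrix(ann_norm, run_ids)
    flags = flag_outliers(pep, n_mads=n_mads)
    pm = aggregate_protein(pep, flags, groups, min_peptides=min_peptides)
    return pm, factors, flags
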
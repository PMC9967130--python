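"""Differential abundance gating and reproducibility metrics.

A protein is *altered* when its one-way ANOVA p-value (on log2 abundances,
across all groups) is below ``p_threshold`` AND at least one tumor/control
abundance ratio exceeds ``ratio_up`` or falls below ``ratio_down`` (strict
inequalities).  *Metastasis-specific* proteins are the altered proteins
whose metastatic / non-metastatic ratio additionally passes the same gate
in at least one of the metastatic comparisons.  Ratios are ratios of
arithmetic group means on the linear scale (a geometric-mean option is
provided).  No multiple-testing correction is applied by default; a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.stats.multitest import multipletests

from .types import ProteinMatrix

P_THRESHOLD = 0.05
RATIO_UP = 1.5
RATIO_DOWN = 0.67


def anova_pvalues(matrix: ProteinMatrix) -> pd.Series:
    """One-way fixed-effects ANOVA on log2 abundances, per protein."""
    group_cols = []
    for g in matrix.groups.unique():
        cols = matrix.group_columns(g)
        if cols.shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples; ANOVA undefined")
        group_cols.append(np.log2(cols.to_numpy()))
    if len(group_cols) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs yield nan, handled below
        res = f_oneway(*group_cols, axis=1)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.Series(p, index=matrix.proteins, name="anova_p")


def compare_ratios(
    matrix: ProteinMatrix,
    control_group: str,
    comparison_groups: list[str],
    geometric: bool = False,
) -> pd.DataFrame:
    """Per-protein abundance ratios group/control (linear arithmetic means).

    Returns one column ``<group>/<control>`` per comparison group.
    """
    ctrl = matrix.group_columns(control_group)
    ctrl_mean = (
        np.exp(np.log(ctrl).mean(axis=1)) if geometric else ctrl.mean(axis=1)
    )
    out = {}
    for g in comparison_groups:
        cols = matrix.group_columns(g)
        mean = np.exp(np.log(cols).mean(axis=1)) if geometric else cols.mean(axis=1)
        out[f"{g}/{control_group}"] = mean / ctrl_mean
    return pd.DataFrame(out, index=matrix.proteins)


def _ratio_gate(ratios: pd.DataFrame, up: float, down: float) -> pd.Series:
    return ((ratios > up) | (ratios < down)).any(axis=1)


def select_altered(
    pvalues: pd.Series,
    tumor_ratios: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    ratio_up: float = RATIO_UP,
    ratio_down: float = RATIO_DOWN,
    bh_correct: bool = False,
) -> pd.Series:
    """Boolean altered flag: p below threshold AND ratio gate in >= 1 comparison."""
    p = pvalues.copy()
    if bh_correct:
        p = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index)
    gate = _ratio_gate(tumor_ratios.reindex(p.index), ratio_up, ratio_down)
    return ((p < p_threshold) & gate).rename("altered")


def select_metastasis_specific(
    altered: pd.Series,
    metastatic_ratios: pd.DataFrame,
    ratio_up: float = RATIO_UP,
    ratio_down: float = RATIO_DOWN,
) -> pd.Series:
    """Metastasis-specific flag: altered AND the met/non-met ratio gate."""
    gate = _ratio_gate(metastatic_ratios.reindex(altered.index), ratio_up, ratio_down)
    return (altered & gate).rename("metastasis_specific")


def intragroup_cv(matrix: ProteinMatrix) -> pd.Series:
    """Per-group mean coefficient of variation across proteins, in percent.

    CV per protein per group is sample-sd / mean on the linear scale
    (ddof = 1, appropriate for small replicate groups); proteins with a
    non-positive mean in a group are skipped with a warning.
    """
    out = {}
    for g in matrix.groups.unique():
        cols = matrix.group_columns(g)
        if cols.shape[1] < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples for a CV")
        mean = cols.mean(axis=1)
        sd = cols.std(axis=1, ddof=1)
        ok = mean > 0
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} proteins with non-positive mean skipped in group {g!r}",
                stacklevel=2,
            )
        out[g] = float((sd[ok] / mean[ok]).mean() * 100.0)
    return pd.Series(out, name="mean_cv_percent")


def differential_table(
    matrix: ProteinMatrix,
    control_group: str,
    nonmetastatic_group: str,
    metastatic_groups: list[str],
    p_threshold: float = P_THRESHOLD,
    ratio_up: float = RATIO_UP,
    ratio_down: float = RATIO_DOWN,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full per-protein differential record.

    Columns: the ANOVA p, one tumor/control ratio per tumor group, one
    metastatic/non-metastatic ratio per metastatic group, and the
    ``altered`` / ``metastasis_specific`` flags.
    """
    tumor_groups = [nonmetastatic_group] + list(metastatic_groups)
    p = anova_pvalues(matrix)
    tumor_ratios = compare_ratios(matrix, control_group, tumor_groups)
    met_ratios = compare_ratios(matrix, nonmetastatic_group, list(metastatic_groups))
    altered = select_altered(
        p, tumor_ratios, p_threshold=p_threshold, ratio_up=ratio_up,
        ratio_down=ratio_down, bh_correct=bh_correct,
    )
    met = select_metastasis_specific(altered, met_ratios, ratio_up=ratio_up, ratio_down=ratio_down)
    out = pd.concat([p, tumor_ratios, met_ratios, altered, met], axis=1)
    assert (out.loc[out["metastasis_specific"], "altered"]).all()
    return out
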
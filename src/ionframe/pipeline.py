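"""End-to-end pipeline driver: align -> extract -> quantify -> differential
-> classify [-> survival -> enrichment], with a structured run log and
deterministic, config-hashed outputs."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import align as _align
from . import differential as _diff
from . import enrichment as _enrich
from . import frames as _frames
from . import io as _io
from . import patterns as _patterns
from . import quant as _quant
from . import survival as _surv
from .synthdata import DEFAULT_GROUPS
from .types import ProteinMatrix, SpectrumRun


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline invocation.

    The thresholds default to the study conventions: a 10 ppm / 1 min
    extraction window, ANOVA p < 0.05, ratio gates > 1.5 or < 0.67, and a
    0.5 z-score margin for the pattern cascade.
    """

    group_map: dict[str, str] = field(default_factory=dict)  # sample/run id -> group
    control_group: str = DEFAULT_GROUPS[0]
    nonmetastatic_group: str = DEFAULT_GROUPS[1]
    metastatic_groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS[2:]))
    ppm: float = 10.0
    rt_window_s: float = 60.0
    p_threshold: float = 0.05
    ratio_up: float = 1.5
    ratio_down: float = 0.67
    margin: float = 0.5
    bin_s: float = 5.0
    band_s: float = 120.0
    n_mads: float = 3.0
    min_peptides: int = 2
    seed: int = 0
    spectra_dir: str | None = None
    psm_path: str | None = None
    survival_path: str | None = None
    gmt_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (self.ratio_down < 1.0 < self.ratio_up):
            raise ValueError("need ratio_down < 1 < ratio_up")
        if self.p_threshold <= 0 or self.ppm <= 0 or self.rt_window_s <= 0:
            raise ValueError("thresholds must be positive")

    def tumor_groups(self) -> list[str]:
        return [self.nonmetastatic_group] + list(self.metastatic_groups)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: they do not
        influence the computed values)."""
        payload = asdict(self)
        for key in ("spectra_dir", "psm_path", "survival_path", "gmt_path", "output_dir"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class PipelineResult:
    reference_run: str
    warps: dict
    protein_matrix: ProteinMatrix
    normalization_factors: pd.Series
    outlier_flags: pd.Series
    differential: pd.DataFrame
    assignments: pd.DataFrame | None
    metastasis_specific: list[str]
    survival: pd.DataFrame | None
    concordance: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    log: list[dict]
    config_hash: str


def run_pipeline(
    runs: list[SpectrumRun],
    psm_table: pd.DataFrame,
    config: PipelineConfig,
    survival_cohort: pd.DataFrame | None = None,
    gene_sets: dict[str, list[str]] | None = None,
) -> PipelineResult:
    """Execute the full pipeline on in-memory inputs.

    Stage failures raise with the stage name prefixed.  Identical inputs
    and config produce identical outputs (every stage is deterministic).
    """
    log: list[dict] = []
    chash = config.config_hash()

    def stage(name: str):
        log.append({"stage": name, "t": time.time(), "config_hash": chash, "seed": config.seed})

    def fail(name: str, err: Exception) -> Exception:
        return RuntimeError(f"pipeline stage {name!r} failed: {err}")

    groups = pd.Series(config.group_map)
    if groups.empty:
        raise ValueError("config.group_map must assign every run to a group")

    try:
        stage("align")
        aligned, warps, ref_id = _align.align_cohort(runs, bin_s=config.bin_s, band_s=config.band_s)
    except Exception as e:  # noqa: BLE001 - stage-named abort
        raise fail("align", e) from e

    try:
        stage("extract")
        targets = _frames.build_frame_targets(psm_table, aligned, ppm=config.ppm, rt_window_s=config.rt_window_s)
        areas, _apex = _frames.extract_frames(aligned, targets)
    except Exception as e:
        raise fail("extract", e) from e

    try:
        stage("quantify")
        annotated = _quant.annotate_frames(targets, areas, psm_table)
        run_ids = [r.run_id for r in runs]
        pm, factors, flags = _quant.quantify(
            annotated, run_ids, groups, n_mads=config.n_mads, min_peptides=config.min_peptides
        )
    except Exception as e:
        raise fail("quantify", e) from e

    try:
        stage("diff")
        diff = _diff.differential_table(
            pm,
            config.control_group,
            config.nonmetastatic_group,
            config.metastatic_groups,
            p_threshold=config.p_threshold,
            ratio_up=config.ratio_up,
            ratio_down=config.ratio_down,
        )
    except Exception as e:
        raise fail("diff", e) from e

    assignments = None
    met_specific: list[str] = []
    try:
        stage("classify")
        selected = list(diff.index[diff["metastasis_specific"]])
        if selected:
            z = _patterns.standardize_profiles(pm, config.tumor_groups(), proteins=selected)
            assignments = _patterns.assign_patterns(z, margin=config.margin)
            met_specific = list(_patterns.exclude_non_metastatic(assignments).index)
    except Exception as e:
        raise fail("classify", e) from e

    surv_table = None
    concordance = None
    if survival_cohort is not None:
        try:
            stage("survival")
            genes = [g for g in _io.survival_genes(survival_cohort)]
            surv_table = _surv.survival_screen(survival_cohort, genes)
            met_ratios = _diff.compare_ratios(
                pm, config.nonmetastatic_group, list(config.metastatic_groups)
            )
            shared = [g for g in surv_table.index if g in met_ratios.index]
            if shared:
                concordance = _surv.concordance_screen(met_ratios, surv_table.loc[shared])
        except Exception as e:
            raise fail("survival", e) from e

    enr = None
    if gene_sets is not None and met_specific:
        try:
            stage("enrich")
            collection = _enrich.GeneSetCollection.from_sets(gene_sets, set(pm.proteins))
            enr = _enrich.fisher_enrichment(met_specific, collection)
        except Exception as e:
            raise fail("enrich", e) from e

    result = PipelineResult(
        reference_run=ref_id,
        warps=warps,
        protein_matrix=pm,
        normalization_factors=factors,
        outlier_flags=flags,
        differential=diff,
        assignments=assignments,
        metastasis_specific=met_specific,
        survival=surv_table,
        concordance=concordance,
        enrichment=enr,
        log=log,
        config_hash=chash,
    )
    if config.output_dir:
        write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    """Write the output bundle (CSV tables + run log) to config.output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_protein_matrix(result.protein_matrix, out / "protein_matrix.csv")
    result.normalization_factors.to_csv(out / "normalization_factors.csv")
    _io.write_warps(result.warps, out / "warps.csv")
    diff = result.differential.copy()
    diff.insert(0, "config_hash", result.config_hash)
    diff.to_csv(out / "differential.csv")
    if result.assignments is not None:
        result.assignments.to_csv(out / "pattern_assignments.csv")
        if len(result.assignments) >= 2:
            z_cols = [c for c in result.assignments.columns if c not in ("pattern", "excluded")]
            link, order, _ = _patterns.cluster_profiles(result.assignments[z_cols])
            (out / "dendrogram.nwk").write_text(_patterns.dendrogram_newick(link, list(result.assignments.index)))
    if result.survival is not None:
        result.survival.to_csv(out / "survival_screen.csv")
    if result.concordance is not None:
        result.concordance.to_csv(out / "concordance.csv")
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.csv")
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {"config_hash": result.config_hash, "seed": config.seed,
             "reference_run": result.reference_run, "stages": result.log},
            fh, indent=2,
        )
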
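"""End-to-end orchestration: raw signals in, ancestry PCs out.

The stage order is: probe selection → detection p-values (on uncorrected
signals) → background correction → masking → probe QC → quantile
normalization (methylated and unmethylated separately, over the selected
probes) → beta computation → kNN imputation → covariate construction →
residualization → rs genotype calling → feature combination → PCA per
method variant. A provenance record captures every threshold applied and the
probe counts surviving each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from ._utils import ValidationError
from .annotations import load_annotations, select_rs_probes, select_snp0bp
from .core import (
    METHOD_COMBINED,
    METHOD_RAW,
    METHOD_RESIDUALIZED,
    METHODS,
    AncestryPCs,
    ancestry_pca,
    baseline_pcs,
    call_rs_genotypes,
    combine_features,
    residualize,
)
from .covariates import build_design, cell_proportion_pcs, control_probe_pcs
from .preprocess import (
    SignalSet,
    background_correct,
    compute_beta,
    detection_pvalues,
    filter_probes_qc,
    impute_knn,
    mask_failed_detections,
    quantile_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, method set, and (optionally) input/output paths."""

    array: str = "EPICv1"
    annotation_paths: list[str] = field(default_factory=list)
    meth_path: str | None = None
    unmeth_path: str | None = None
    beads_path: str | None = None
    negctrl_path: str | None = None
    samplesheet_path: str | None = None
    cellprops_path: str | None = None
    controlprobes_path: str | None = None
    detection_p_path: str | None = None  # pre-computed detection p-values (skips that stage)
    outdir: str | None = None

    maf_min: float = 0.05
    detection_threshold: float = 1e-16
    bead_min: int = 3
    bead_frac: float = 0.05
    miss_frac: float = 0.10
    beta_offset: float = 100.0
    impute_k: int = 5
    genotype_low: float = 0.25
    genotype_high: float = 0.75
    n_control_pcs: int = 10
    n_pcs: int = 10
    methods: tuple[str, ...] = METHODS
    #: rs probes are extracted as their own block; quantile-normalizing them
    #: together with the CpG panel blurs their trimodal beta distribution
    #: (each sample's genotype mix differs), so joint normalization is off
    #: by default and available only as an explicit flag.
    normalize_rs_jointly: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_min", "bead_frac", "miss_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.detection_threshold <= 1.0):
            raise ValidationError("detection_threshold must lie in (0, 1]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValidationError(f"unknown methods {sorted(unknown)}; expected subset of {METHODS}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        data["methods"] = tuple(data.get("methods", METHODS))
        return cls(**data)


@dataclass
class PipelineResult:
    pcs: dict[str, AncestryPCs]
    features: pd.DataFrame
    residuals: pd.DataFrame
    genotypes: pd.DataFrame
    beta: pd.DataFrame
    design: pd.DataFrame
    snp0bp_kept: list[str]
    rs_kept: list[str]
    provenance: dict


def run_from_data(
    annotation: pd.DataFrame,
    signals: SignalSet,
    sheet: pd.DataFrame,
    cell_props: pd.DataFrame,
    control_probes: pd.DataFrame,
    config: PipelineConfig | None = None,
    detection_p: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full method on in-memory inputs (the core of ``run_pipeline``)."""
    cfg = config or PipelineConfig()
    prov: dict = {"thresholds": {
        "maf_min": cfg.maf_min, "detection_threshold": cfg.detection_threshold,
        "bead_min": cfg.bead_min, "bead_frac": cfg.bead_frac, "miss_frac": cfg.miss_frac,
        "beta_offset": cfg.beta_offset, "impute_k": cfg.impute_k,
        "genotype_low": cfg.genotype_low, "genotype_high": cfg.genotype_high,
        "n_control_pcs": cfg.n_control_pcs, "n_pcs": cfg.n_pcs,
    }, "stages": {}}

    snp0bp = select_snp0bp(annotation, cfg.maf_min)
    rs_ids = select_rs_probes(annotation)
    selected = snp0bp + rs_ids
    prov["stages"]["selected_snp0bp"] = len(snp0bp)
    prov["stages"]["selected_rs"] = len(rs_ids)
    if not snp0bp:
        raise ValidationError("no SNP-overlapping probes selected; check annotation and maf_min")

    sub = signals.subset_probes(selected)
    if len(sub.meth) < len(selected):
        missing = sorted(set(selected) - set(sub.meth.index))
        raise ValidationError(f"signal matrices lack selected probes, e.g. {missing[:3]}")

    detp = detection_p.loc[sub.meth.index, sub.meth.columns] if detection_p is not None else detection_pvalues(sub)
    corrected = background_correct(sub)
    meth = mask_failed_detections(corrected.meth, detp, cfg.detection_threshold)
    unmeth = mask_failed_detections(corrected.unmeth, detp, cfg.detection_threshold)

    missing_mask = meth.isna() | unmeth.isna()
    retained = filter_probes_qc(missing_mask, sub.bead_counts, cfg.bead_min, cfg.bead_frac, cfg.miss_frac)
    prov["stages"]["retained_after_qc"] = len(retained)
    snp0bp_kept = [p for p in retained if p in set(snp0bp)]
    rs_kept = [p for p in retained if p in set(rs_ids)]
    if not snp0bp_kept:
        raise ValidationError("all SNP-overlapping probes removed by QC")

    if cfg.normalize_rs_jointly:
        meth_n = quantile_normalize(meth.loc[retained])
        unmeth_n = quantile_normalize(unmeth.loc[retained])
        beta = impute_knn(compute_beta(meth_n, unmeth_n, cfg.beta_offset), cfg.impute_k)
    else:
        meth_n = quantile_normalize(meth.loc[snp0bp_kept])
        unmeth_n = quantile_normalize(unmeth.loc[snp0bp_kept])
        beta_snp = impute_knn(compute_beta(meth_n, unmeth_n, cfg.beta_offset), cfg.impute_k)
        if rs_kept:
            rs_beta = compute_beta(meth.loc[rs_kept], unmeth.loc[rs_kept], cfg.beta_offset)
            if rs_beta.isna().any().any():
                rs_beta = impute_knn(rs_beta, cfg.impute_k)
            beta = pd.concat([beta_snp, rs_beta])
        else:
            beta = beta_snp

    sheet = sheet.reset_index(drop=True)
    if list(sheet["sample_id"]) != list(beta.columns):
        raise ValidationError("sample sheet order does not match the signal matrices")
    ctrl_pcs = control_probe_pcs(control_probes, cfg.n_control_pcs)
    cell_pcs = cell_proportion_pcs(cell_props)
    design = build_design(sheet, cell_pcs, ctrl_pcs)
    prov["stages"]["design_columns"] = list(design.columns)

    residuals = residualize(beta.loc[snp0bp_kept], design)
    genotypes = call_rs_genotypes(beta.loc[rs_kept], cfg.genotype_low, cfg.genotype_high)
    features = combine_features(residuals, genotypes)
    prov["stages"]["feature_rows"] = len(features)

    pcs: dict[str, AncestryPCs] = {}
    if METHOD_RAW in cfg.methods:
        pcs[METHOD_RAW] = baseline_pcs(beta.loc[snp0bp_kept], cfg.n_pcs)
    if METHOD_RESIDUALIZED in cfg.methods:
        pcs[METHOD_RESIDUALIZED] = ancestry_pca(residuals, cfg.n_pcs, METHOD_RESIDUALIZED)
    if METHOD_COMBINED in cfg.methods:
        pcs[METHOD_COMBINED] = ancestry_pca(features, cfg.n_pcs, METHOD_COMBINED)

    return PipelineResult(pcs, features, residuals, genotypes, beta, design,
                          snp0bp_kept, rs_kept, prov)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load all inputs, run, write outputs."""
    required = ("meth_path", "unmeth_path", "beads_path", "negctrl_path",
                "samplesheet_path", "cellprops_path", "controlprobes_path")
    missing = [name for name in required if getattr(config, name) is None]
    if missing or not config.annotation_paths:
        raise ValidationError(f"pipeline config lacks input paths: {missing or 'annotation_paths'}")

    annotation = load_annotations(config.annotation_paths, config.array)
    chan = annotation.set_index("probe_id")["channel"] if "channel" in annotation.columns else None
    signals = mio.read_signalset(config.meth_path, config.unmeth_path, config.beads_path,
                                 config.negctrl_path, chan)
    sheet = mio.read_samplesheet(config.samplesheet_path)
    cell_props = mio.read_samples_table(config.cellprops_path)
    control_probes = mio.read_samples_table(config.controlprobes_path)
    detp = mio.read_matrix(config.detection_p_path) if config.detection_p_path else None

    result = run_from_data(annotation, signals, sheet, cell_props, control_probes, config, detp)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for pcs in result.pcs.values():
            pcs.to_tsv(outdir)
        (outdir / "retained_probes.txt").write_text(
            "\n".join(result.snp0bp_kept + result.rs_kept) + "\n"
        )
        (outdir / "provenance.json").write_text(json.dumps(
            {**result.provenance, "config": {k: v for k, v in asdict(config).items()}},
            indent=1, default=str))
        logger.info("pipeline outputs written to %s", outdir)
    return result
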
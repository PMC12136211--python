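"""Synthetic methylation-array cohorts with known ancestry structure.

The generator produces everything the pipeline consumes — raw intensities,
bead counts, negative controls, a sample sheet with repeated samples, cell
proportions, a control-probe matrix and a probe annotation table — plus full
ground truth (group memberships, genotypes, a genotype-PC surrogate).

The generative model, briefly:

* Population structure follows the Balding–Nichols model: each SNP site has
  a base allele frequency, and each ancestry group draws its own frequency
  from Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence parameter F (fst).
  Individual genotypes are Binomial(2, group frequency), stored as dosage/2.
* SNP-overlapping CpG betas are trimodal in genotype (means 0.1/0.5/0.9 by
  default) plus nuisance terms: a per-probe loading on a latent per-batch
  factor (shared with the control probes, so control-probe PCs can genuinely
  remove it), loadings on centered cell-type proportions, sex and age
  effects, and Gaussian noise, clipped to (0, 1).
* rs-probe betas follow the same trimodal model with half the noise and a
  5×-shrunk batch loading (genotyping probes are engineered to stay cleanly
  trimodal), and no other nuisance terms.
* Intensities invert the beta formula around a log-normal total intensity,
  with channel backgrounds added on top; negative controls are Gaussian.
  A small fraction of entries are forced to background level (detection
  failures) or given bead counts below 3.
* Repeated samples of an individual reuse the genotypes but redraw batch,
  cell proportions and technical noise — exactly the variation the
  residualization step is meant to remove.

A ``confounded`` flag ties batch, sex and cell-type distributions to the
ancestry groups, reproducing designs where residualization removes part of
the ancestry signal itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import ValidationError, centered_pca
from .preprocess import SignalSet

logger = logging.getLogger(__name__)

BETA_OFFSET = 100.0  # matches the beta computation in preprocess


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort (defaults = standard design)."""

    seed: int = 0
    groups: tuple[tuple[str, int], ...] = (("AFR", 50), ("EAS", 50), ("EUR", 50))
    #: per-individual sample-count distribution: 80% single sample, 20% duplicated
    repeat_fractions: tuple[tuple[int, float], ...] = ((1, 0.8), (2, 0.2))
    fst: float = 0.1
    n_snp0bp: int = 500
    n_rs: int = 50
    n_control: int = 200
    n_decoy: int = 50
    n_celltypes: int = 6
    n_batches: int = 6
    #: latent technical factors per batch (plate / slide / position style structure)
    n_batch_factors: int = 3
    batch_sd: float = 0.15          # per-probe loading SD on each unit-variance batch factor
    cell_sd: float = 0.5            # per-probe loading SD per unit cell-proportion deviation
    sex_effect_sd: float = 0.05
    age_effect_sd: float = 0.002    # per year
    noise_sd: float = 0.05          # beta-scale residual SD at SNP0bp probes
    genotype_means: tuple[float, float, float] = (0.1, 0.5, 0.9)
    detect_fail_rate: float = 0.002
    low_bead_rate: float = 0.002
    confounded: bool = False
    base_freq_range: tuple[float, float] = (0.1, 0.9)
    mean_total_intensity: float = 10000.0
    intensity_log_sd: float = 0.3
    background_mean: float = 200.0
    background_sd: float = 30.0
    n_neg_per_channel: int = 60
    control_batch_sd: float = 0.3   # control-probe log2 loading SD on the batch factor
    control_noise_sd: float = 0.1
    rs_batch_shrink: float = 5.0

    def __post_init__(self) -> None:
        if not self.groups or any(n <= 0 for _, n in self.groups):
            raise ValidationError("each group needs a positive individual count")
        if not (0.0 < self.fst < 1.0):
            raise ValidationError("fst must lie in (0, 1)")
        for name in ("n_snp0bp", "n_rs", "n_control", "n_celltypes", "n_batches", "n_batch_factors"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("detect_fail_rate", "low_bead_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        total = sum(f for _, f in self.repeat_fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("repeat_fractions must sum to 1")
        lo, hi = self.base_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("base_freq_range must be inside (0, 1)")

    def with_no_nuisance(self) -> "SimConfig":
        """The same design with every nuisance effect size set to zero."""
        return replace(self, batch_sd=0.0, cell_sd=0.0, sex_effect_sd=0.0,
                       age_effect_sd=0.0, control_batch_sd=0.0)


@dataclass
class SimulatedCohort:
    """A complete pipeline input set plus ground truth."""

    signals: SignalSet
    sheet: pd.DataFrame
    cell_props: pd.DataFrame
    control_probes: pd.DataFrame
    annotation: pd.DataFrame
    truth: dict
    config: SimConfig


def draw_group_allele_freqs(
    base_freq, fst: float, n_groups: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding–Nichols per-group allele frequencies.

    Each group draws independently from Beta(p(1−F)/F, (1−p)(1−F)/F), whose
    mean is the base frequency p and whose variance is F·p(1−p). Accepts a
    scalar or an array of base frequencies; returns shape (n_sites, n_groups).
    """
    p = np.atleast_1d(np.asarray(base_freq, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("base_freq must lie in (0, 1)")
    if not (0.0 < fst < 1.0):
        raise ValidationError("fst must lie in (0, 1)")
    if n_groups < 1:
        raise ValidationError("need >= 1 group")
    scale = (1.0 - fst) / fst
    draws = rng.beta(p[:, None] * scale, (1.0 - p)[:, None] * scale, size=(p.size, n_groups))
    return np.clip(draws, 1e-4, 1.0 - 1e-4)


def _dirichlet_alpha(n_celltypes: int) -> np.ndarray:
    base = np.array([10.0, 8.0, 5.0, 3.0, 2.0, 2.0])
    if n_celltypes <= base.size:
        return base[:n_celltypes]
    return np.concatenate([base, np.full(n_celltypes - base.size, 2.0)])


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one cohort under ``config`` (bit-identical for a fixed seed)."""
    rng = np.random.default_rng(config.seed)
    group_names = [g for g, _ in config.groups]
    n_groups = len(group_names)

    # --- individuals, repeats, demographics -------------------------------
    ind_ids, ind_group = [], []
    for gi, (gname, n_ind) in enumerate(config.groups):
        for j in range(n_ind):
            ind_ids.append(f"{gname}_I{j:03d}")
            ind_group.append(gi)
    n_ind_total = len(ind_ids)
    counts = np.array([c for c, _ in config.repeat_fractions])
    probs = np.array([f for _, f in config.repeat_fractions])
    n_samples_per_ind = rng.choice(counts, size=n_ind_total, p=probs)

    ind_sex = rng.integers(0, 2, size=n_ind_total)  # 0=F, 1=M
    ind_age = np.clip(rng.normal(40.0, 10.0, size=n_ind_total), 18.0, 80.0)
    if config.confounded:
        # skew sex and age distributions across groups
        for gi in range(n_groups):
            mask = np.asarray(ind_group) == gi
            ind_sex[mask] = rng.random(mask.sum()) < (0.3 + 0.4 * gi / max(n_groups - 1, 1))
            ind_age[mask] += 4.0 * (gi - (n_groups - 1) / 2)

    sample_ind, sample_ids = [], []
    for i in range(n_ind_total):
        for _ in range(int(n_samples_per_ind[i])):
            sample_ind.append(i)
            sample_ids.append(f"S{len(sample_ids):04d}")
    sample_ind = np.asarray(sample_ind)
    n = len(sample_ids)
    sample_group = np.asarray(ind_group)[sample_ind]
    sex = ind_sex[sample_ind].astype(float)
    age = ind_age[sample_ind]

    # --- batches (per sample; repeats redraw their batch) -----------------
    q = config.n_batch_factors
    batch_effects = rng.normal(0.0, 1.0, size=(config.n_batches, q))
    if config.confounded:
        pref = (sample_group % config.n_batches).astype(int)
        batch = np.where(rng.random(n) < 0.7, pref, rng.integers(0, config.n_batches, size=n))
    else:
        batch = rng.integers(0, config.n_batches, size=n)
    u_batch = batch_effects[batch]  # samples × factors

    # --- genotypes (Balding–Nichols; shared across an individual's repeats)
    n_sites = config.n_snp0bp + config.n_rs
    lo, hi = config.base_freq_range
    base_freq = rng.uniform(lo, hi, size=n_sites)
    group_freq = draw_group_allele_freqs(base_freq, config.fst, n_groups, rng)
    ind_freq = group_freq[:, np.asarray(ind_group)]          # sites × individuals
    ind_dosage = rng.binomial(2, ind_freq) / 2.0              # {0, 0.5, 1}
    dosage = ind_dosage[:, sample_ind]                        # sites × samples
    snp_dosage = dosage[: config.n_snp0bp]
    rs_dosage = dosage[config.n_snp0bp:]

    # --- cell proportions --------------------------------------------------
    alpha = _dirichlet_alpha(config.n_celltypes)
    if config.confounded:
        props = np.empty((n, config.n_celltypes))
        for gi in range(n_groups):
            mask = sample_group == gi
            a = alpha * (1.0 + 0.4 * gi / max(n_groups - 1, 1) * np.linspace(-1, 1, config.n_celltypes))
            props[mask] = rng.dirichlet(np.clip(a, 0.5, None), size=int(mask.sum()))
    else:
        props = rng.dirichlet(alpha, size=n)
    props_centered = props - alpha / alpha.sum()

    # --- beta targets -------------------------------------------------------
    means = np.asarray(config.genotype_means)
    lam_batch = rng.normal(0.0, config.batch_sd, size=(config.n_snp0bp, q))
    w_cell = rng.normal(0.0, config.cell_sd, size=(config.n_snp0bp, config.n_celltypes))
    w_sex = rng.normal(0.0, config.sex_effect_sd, size=config.n_snp0bp)
    w_age = rng.normal(0.0, config.age_effect_sd, size=config.n_snp0bp)
    snp_beta = (
        means[(snp_dosage * 2).astype(int)]
        + lam_batch @ u_batch.T
        + w_cell @ props_centered.T
        + w_sex[:, None] * sex[None, :]
        + w_age[:, None] * (age - 40.0)[None, :]
        + rng.normal(0.0, config.noise_sd, size=snp_dosage.shape)
    )
    # total rs batch SD is batch_sd / rs_batch_shrink regardless of factor count
    lam_rs = rng.normal(0.0, config.batch_sd / (config.rs_batch_shrink * np.sqrt(q)),
                        size=(config.n_rs, q))
    rs_beta = (
        means[(rs_dosage * 2).astype(int)]
        + lam_rs @ u_batch.T
        + rng.normal(0.0, config.noise_sd / 2.0, size=rs_dosage.shape)
    )
    decoy_base = rng.beta(2.0, 2.0, size=config.n_decoy)
    lam_decoy = rng.normal(0.0, config.batch_sd, size=(config.n_decoy, q))
    decoy_beta = (
        decoy_base[:, None]
        + lam_decoy @ u_batch.T
        + rng.normal(0.0, config.noise_sd, size=(config.n_decoy, n))
    )
    beta = np.clip(np.vstack([snp_beta, rs_beta, decoy_beta]), 0.001, 0.999)
    n_probes = beta.shape[0]

    # --- probe identities and channels -------------------------------------
    snp_ids = [f"cg{i:07d}" for i in range(config.n_snp0bp)]
    rs_ids = [f"rs{i:07d}" for i in range(config.n_rs)]
    decoy_ids = [f"cg{i:07d}" for i in range(config.n_snp0bp, config.n_snp0bp + config.n_decoy)]
    probe_ids = snp_ids + rs_ids + decoy_ids
    channel = rng.choice(np.array(["both", "grn", "red"]), size=n_probes, p=[0.6, 0.2, 0.2])

    # --- intensities --------------------------------------------------------
    total = rng.lognormal(np.log(config.mean_total_intensity), config.intensity_log_sd,
                          size=(n_probes, n))
    meth_sig = beta * (total + BETA_OFFSET)
    unmeth_sig = np.clip(total - meth_sig, 0.0, None)
    meth = meth_sig + rng.normal(config.background_mean, 10.0, size=meth_sig.shape)
    unmeth = unmeth_sig + rng.normal(config.background_mean, 10.0, size=unmeth_sig.shape)

    fail = rng.random((n_probes, n)) < config.detect_fail_rate
    meth[fail] = rng.normal(config.background_mean / 2.0, 20.0, size=int(fail.sum()))
    unmeth[fail] = rng.normal(config.background_mean / 2.0, 20.0, size=int(fail.sum()))
    meth = np.clip(meth, 1.0, None)
    unmeth = np.clip(unmeth, 1.0, None)

    beads = rng.poisson(12.0, size=(n_probes, n)) + 3
    low = rng.random((n_probes, n)) < config.low_bead_rate
    beads[low] = rng.integers(0, 3, size=int(low.sum()))

    # --- negative controls and control probes -------------------------------
    neg_rows = []
    for sid in sample_ids:
        for ch in ("grn", "red"):
            vals = np.clip(rng.normal(config.background_mean, config.background_sd,
                                      size=config.n_neg_per_channel), 1.0, None)
            for v in vals:
                neg_rows.append((sid, ch, v))
    neg_controls = pd.DataFrame(neg_rows, columns=["sample_id", "channel", "intensity"])

    gamma = rng.normal(0.0, config.control_batch_sd, size=(config.n_control, q))
    log2_ctrl = (
        np.log2(2000.0)
        + u_batch @ gamma.T
        + rng.normal(0.0, config.control_noise_sd, size=(n, config.n_control))
    )
    control_probes = pd.DataFrame(2.0**log2_ctrl, index=pd.Index(sample_ids, name="sample_id"),
                                  columns=[f"ctl{i:04d}" for i in range(config.n_control)])

    # --- assemble tables -----------------------------------------------------
    cols = pd.Index(sample_ids, name="sample_id")
    idx = pd.Index(probe_ids, name="probe_id")
    signals = SignalSet(
        meth=pd.DataFrame(meth, index=idx, columns=cols),
        unmeth=pd.DataFrame(unmeth, index=idx, columns=cols),
        bead_counts=pd.DataFrame(beads, index=idx, columns=cols),
        neg_controls=neg_controls,
        probe_channel=pd.Series(channel, index=idx, name="channel"),
    )
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "individual_id": [ind_ids[i] for i in sample_ind],
        "sex": np.where(sex > 0.5, "M", "F"),
        "age": age,
        "ancestry_label": [group_names[g] for g in sample_group],
        "batch": [f"batch{b}" for b in batch],
    })
    cell_props = pd.DataFrame(props, index=cols.copy(),
                              columns=[f"cell{t}" for t in range(config.n_celltypes)])

    maf = np.minimum(base_freq, 1.0 - base_freq)
    ann_rows = []
    for i, pid in enumerate(snp_ids):
        ann_rows.append((pid, "cpg", 0.0, maf[i]))
    for i, pid in enumerate(rs_ids):
        ann_rows.append((pid, "rs", 0.0, maf[config.n_snp0bp + i]))
    for i, pid in enumerate(decoy_ids):
        kind = i % 3
        if kind == 0:
            ann_rows.append((pid, "cpg", np.nan, np.nan))       # no SNP overlap recorded
        elif kind == 1:
            ann_rows.append((pid, "cpg", 5.0, 0.30))            # nearby but not overlapping
        else:
            ann_rows.append((pid, "cpg", 0.0, 0.02))            # overlapping but rare
    annotation = pd.DataFrame(ann_rows, columns=["probe_id", "probe_kind", "snp_distance", "maf"])
    annotation["design_type"] = np.where(channel == "both", "II", "I")
    annotation["channel"] = channel
    annotation["array"] = "EPICv1"
    annotation["control_category"] = None

    # genotype-PC surrogate: PCA of the group one-hot matrix, padded to 3 columns
    onehot = np.eye(n_groups)[sample_group]
    scores, _, _, rank = centered_pca(onehot)
    surrogate = np.zeros((n, 3))
    take = min(3, rank)
    surrogate[:, :take] = scores[:, :take]
    for j in range(take, 3):
        surrogate[:, j] = rng.normal(0.0, 0.01, size=n)
    geno_pcs = pd.DataFrame(surrogate, index=cols.copy(), columns=["gt_PC1", "gt_PC2", "gt_PC3"])

    truth = {
        "group": pd.Series([group_names[g] for g in sample_group], index=cols.copy(), name="group"),
        "group_code": pd.Series(sample_group.astype(int), index=cols.copy(), name="group_code"),
        "genotypes": pd.DataFrame(dosage, index=pd.Index(snp_ids + rs_ids, name="probe_id"),
                                  columns=cols.copy()),
        "geno_pcs": geno_pcs,
        "batch": pd.Series([f"batch{b}" for b in batch], index=cols.copy(), name="batch"),
        "batch_effect": pd.DataFrame(u_batch, index=cols.copy(),
                                     columns=[f"factor{j + 1}" for j in range(q)]),
    }
    return SimulatedCohort(signals, sheet, cell_props, control_probes, annotation, truth, config)


def write_cohort(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as the TSV set the pipeline reads, plus truth/ tables."""
    from . import io as mio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "meth": directory / "meth.tsv",
        "unmeth": directory / "unmeth.tsv",
        "beadcounts": directory / "beadcounts.tsv",
        "negcontrols": directory / "negcontrols.tsv",
        "samplesheet": directory / "samplesheet.tsv",
        "cellprops": directory / "cellprops.tsv",
        "controlprobes": directory / "controlprobes.tsv",
        "annotation": directory / "annotation.tsv",
    }
    mio.write_matrix(cohort.signals.meth, paths["meth"])
    mio.write_matrix(cohort.signals.unmeth, paths["unmeth"])
    mio.write_matrix(cohort.signals.bead_counts, paths["beadcounts"])
    cohort.signals.neg_controls.to_csv(paths["negcontrols"], sep="\t", index=False)
    cohort.sheet.to_csv(paths["samplesheet"], sep="\t", index=False)
    cohort.cell_props.to_csv(paths["cellprops"], sep="\t")
    cohort.control_probes.to_csv(paths["controlprobes"], sep="\t")
    ann = cohort.annotation.copy()
    ann.to_csv(paths["annotation"], sep="\t", index=False, na_rep="NA")

    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    mio.write_matrix(cohort.truth["genotypes"], truth_dir / "genotypes.tsv")
    cohort.truth["geno_pcs"].to_csv(truth_dir / "geno_pcs.tsv", sep="\t")
    pd.DataFrame({
        "sample_id": cohort.truth["group"].index,
        "group": cohort.truth["group"].to_numpy(),
        "group_code": cohort.truth["group_code"].to_numpy(),
        "batch": cohort.truth["batch"].to_numpy(),
    }).to_csv(truth_dir / "groups.tsv", sep="\t", index=False)
    return paths
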
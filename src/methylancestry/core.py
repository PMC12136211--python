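"""The ancestry-PC method itself.

Three variants are produced and compared throughout the package:

``raw``
    PCA on the row-centered beta values of SNP-overlapping (SNP0bp) CpG
    probes, with no adjustment — the classic baseline. Its first PC is often
    dominated by batch or cell-composition variation rather than ancestry.
``residualized``
    Each SNP0bp probe's betas are first residualized against the nuisance
    design (intercept, sex, age, cell-proportion PCs, ten control-probe PCs);
    PCA on the residuals.
``combined``
    The residualized SNP0bp rows are stacked with genotype calls from the
    array's rs probes (beta-thresholded to dosages 0 / 0.5 / 1), then PCA.
    Genotypes are noise-free ancestry signal, so this variant is the most
    robust when technical effects are strong.

All PCAs are center-only (samples as observations), signs are fixed by the
largest-magnitude loading, and score columns are additionally min-max scaled
to [0, 1] so the variants are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ConfigurationError, ValidationError, centered_pca, minmax_scale_columns

logger = logging.getLogger(__name__)

METHOD_RAW = "raw"
METHOD_RESIDUALIZED = "residualized"
METHOD_COMBINED = "combined"
METHODS = (METHOD_RAW, METHOD_RESIDUALIZED, METHOD_COMBINED)


def residualize(beta: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-probe OLS residuals of beta values on the nuisance design.

    ``beta`` is probes × samples with no missing entries (post-imputation);
    ``design`` is samples × covariates, full rank, same sample order. One
    least-squares solve is shared across probes. Residual rows are orthogonal
    to every design column (the intercept makes them mean-centered).
    """
    if list(beta.columns) != list(design.index):
        raise ValidationError("beta sample order does not match the design matrix")
    b = beta.to_numpy(float)
    if np.isnan(b).any():
        raise ValidationError("beta matrix contains missing values; impute first")
    x = design.to_numpy(float)
    coef, _, rank, _ = np.linalg.lstsq(x, b.T, rcond=None)
    if rank < x.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    resid = b.T - x @ coef
    return pd.DataFrame(resid.T, index=beta.index, columns=beta.columns)


def call_rs_genotypes(
    rs_beta: pd.DataFrame, low: float = 0.25, high: float = 0.75
) -> pd.DataFrame:
    """Call genotypes from rs-probe betas by fixed thresholds.

    rs probes are engineered to be trimodal across genotypes, so simple
    thresholds suffice: beta < ``low`` → 0, ``low`` ≤ beta ≤ ``high`` → 0.5
    (boundaries fall into the heterozygote), beta > ``high`` → 1. Values are
    dosage/2; missing propagates.
    """
    if low >= high:
        raise ConfigurationError(f"genotype thresholds out of order: low={low} >= high={high}")
    b = rs_beta.to_numpy(float)
    calls = np.where(b < low, 0.0, np.where(b > high, 1.0, 0.5))
    calls = np.where(np.isnan(b), np.nan, calls)
    return pd.DataFrame(calls, index=rs_beta.index, columns=rs_beta.columns)


def combine_features(residuals: pd.DataFrame, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Stack residualized SNP0bp rows with genotype rows and center every row.

    Genotype rows with any missing call are dropped (logged). If no genotype
    row survives, the result equals the centered residuals and the combined
    method degenerates to the residualized one.
    """
    if list(residuals.columns) != list(genotypes.columns) and len(genotypes):
        raise ValidationError("residuals and genotypes cover different samples")
    complete = genotypes.dropna(axis=0)
    dropped = len(genotypes) - len(complete)
    if dropped:
        logger.info("dropped %d genotype row(s) with missing calls", dropped)
    if complete.empty:
        logger.warning("no usable genotype rows; combined features equal residualized features")
        stacked = residuals.copy()
    else:
        stacked = pd.concat([residuals, complete])
    vals = stacked.to_numpy(float)
    vals = vals - vals.mean(axis=1, keepdims=True)
    return pd.DataFrame(vals, index=stacked.index, columns=residuals.columns)


@dataclass
class AncestryPCs:
    """Sample scores on the ancestry PCs of one method variant.

    ``scores`` columns are min-max scaled to [0, 1]; ``raw_scores`` are the
    unscaled SVD scores (useful when the scaling's loss of overall scale
    matters); ``explained_variance`` holds the per-PC variance fractions
    computed before scaling.
    """

    method: str
    scores: pd.DataFrame
    raw_scores: pd.DataFrame
    explained_variance: np.ndarray = field(repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scores.rename_axis("sample_id").to_csv(directory / f"ancestry_pcs_{self.method}.tsv", sep="\t")
        self.raw_scores.rename_axis("sample_id").to_csv(
            directory / f"ancestry_pcs_raw_scores_{self.method}.tsv", sep="\t"
        )
        pd.DataFrame(
            {"pc": [f"PC{i + 1}" for i in range(len(self.explained_variance))],
             "variance_fraction": self.explained_variance}
        ).to_csv(directory / f"variance_explained_{self.method}.tsv", sep="\t", index=False)


def ancestry_pca(features: pd.DataFrame, k: int = 10, method: str = METHOD_COMBINED) -> AncestryPCs:
    """Compute ancestry PCs from a feature matrix (features × samples).

    Samples are the observations; rows are expected to be (approximately)
    centered already, and no variance scaling is applied. ``k`` is clipped to
    the numerical rank with a warning. Explained-variance fractions are
    computed from the singular values before any scaling.
    """
    x = features.to_numpy(float).T  # samples × features
    n = x.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 samples for PCA")
    scores, _, s, rank = centered_pca(x)
    k_eff = min(k, rank, n - 1, x.shape[1])
    if k_eff < k:
        logger.warning("requested %d PCs but only %d available; clipping", k, k_eff)
    total = float((s**2).sum())
    ev = (s[:k_eff] ** 2) / total if total > 0 else np.zeros(k_eff)
    raw = scores[:, :k_eff]
    cols = [f"PC{i + 1}" for i in range(k_eff)]
    idx = pd.Index(features.columns, name="sample_id")
    return AncestryPCs(
        method=method,
        scores=pd.DataFrame(minmax_scale_columns(raw), index=idx, columns=cols),
        raw_scores=pd.DataFrame(raw, index=idx, columns=cols),
        explained_variance=ev,
    )


def baseline_pcs(beta: pd.DataFrame, k: int = 10) -> AncestryPCs:
    """The unadjusted baseline: PCA on row-centered raw SNP0bp betas."""
    vals = beta.to_numpy(float)
    if np.isnan(vals).any():
        raise ValidationError("beta matrix contains missing values; impute first")
    centered = vals - vals.mean(axis=1, keepdims=True)
    features = pd.DataFrame(centered, index=beta.index, columns=beta.columns)
    return ancestry_pca(features, k=k, method=METHOD_RAW)
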
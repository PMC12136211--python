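"""Nuisance covariates for residualization.

The method removes linear effects of technical and biological factors before
computing ancestry PCs: ten principal components of the (log2) control-probe
intensities summarize batch/technical variation, principal components of the
estimated cell-type proportions summarize cellular heterogeneity, and sex and
age enter directly. This module builds those covariates and assembles the
full-rank design matrix used for residualization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import qr

from ._utils import ValidationError, centered_pca

logger = logging.getLogger(__name__)

SEX_CODES = {"F": 0.0, "M": 1.0}


def control_probe_pcs(control_intensities: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """Sample scores on the first ``n_pcs`` PCs of log2 control intensities.

    ``control_intensities`` is samples × control probes with positive values
    (both channels concatenated as features). Intensities are log2
    transformed and column-centered; no variance scaling. If the centered
    matrix has rank below ``n_pcs`` all available PCs are returned with a
    warning.
    """
    vals = control_intensities.to_numpy(float)
    if np.nanmin(vals) <= 0:
        raise ValidationError("control intensities must be positive for log2 transform")
    scores, _, _, rank = centered_pca(np.log2(vals))
    take = min(n_pcs, rank)
    if take < n_pcs:
        logger.warning("control-probe matrix rank %d < requested %d PCs", rank, n_pcs)
    return pd.DataFrame(
        scores[:, :take],
        index=control_intensities.index,
        columns=[f"ctrlPC{i + 1}" for i in range(take)],
    )


def cell_proportion_pcs(props: pd.DataFrame) -> pd.DataFrame:
    """PCs of the cell-type proportion matrix (samples × cell types).

    Proportions are compositional (rows sum to one), so the centered matrix
    has rank at most d−1; the first d−1 score columns are returned.
    """
    vals = props.to_numpy(float)
    d = vals.shape[1]
    if d < 2:
        raise ValidationError("need >= 2 cell types for cell-proportion PCs")
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValidationError("cell proportions must lie in [0, 1]")
    sums = vals.sum(axis=1)
    if np.abs(sums - 1.0).max() > 0.02:
        bad = props.index[np.abs(sums - 1.0) > 0.02][0]
        raise ValidationError(f"cell proportions for {bad!r} do not sum to 1 (+/- 0.02)")
    scores, _, _, rank = centered_pca(vals)
    take = min(d - 1, rank)
    out = np.zeros((vals.shape[0], d - 1))
    out[:, :take] = scores[:, :take]
    return pd.DataFrame(out, index=props.index, columns=[f"cellPC{i + 1}" for i in range(d - 1)])


def build_design(
    sheet: pd.DataFrame,
    cell_pcs: pd.DataFrame,
    control_pcs: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the residualization design: intercept, sex, age, cell PCs, control PCs.

    Sex is coded F=0 / M=1; age enters in years untransformed. All three
    inputs must cover the same samples in the same order. The design must be
    full column rank; collinear columns are named in the error (e.g. a
    constant sex column in a single-sex cohort).
    """
    sample_ids = list(sheet["sample_id"])
    for name, other in (("cell PCs", cell_pcs), ("control PCs", control_pcs)):
        if list(other.index) != sample_ids:
            raise ValidationError(f"{name} sample order does not match the sample sheet")

    missing = sheet.index[sheet["sex"].isna() | sheet["age"].isna()]
    if len(missing):
        bad = list(sheet.loc[missing, "sample_id"])
        raise ValidationError(f"missing sex/age for samples {bad[:5]}")
    sex = sheet["sex"].map(SEX_CODES)
    if sex.isna().any():
        raise ValidationError("sex must be coded F or M")

    design = pd.DataFrame({"intercept": 1.0, "sex": sex.to_numpy(), "age": sheet["age"].to_numpy(float)},
                          index=pd.Index(sample_ids, name="sample_id"))
    design = pd.concat([design, cell_pcs.set_axis(design.index), control_pcs.set_axis(design.index)], axis=1)

    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        collinear = [design.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        collinear += [design.columns[p] for p in piv[len(diag):]]
        raise ValidationError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {collinear} — drop them (e.g. sex in a single-sex cohort)"
        )
    return design
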
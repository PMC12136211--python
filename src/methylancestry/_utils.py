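"""Shared numerical helpers: exceptions, deterministic PCA, sign conventions."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("methylancestry")


class ValidationError(ValueError):
    """Input data violates a documented precondition or invariant."""


class FormatError(ValueError):
    """A file or table does not match the expected layout."""


class ConfigurationError(ValueError):
    """Parameters are inconsistent (e.g. genotype thresholds out of order)."""


def fix_component_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Flip each component so its largest-magnitude loading is positive.

    PCA components are defined only up to sign; fixing the sign by the
    dominant loading makes scores reproducible across runs and platforms.
    Operates in place on both arrays (columns are components).
    """
    for j in range(scores.shape[1]):
        col = loadings[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]


def centered_pca(x: np.ndarray):
    """Center-only PCA of an observations × variables matrix via SVD.

    Returns ``(scores, loadings, singular_values, rank)`` where scores and
    loadings are truncated to the numerical rank and signs follow
    :func:`fix_component_signs`. No variance scaling is applied.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    try:
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
    except np.linalg.LinAlgError:
        # the divide-and-conquer driver occasionally fails to converge on
        # valid input; the slower QR-based driver is robust
        from scipy.linalg import svd as _svd

        u, s, vt = _svd(xc, full_matrices=False, lapack_driver="gesvd")
    if s.size == 0 or s[0] <= 0.0:
        rank = 0
    else:
        tol = s[0] * max(x.shape) * np.finfo(float).eps
        rank = int((s > tol).sum())
    scores = u[:, :rank] * s[:rank]
    loadings = vt[:rank].T.copy()
    fix_component_signs(scores, loadings)
    return scores, loadings, s, rank


def minmax_scale_columns(x: np.ndarray) -> np.ndarray:
    """Scale each column to [0, 1]; constant columns map to zeros."""
    x = np.asarray(x, dtype=float)
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    out = np.zeros_like(x)
    ok = span > 0
    out[:, ok] = (x[:, ok] - lo[ok]) / span[ok]
    if not ok.all():
        logger.warning("min-max scaling: %d constant column(s) set to 0", (~ok).sum())
    return out
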
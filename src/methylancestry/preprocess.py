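"""Signal-level preprocessing for the selected probes.

The chain mirrors standard Illumina array practice restricted to the
ancestry-informative probes: background correction against negative-control
probes, detection p-values, masking of failed detections, probe-level QC
(bead counts, call rates), across-sample quantile normalization of the
methylated and unmethylated intensities, beta computation, and k-nearest-
neighbour imputation of the remaining missing betas.

All matrices are pandas DataFrames with probes as rows and samples as
columns; missing values are NaN (serialized as ``NA``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ValidationError

logger = logging.getLogger(__name__)

CHANNELS = ("grn", "red")

#: background-corrected intensities never drop below this floor (arbitrary units)
INTENSITY_FLOOR = 1.0
#: lower bound on the background SD used for detection p-values
SIGMA_FLOOR = 1e-6


@dataclass
class SignalSet:
    """Raw intensities and controls for a cohort.

    ``meth``/``unmeth``/``bead_counts`` share the probe index and sample
    columns. ``neg_controls`` is long format with columns
    ``sample_id, channel, intensity``. ``probe_channel`` maps each probe to
    ``grn``/``red`` (type-I designs) or ``both`` (type II: methylated signal
    on the green channel, unmethylated on red).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    bead_counts: pd.DataFrame
    neg_controls: pd.DataFrame
    probe_channel: pd.Series

    def __post_init__(self) -> None:
        for name in ("unmeth", "bead_counts"):
            other = getattr(self, name)
            if not other.index.equals(self.meth.index) or not other.columns.equals(self.meth.columns):
                raise ValidationError(f"{name} does not share the meth matrix index")
        if not self.probe_channel.index.equals(self.meth.index):
            self.probe_channel = self.probe_channel.reindex(self.meth.index)
            if self.probe_channel.isna().any():
                raise ValidationError("probe_channel missing for some probes")
        for name in ("meth", "unmeth"):
            vals = getattr(self, name).to_numpy(float)
            if vals.size and np.nanmin(vals) < 0:
                raise ValidationError(f"negative intensities in {name}")
        missing = {"sample_id", "channel", "intensity"} - set(self.neg_controls.columns)
        if missing:
            raise ValidationError(f"neg_controls lacks columns {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    def subset_probes(self, probe_ids) -> "SignalSet":
        probe_ids = [p for p in probe_ids if p in self.meth.index]
        return SignalSet(
            self.meth.loc[probe_ids],
            self.unmeth.loc[probe_ids],
            self.bead_counts.loc[probe_ids],
            self.neg_controls,
            self.probe_channel.loc[probe_ids],
        )


def _negctrl_arrays(signals: SignalSet) -> dict[tuple[str, str], np.ndarray]:
    out: dict[tuple[str, str], np.ndarray] = {}
    for (sid, ch), grp in signals.neg_controls.groupby(["sample_id", "channel"], sort=False):
        out[(str(sid), str(ch))] = grp["intensity"].to_numpy(float)
    return out


def background_correct(signals: SignalSet) -> SignalSet:
    """Subtract a per-sample, per-channel background estimate.

    The background is the 5th percentile of that sample/channel's
    negative-control intensities; corrected intensities are floored at
    ``INTENSITY_FLOOR`` so downstream log/ratio steps stay defined. Type-II
    probes route methylated signal to the green channel background and
    unmethylated to red.
    """
    ctrls = _negctrl_arrays(signals)
    samples = signals.sample_ids
    bg = {}
    for ch in CHANNELS:
        vals = []
        for sid in samples:
            arr = ctrls.get((sid, ch))
            if arr is None or arr.size == 0:
                raise ValidationError(f"sample {sid}: no negative controls on channel {ch}")
            vals.append(np.percentile(arr, 5))
        bg[ch] = np.asarray(vals)

    chan = signals.probe_channel.to_numpy()
    # per-probe background for the meth and unmeth signals
    meth_bg = np.where((chan == "grn") | (chan == "both"), 1.0, 0.0)[:, None] * bg["grn"][None, :] + (
        chan == "red"
    )[:, None] * bg["red"][None, :]
    unmeth_bg = np.where((chan == "red") | (chan == "both"), 1.0, 0.0)[:, None] * bg["red"][None, :] + (
        chan == "grn"
    )[:, None] * bg["grn"][None, :]

    meth = np.maximum(signals.meth.to_numpy(float) - meth_bg, INTENSITY_FLOOR)
    unmeth = np.maximum(signals.unmeth.to_numpy(float) - unmeth_bg, INTENSITY_FLOOR)
    return SignalSet(
        pd.DataFrame(meth, index=signals.meth.index, columns=signals.meth.columns),
        pd.DataFrame(unmeth, index=signals.meth.index, columns=signals.meth.columns),
        signals.bead_counts,
        signals.neg_controls,
        signals.probe_channel,
    )


def detection_pvalues(signals: SignalSet) -> pd.DataFrame:
    """Probability that a probe's total signal arises from background.

    For each probe/sample the total intensity (meth + unmeth, uncorrected) is
    compared with a normal background model whose mean and SD come from the
    negative controls of the probe's channel for that sample (type-II probes
    pool both channels); p is the upper-tail probability. Low p means real
    signal.
    """
    ctrls = _negctrl_arrays(signals)
    samples = signals.sample_ids
    mu = {ch: np.empty(len(samples)) for ch in (*CHANNELS, "both")}
    sd = {ch: np.empty(len(samples)) for ch in (*CHANNELS, "both")}
    for i, sid in enumerate(samples):
        per_ch = {}
        for ch in CHANNELS:
            arr = ctrls.get((sid, ch))
            if arr is None or arr.size < 2:
                raise ValidationError(f"sample {sid}: need >= 2 negative controls on channel {ch}")
            per_ch[ch] = arr
            mu[ch][i] = arr.mean()
            sd[ch][i] = arr.std(ddof=1)
        pooled = np.concatenate([per_ch["grn"], per_ch["red"]])
        mu["both"][i] = pooled.mean()
        sd["both"][i] = pooled.std(ddof=1)

    chan = signals.probe_channel.to_numpy()
    mu_mat = np.empty(signals.meth.shape)
    sd_mat = np.empty(signals.meth.shape)
    for ch in ("grn", "red", "both"):
        rows = chan == ch
        mu_mat[rows] = mu[ch][None, :]
        sd_mat[rows] = sd[ch][None, :]
    total = signals.meth.to_numpy(float) + signals.unmeth.to_numpy(float)
    p = stats.norm.sf(total, loc=mu_mat, scale=np.maximum(sd_mat, SIGMA_FLOOR))
    return pd.DataFrame(p, index=signals.meth.index, columns=signals.meth.columns)


def mask_failed_detections(values: pd.DataFrame, p: pd.DataFrame, threshold: float = 1e-16) -> pd.DataFrame:
    """Set entries whose detection p exceeds ``threshold`` to missing."""
    if not values.index.equals(p.index) or not values.columns.equals(p.columns):
        raise ValidationError("detection p-value matrix does not match data shape")
    mask = p.to_numpy() > threshold
    out = values.to_numpy(float).copy()
    out[mask] = np.nan
    n = int(mask.sum())
    if n:
        logger.info("masked %d entries with detection p > %g", n, threshold)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def filter_probes_qc(
    missing: pd.DataFrame,
    bead_counts: pd.DataFrame,
    bead_min: int = 3,
    bead_frac: float = 0.05,
    miss_frac: float = 0.10,
) -> list[str]:
    """Probe-level QC: exclude low-bead-count and low-call-rate probes.

    A probe is removed when *strictly more* than ``bead_frac`` of samples have
    a bead count below ``bead_min``, or strictly more than ``miss_frac`` of
    samples are missing. Boundary fractions are retained. Returns the retained
    probe ids in input order.
    """
    if not missing.index.equals(bead_counts.index) or not missing.columns.equals(bead_counts.columns):
        raise ValidationError("missingness and bead-count matrices do not share an index")
    n = missing.shape[1]
    if n == 0:
        raise ValidationError("no samples")
    low_bead = (bead_counts.to_numpy(float) < bead_min).mean(axis=1)
    miss = missing.to_numpy(bool).mean(axis=1)
    keep = ~((low_bead > bead_frac) | (miss > miss_frac))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("QC filter removed %d/%d probes", dropped, len(keep))
    return list(missing.index[keep])


def quantile_normalize(x: pd.DataFrame) -> pd.DataFrame:
    """Classic across-sample quantile normalization, missing-aware.

    The reference distribution is the mean across samples of each sample's
    empirical quantile function. Each observed value is replaced by the
    reference quantile at its (average, tie-aware) rank; missing entries are
    excluded from ranking and restored as missing. With complete, tie-free
    data this reduces to replacing each column's sorted values by the mean of
    order statistics across columns, so all columns end up with an identical
    sorted multiset.
    """
    vals = x.to_numpy(float)
    n, m = vals.shape
    if m < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    obs_counts = (~np.isnan(vals)).sum(axis=0)
    if (obs_counts == 0).any():
        bad = x.columns[obs_counts == 0][0]
        raise ValidationError(f"column {bad!r} is entirely missing")

    grid = (np.arange(n) + 0.5) / n
    ref = np.zeros(n)
    for j in range(m):
        col = np.sort(vals[~np.isnan(vals[:, j]), j])
        k = col.size
        ref += np.interp(grid, (np.arange(k) + 0.5) / k, col)
    ref /= m

    out = np.full_like(vals, np.nan)
    for j in range(m):
        obs = ~np.isnan(vals[:, j])
        col = vals[obs, j]
        k = col.size
        ranks = stats.rankdata(col, method="average")  # 1-based, ties averaged
        out[obs, j] = np.interp((ranks - 0.5) / k, grid, ref)
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def compute_beta(meth: pd.DataFrame, unmeth: pd.DataFrame, offset: float = 100.0) -> pd.DataFrame:
    """Beta = M / (M + U + offset); missing propagates."""
    if not meth.index.equals(unmeth.index) or not meth.columns.equals(unmeth.columns):
        raise ValidationError("meth/unmeth shape mismatch")
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    m = meth.to_numpy(float)
    u = unmeth.to_numpy(float)
    if m.size and (np.nanmin(m) < 0 or np.nanmin(u) < 0):
        raise ValidationError("negative intensities")
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = m / (m + u + offset)
    beta = np.where(np.isnan(m) | np.isnan(u), np.nan, beta)
    # 0/0 with offset 0 would be undefined; offset > 0 yields 0 there
    beta = np.where((m == 0) & ~np.isnan(beta), 0.0, beta)
    return pd.DataFrame(beta, index=meth.index, columns=meth.columns)


def impute_knn(beta: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute missing betas from the k nearest probes.

    Distances between probe rows are root-mean-square differences over
    jointly observed samples. A missing entry is the 1/distance-weighted mean
    of the values of the k nearest probes observed at that sample
    (zero-distance twins dominate exactly); if fewer than k usable neighbours
    exist the probe's row mean is used. Output is complete with all values in
    [0, 1].
    """
    vals = beta.to_numpy(float).copy()
    obs = ~np.isnan(vals)
    if not obs.any(axis=1).all():
        bad = beta.index[~obs.any(axis=1)][0]
        raise ValidationError(f"probe {bad!r} has no observed values")
    miss_rows = np.where(~obs.all(axis=1))[0]
    if miss_rows.size == 0:
        return beta.copy()

    x0 = np.where(obs, vals, 0.0)
    m = obs.astype(float)
    sq = x0**2
    cross = x0 @ x0.T
    a = sq @ m.T  # sum over jointly observed of x_i^2
    counts = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (a + a.T - 2.0 * cross) / counts
    d = np.sqrt(np.maximum(d2, 0.0))  # NaN where no joint support
    np.fill_diagonal(d, np.nan)

    row_means = np.nansum(vals, axis=1) / obs.sum(axis=1)
    out = vals
    for i in miss_rows:
        for j in np.where(~obs[i])[0]:
            cand = np.where(obs[:, j] & np.isfinite(d[:, i]))[0]
            if cand.size < k:
                out[i, j] = row_means[i]
                continue
            nearest = cand[np.argsort(d[cand, i], kind="stable")[:k]]
            dn = d[nearest, i]
            if (dn == 0).any():
                out[i, j] = vals[nearest[dn == 0], j].mean()
            else:
                w = 1.0 / dn
                out[i, j] = float(np.dot(w, vals[nearest, j]) / w.sum())
    out = np.clip(out, 0.0, 1.0)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)
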
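"""Performance battery for comparing ancestry-PC variants.

Clustering quality of the first three (0–1 scaled) ancestry PCs is assessed
at the ancestry-group level and, where repeated samples exist, at the
individual level: silhouette scores, 3D centroids with within-cluster mean
distances, and between-centroid distance matrices. Association of each PC
with the ancestry grouping uses a one-way ANOVA gated on its assumptions
(Shapiro–Wilk normality of residuals, median-centered Levene homogeneity),
falling back to Kruskal–Wallis. Cohorts with genotyping data additionally get
the 3×3 grid of absolute Pearson correlations between ancestry and genotyping
PCs. Covariate-vs-group screening with repeated samples uses a random-
intercept mixed model compared by likelihood-ratio test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from ._utils import ValidationError

logger = logging.getLogger(__name__)


def silhouette(points: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample silhouette scores and their mean (Euclidean distance).

    s(i) = (b − a) / max(a, b) with a the mean distance to the sample's own
    cluster (excluding itself) and b the smallest mean distance to another
    cluster. Samples in singleton clusters score 0, as does the degenerate
    a = b = 0 case. Values always lie in [−1, 1].
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette undefined for a single cluster")
    d = cdist(points, points)
    members = {lab: np.where(labels == lab)[0] for lab in uniq}
    s = np.zeros(len(points))
    for i in range(len(points)):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (own.size - 1)
        b = min(d[i, members[lab]].mean() for lab in uniq if lab != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def group_multiple_correlation(scores: np.ndarray, labels: np.ndarray) -> float:
    """Multiple correlation between one PC and the group factor.

    The square root of the one-way R² (between-group over total sum of
    squares). For two groups this equals |Pearson r| with the binary group
    code; for more groups it measures correlation with the group structure
    without depending on an arbitrary numeric ordering of the labels.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    gm = x.mean()
    ss_tot = float(((x - gm) ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("constant scores; correlation undefined")
    ss_between = 0.0
    for g in np.unique(labels):
        idx = labels == g
        ss_between += idx.sum() * (x[idx].mean() - gm) ** 2
    return float(np.sqrt(ss_between / ss_tot))


def cluster_centroids(points: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-label centroid coordinates and within-cluster mean distance."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    rows = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if idx.size == 0:
            logger.warning("label %r has no members; excluded", lab)
            continue
        c = points[idx].mean(axis=0)
        dist = float(np.linalg.norm(points[idx] - c, axis=1).mean())
        rows.append({"label": lab, **{f"dim{j + 1}": c[j] for j in range(points.shape[1])},
                     "mean_distance": dist, "n": int(idx.size)})
    return pd.DataFrame(rows).set_index("label")


def centroid_distance_matrix(centroids: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between cluster centroids."""
    if len(centroids) < 2:
        raise ValidationError("need >= 2 centroids for a distance matrix")
    coords = centroids[[c for c in centroids.columns if c.startswith("dim")]].to_numpy(float)
    d = cdist(coords, coords)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=centroids.index, columns=centroids.index)


@dataclass
class AssociationResult:
    """Outcome of one group-association test with its assumption diagnostics."""

    test_used: str
    statistic: float
    p_value: float
    pc_index: int | None = None
    assumption_notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def pc_group_association(
    scores: np.ndarray, labels: np.ndarray, alpha_assume: float = 0.05, pc_index: int | None = None
) -> AssociationResult:
    """Assumption-gated one-way test of a PC against group labels.

    Groups with fewer than 3 members are excluded (logged). Normality of the
    one-way-fit residuals (Shapiro–Wilk) and variance homogeneity
    (median-centered Levene) are tested at ``alpha_assume``; if both hold a
    one-way ANOVA is used, otherwise Kruskal–Wallis.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    usable = groups[counts >= 3]
    if (counts < 3).any():
        logger.info("excluding %d group(s) with < 3 members from association test",
                    int((counts < 3).sum()))
    if usable.size < 2:
        raise ValidationError("need >= 2 groups with >= 3 members")
    per_group = [scores[labels == g] for g in usable]
    resid = np.concatenate([g - g.mean() for g in per_group])
    if np.ptp(resid) == 0:
        raise ValidationError("zero within-group variance; assumption tests degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sh_p = float(stats.shapiro(resid).pvalue)
    lev_p = float(stats.levene(*per_group, center="median").pvalue)
    notes = {"shapiro_p": sh_p, "levene_p": lev_p}
    if sh_p > alpha_assume and lev_p > alpha_assume:
        stat, p = stats.f_oneway(*per_group)
        return AssociationResult("anova", float(stat), float(p), pc_index, notes)
    stat, p = stats.kruskal(*per_group)
    return AssociationResult("kruskal_wallis", float(stat), float(p), pc_index, notes)


def pc_genotype_correlation(
    ancestry_pcs: pd.DataFrame, geno_pcs: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """|Pearson r| grid between the first three ancestry and genotyping PCs.

    Constant columns give undefined (NaN) cells, excluded from the mean.
    """
    a = ancestry_pcs.to_numpy(float)[:, :3]
    g = geno_pcs.to_numpy(float)[:, :3]
    if a.shape[0] != g.shape[0]:
        raise ValidationError("ancestry and genotyping PCs cover different samples")
    grid = np.full((a.shape[1], g.shape[1]), np.nan)
    for i in range(a.shape[1]):
        for j in range(g.shape[1]):
            if np.ptp(a[:, i]) == 0 or np.ptp(g[:, j]) == 0:
                logger.warning("constant PC column; correlation cell (%d, %d) undefined", i + 1, j + 1)
                continue
            grid[i, j] = abs(float(stats.pearsonr(a[:, i], g[:, j]).statistic))
    out = pd.DataFrame(grid,
                       index=[f"PC{i + 1}" for i in range(a.shape[1])],
                       columns=[f"gt_PC{j + 1}" for j in range(g.shape[1])])
    return out, float(np.nanmean(grid))


def mixed_model_group_lrt(
    outcome: np.ndarray, group: np.ndarray, individual: np.ndarray
) -> AssociationResult:
    """Likelihood-ratio test of a group effect with a per-individual random intercept.

    Both the full model (outcome ~ group + (1 | individual)) and the null
    (outcome ~ (1 | individual)) are fit by maximum likelihood (not REML, so
    the fixed-effects LRT is valid); the statistic 2(ℓ_full − ℓ_null) is
    referred to χ² with #groups − 1 degrees of freedom. Without repeated
    samples the test falls back to the ANOVA path with a warning.
    """
    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    individual = np.asarray(individual)
    _, ind_counts = np.unique(individual, return_counts=True)
    if (ind_counts <= 1).all():
        logger.warning("no repeated samples; falling back to assumption-gated one-way test")
        return pc_group_association(outcome, group)

    import statsmodels.api as sm

    dummies = pd.get_dummies(pd.Series(group), drop_first=True, dtype=float)
    exog_full = np.column_stack([np.ones(len(outcome)), dummies.to_numpy()])
    exog_null = np.ones((len(outcome), 1))

    def best_llf(exog, name, methods):
        # ML surfaces can stall one optimizer; keep the best likelihood found
        found, errors = None, []
        for method in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cand = sm.MixedLM(outcome, exog, groups=individual).fit(
                        reml=False, method=method, maxiter=500
                    )
                if np.isfinite(cand.llf) and (found is None or cand.llf > found):
                    found = float(cand.llf)
            except Exception as exc:  # noqa: BLE001 - collect for diagnostics
                errors.append(f"{method}: {exc}")
        if found is None:
            raise ValidationError(f"mixed model ({name}) failed to converge: {errors}")
        return found

    def first_llf(exog, name):
        for method in ("lbfgs", "cg", "powell"):
            try:
                return best_llf(exog, name, (method,))
            except ValidationError:
                continue
        raise ValidationError(f"mixed model ({name}) failed to converge with every optimizer")

    llf = {"full": first_llf(exog_full, "full"),
           "null": first_llf(exog_null, "null")}
    if 2.0 * (llf["full"] - llf["null"]) < -1e-6:
        # nesting guarantees llf_full >= llf_null at the optima; re-polish both
        for name, exog in (("full", exog_full), ("null", exog_null)):
            try:
                llf[name] = max(llf[name], best_llf(exog, name, ("cg", "powell")))
            except ValidationError:
                pass

    stat = 2.0 * (llf["full"] - llf["null"])
    if stat < -1e-6:
        raise ValidationError(f"LRT statistic {stat} < 0 beyond tolerance; fits unreliable")
    stat = max(stat, 0.0)
    df = len(np.unique(group)) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return AssociationResult("lrt_mixed", stat, p,
                             assumption_notes={"df": df, "llf_full": llf["full"], "llf_null": llf["null"]})


def mean_distance_to_centroid(points: np.ndarray, labels: np.ndarray, min_size: int = 2) -> float:
    """Mean distance of samples to their own label centroid over labels with >= min_size members."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    dists = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if idx.size < min_size:
            continue
        c = points[idx].mean(axis=0)
        dists.extend(np.linalg.norm(points[idx] - c, axis=1))
    if not dists:
        raise ValidationError("no label has enough members")
    return float(np.mean(dists))


@dataclass
class EvalReport:
    """Assembled evaluation metrics, one entry per method variant."""

    per_method: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, pd.DataFrame):
                return v.to_dict()
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, AssociationResult):
                return v.to_dict()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, list):
                return [conv(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return conv(self.per_method)


def evaluate_methods(
    pcs_by_method: Mapping[str, "AncestryPCs"],
    sheet: pd.DataFrame,
    geno_pcs: pd.DataFrame | None = None,
    n_dims: int = 3,
) -> EvalReport:
    """Run the full performance battery on each method's first PCs.

    Group-level metrics need an ``ancestry_label`` column in the sample
    sheet; repeated-sample metrics are produced only when some individual has
    more than one sample; genotype correlations only when ``geno_pcs`` is
    supplied.
    """
    report = EvalReport()
    labels = sheet["ancestry_label"].to_numpy() if "ancestry_label" in sheet.columns else None
    individuals = sheet["individual_id"].to_numpy()
    _, ind_counts = np.unique(individuals, return_counts=True)
    has_repeats = bool((ind_counts > 1).any())

    for tag, pcs in pcs_by_method.items():
        points = pcs.scores.to_numpy(float)[:, :n_dims]
        entry: dict = {"n_samples": points.shape[0]}
        if labels is not None and np.unique(labels).size >= 2:
            per_sample, mean_s = silhouette(points, labels)
            cents = cluster_centroids(points, labels)
            entry["group"] = {
                "silhouette_mean": mean_s,
                "silhouette_per_sample": per_sample,
                "centroids": cents,
                "centroid_distances": centroid_distance_matrix(cents),
            }
            assoc = []
            for j in range(points.shape[1]):
                try:
                    assoc.append(pc_group_association(points[:, j], labels, pc_index=j + 1))
                except ValidationError as exc:
                    logger.warning("PC%d association skipped: %s", j + 1, exc)
            entry["group"]["associations"] = assoc
        if has_repeats:
            rep_mask = np.isin(individuals, np.unique(individuals)[ind_counts > 1])
            rep_points = points[rep_mask]
            rep_labels = individuals[rep_mask]
            rep: dict = {"mean_distance_to_centroid": mean_distance_to_centroid(points, individuals)}
            if np.unique(rep_labels).size >= 2:
                _, rep_sil = silhouette(rep_points, rep_labels)
                rep["silhouette_mean"] = rep_sil
            entry["repeated"] = rep
        if geno_pcs is not None:
            grid, mean_r = pc_genotype_correlation(pcs.scores, geno_pcs)
            entry["genotype_correlation"] = {"grid": grid, "mean_abs_r": mean_r}
        report.per_method[tag] = entry
    return report
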
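"""Probe annotation tables and ancestry-informative probe selection.

Illumina methylation arrays (450K, EPICv1, EPICv2) carry three probe families
relevant here:

* CpG probes whose interrogated cytosine directly overlaps a common SNP
  ("SNP0bp" probes, overlap distance 0 and minor allele frequency >= 0.05) —
  their beta values are genotype-driven and therefore ancestry-informative;
* explicit genotyping ``rs`` probes whose betas are trimodal across the three
  genotypes;
* everything else (regular CpGs, control probes), which is ignored by the
  method.

Annotation sources differ per platform, so this module consumes plain
delimited tables with a per-platform column mapping rather than hard-coded
annotation packages. For EPICv1 two published SNP-overlap annotations may be
combined; the union (deduplicated by probe id) is used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._utils import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

PLATFORMS = ("450K", "EPICv1", "EPICv2")
PROBE_KINDS = ("cpg", "rs", "control")

#: canonical column names; a column-mapping config maps source headers onto these
CANONICAL_COLUMNS = (
    "probe_id",
    "probe_kind",
    "design_type",
    "channel",
    "snp_distance",
    "maf",
    "control_category",
)


def _infer_kind(probe_id: str) -> str:
    pid = str(probe_id).lower()
    if pid.startswith("rs"):
        return "rs"
    if pid.startswith(("ctl", "neg", "ctrl")):
        return "control"
    return "cpg"


def load_annotation(
    path: str | Path,
    array: str,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Load one platform annotation table.

    Parameters
    ----------
    path:
        Delimited table with at least a probe-id column. ``.csv`` files are
        read comma-separated, anything else tab-separated unless ``sep`` is
        given.
    array:
        Platform name, one of ``450K``, ``EPICv1``, ``EPICv2``.
    column_map:
        Mapping from canonical names (``probe_id``, ``maf``, ...) to the
        source file's headers. Identity by default.

    Returns
    -------
    DataFrame indexed 0..n with canonical columns; ``maf`` and
    ``snp_distance`` are floats with NaN for absent values; ``probe_kind`` is
    inferred from the probe-id prefix when the source has no kind column.
    """
    if array not in PLATFORMS:
        raise ConfigurationError(f"unknown platform {array!r}; expected one of {PLATFORMS}")
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in CANONICAL_COLUMNS if column_map.get(c, c) in raw.columns}
    table = raw.rename(columns=rename)
    if "probe_id" not in table.columns:
        raise FormatError(f"{path}: no probe_id column (headers: {list(raw.columns)[:8]})")
    out = pd.DataFrame({"probe_id": table["probe_id"].astype(str)})
    dup = out["probe_id"][out["probe_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicated probe_id {dup.iloc[0]!r}")
    if "probe_kind" in table.columns:
        out["probe_kind"] = table["probe_kind"].str.lower()
        bad = ~out["probe_kind"].isin(PROBE_KINDS)
        if bad.any():
            raise ValidationError(f"{path}: unknown probe_kind {out.loc[bad, 'probe_kind'].iloc[0]!r}")
    else:
        out["probe_kind"] = out["probe_id"].map(_infer_kind)
    out["design_type"] = table["design_type"] if "design_type" in table.columns else "II"
    out["channel"] = table["channel"] if "channel" in table.columns else "both"
    for col in ("snp_distance", "maf"):
        out[col] = pd.to_numeric(table[col], errors="coerce") if col in table.columns else float("nan")
    out["control_category"] = table.get("control_category", pd.Series([None] * len(out)))
    out["array"] = array
    _validate_annotation(out, str(path))
    return out


def _validate_annotation(ann: pd.DataFrame, origin: str) -> None:
    maf = ann["maf"].dropna()
    if ((maf < 0) | (maf > 1)).any():
        raise ValidationError(f"{origin}: MAF outside [0, 1]")
    dist = ann["snp_distance"].dropna()
    if (dist < 0).any():
        raise ValidationError(f"{origin}: negative snp_distance")


def load_annotations(
    paths: Sequence[str | Path],
    array: str,
    column_maps: Sequence[Mapping[str, str] | None] | None = None,
) -> pd.DataFrame:
    """Load and union several annotation tables (EPICv1's two-source rule).

    Duplicated probe ids across sources are deduplicated keeping the first
    occurrence; duplicates *within* one source remain an error.
    """
    if not paths:
        raise ValidationError("no annotation paths given")
    if column_maps is None:
        column_maps = [None] * len(paths)
    frames = [load_annotation(p, array, m) for p, m in zip(paths, column_maps)]
    merged = pd.concat(frames, ignore_index=True)
    n_dup = int(merged["probe_id"].duplicated().sum())
    if n_dup:
        logger.info("annotation union: %d probe(s) present in multiple sources", n_dup)
    return merged.drop_duplicates("probe_id", keep="first").reset_index(drop=True)


def select_snp0bp(annotation: pd.DataFrame, maf_min: float = 0.05) -> list[str]:
    """CpG probes directly overlapping a common SNP.

    Keeps probes of kind ``cpg`` with ``snp_distance == 0`` and
    ``maf >= maf_min`` (inclusive threshold); probes with absent MAF or
    overlap distance are excluded. The result is sorted by probe id so the
    selection is deterministic regardless of input row order.
    """
    ann = annotation
    keep = (
        (ann["probe_kind"] == "cpg")
        & (ann["snp_distance"] == 0)
        & (ann["maf"] >= maf_min)
    )
    return sorted(ann.loc[keep.fillna(False), "probe_id"])


def select_rs_probes(annotation: pd.DataFrame) -> list[str]:
    """All genotyping rs probes, sorted by probe id.

    An empty result is allowed (the combined method then degenerates to the
    residualized-only method) and is logged as a warning.
    """
    ids = sorted(annotation.loc[annotation["probe_kind"] == "rs", "probe_id"])
    if not ids:
        logger.warning("annotation contains no rs probes; genotype block will be empty")
    return ids


@dataclass
class ProbeSelection:
    """The probes feeding the method, per platform."""

    snp0bp_ids: list[str]
    rs_ids: list[str]
    array: str = "EPICv1"

    def __post_init__(self) -> None:
        overlap = set(self.snp0bp_ids) & set(self.rs_ids)
        if overlap:
            raise ValidationError(f"snp0bp and rs selections overlap: {sorted(overlap)[:3]}")

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame, maf_min: float = 0.05) -> "ProbeSelection":
        array = annotation["array"].iloc[0] if len(annotation) else "EPICv1"
        return cls(select_snp0bp(annotation, maf_min), select_rs_probes(annotation), array)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"array": self.array, "snp0bp_ids": self.snp0bp_ids, "rs_ids": self.rs_ids},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ProbeSelection":
        d = json.loads(Path(path).read_text())
        return cls(d["snp0bp_ids"], d["rs_ids"], d.get("array", "EPICv1"))
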
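"""TSV readers/writers for the pipeline's tabular formats.

All tables are tab-separated with a header row; probe-major matrices carry
``probe_id`` as the first column, sample-major tables ``sample_id``. Missing
values are written as ``NA``; floats round-trip at full precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._utils import FormatError
from .preprocess import SignalSet


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    # %.17g guarantees float64 round-trip
    df.rename_axis("probe_id").to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    if df.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be probe_id, got {df.columns[0]!r}")
    return df.set_index("probe_id")


def read_samples_table(path: str | Path) -> pd.DataFrame:
    """Samples × features table with sample_id as the first column."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be sample_id, got {df.columns[0]!r}")
    return df.set_index("sample_id")


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str, "individual_id": str})
    required = {"sample_id", "individual_id", "sex", "age"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated sample_id {dup!r}")
    return sheet


def read_negcontrols(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "channel", "intensity"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: negative-control table lacks columns {sorted(missing)}")
    return df


def read_signalset(
    meth_path: str | Path,
    unmeth_path: str | Path,
    beads_path: str | Path,
    negctrl_path: str | Path,
    probe_channel: pd.Series,
) -> SignalSet:
    meth = read_matrix(meth_path)
    return SignalSet(
        meth=meth,
        unmeth=read_matrix(unmeth_path),
        bead_counts=read_matrix(beads_path),
        neg_controls=read_negcontrols(negctrl_path),
        probe_channel=probe_channel.reindex(meth.index),
    )
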
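import numpy as np
import pandas as pd
import pytest

from methylancestry import SimConfig, simulate_cohort, run_from_data
from methylancestry.preprocess import SignalSet


#: reduced cohort for unit tests — small but structurally complete
SMALL_CONFIG = SimConfig(
    seed=11,
    groups=(("AFR", 15), ("EAS", 15), ("EUR", 15)),
    n_snp0bp=80,
    n_rs=15,
    n_control=40,
    n_decoy=12,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    co = small_cohort
    return run_from_data(co.annotation, co.signals, co.sheet, co.cell_props, co.control_probes)


def make_signalset(meth, unmeth, channels, bead=None, neg=None, sample_ids=None, probe_ids=None):
    """Hand-build a SignalSet from plain arrays for targeted preprocessing tests."""
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    unmeth = np.atleast_2d(np.asarray(unmeth, dtype=float))
    n_probes, n_samples = meth.shape
    probe_ids = probe_ids or [f"cg{i}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    idx = pd.Index(probe_ids, name="probe_id")
    cols = pd.Index(sample_ids, name="sample_id")
    if bead is None:
        bead = np.full(meth.shape, 10)
    if neg is None:
        rows = []
        for sid in sample_ids:
            for ch in ("grn", "red"):
                for v in (90.0, 100.0, 110.0):
                    rows.append((sid, ch, v))
        neg = pd.DataFrame(rows, columns=["sample_id", "channel", "intensity"])
    return SignalSet(
        meth=pd.DataFrame(meth, index=idx, columns=cols),
        unmeth=pd.DataFrame(unmeth, index=idx, columns=cols),
        bead_counts=pd.DataFrame(np.atleast_2d(bead), index=idx, columns=cols),
        neg_controls=neg,
        probe_channel=pd.Series(list(channels), index=idx),
    )
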
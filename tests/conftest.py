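"""Shared fixtures: tiny event streams and a clustered simulated dataset."""

from __future__ import annotations

import warnings

import pytest

from songkit.annotations import Recording, SyllableEvent

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="scanpy")


def make_events(gaps, labels=None, duration=0.05, start=0.0, **kwargs):
    """Build a sorted event stream from a list of inter-event gaps."""
    labels = labels or ["s"] * (len(gaps) + 1)
    assert len(labels) == len(gaps) + 1
    events = []
    t = start
    for i, label in enumerate(labels):
        events.append(SyllableEvent(label, t, t + duration, **kwargs))
        t += duration
        if i < len(gaps):
            t += gaps[i]
    return events


@pytest.fixture
def simple_recording():
    return Recording(
        "rec1",
        [
            SyllableEvent("a", 0.00, 0.10),
            SyllableEvent("b", 0.15, 0.25),
            SyllableEvent("c", 0.30, 0.40),
        ],
    )


@pytest.fixture(scope="session")
def clustered_sim():
    """A small simulated Area X dataset run through QC/normalize/cluster."""
    import songkit.snrna as sn
    from songkit.simulate.expression import area_x_preset, simulate_counts

    spec = area_x_preset(n_cells=1500, n_genes=500)
    adata, truth = simulate_counts(spec, seed=7)
    adata, report = sn.qc_filter(adata)
    sn.log_normalize(adata)
    sn.cluster_cells(adata, seed=0)
    types = sn.assign_cell_types(adata)
    return adata, truth.loc[adata.obs_names], types, report
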
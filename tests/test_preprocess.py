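"""Compensation, logicle transform and the morphology/QC gates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemoflow as hf
from hemoflow.core import FL_CHANNELS, FSC_INT, FSC_PEAK, FSC_TOF, SSC, TIME
from hemoflow.preprocess import (
    LogicleParams,
    QcConfig,
    all_cells_gate,
    compensate,
    flow_gate,
    from_logicle,
    singlet_gate,
    to_logicle,
)


# ---------------------------------------------------------------------------
# compensation
# ---------------------------------------------------------------------------

def _table_from_fl(fl: np.ndarray, channels) -> hf.EventTable:
    n = len(fl)
    data = pd.DataFrame({
        TIME: np.linspace(0, 10, n),
        FSC_INT: np.full(n, 2e5), FSC_TOF: np.full(n, 200.0),
        FSC_PEAK: np.full(n, 2.5e4), SSC: np.full(n, 3e4),
    })
    for j, ch in enumerate(channels):
        data[ch] = fl[:, j]
    return hf.EventTable(data=data)


def test_identity_compensation_is_noop(p01_table):
    spill = hf.SpilloverMatrix.identity()
    out = compensate(p01_table, spill)
    pd.testing.assert_frame_equal(out.data, p01_table.data)


def test_compensation_inverts_known_mixing():
    true = np.array([[1000.0, 50.0], [20.0, 4000.0], [0.0, 0.0]])
    spill = hf.SpilloverMatrix(["FL1", "FL2"], np.array([[1.0, 0.2], [0.1, 1.0]]))
    observed = true @ spill.matrix
    table = _table_from_fl(observed, ["FL1", "FL2"])
    out = compensate(table, spill)
    np.testing.assert_allclose(out.data[["FL1", "FL2"]].to_numpy(), true, atol=1e-9)


def test_singular_spillover_raises():
    with pytest.raises(np.linalg.LinAlgError):
        hf.SpilloverMatrix(["FL1", "FL2"], np.array([[1.0, 1.0], [1.0, 1.0]])).inverse()


# ---------------------------------------------------------------------------
# logicle
# ---------------------------------------------------------------------------

def test_logicle_top_of_scale_maps_to_one():
    p = LogicleParams()
    assert to_logicle(p.T, p) == pytest.approx(1.0, abs=1e-9)


def test_logicle_round_trip_spanning_negatives():
    p = LogicleParams()
    x = np.concatenate([
        np.linspace(-1e4, 1e4, 400), np.logspace(0, np.log10(p.T), 600)
    ])
    err = np.abs(from_logicle(to_logicle(x, p), p) - x) / np.maximum(np.abs(x), 1.0)
    assert err.max() < 1e-6


def test_logicle_matches_log10_for_high_signals_without_linearization():
    p = LogicleParams(W=0.0, A=0.0)
    x = np.logspace(3, np.log10(p.T), 200)
    pure_log = 1.0 + np.log10(x / p.T) / p.M
    assert np.max(np.abs(to_logicle(x, p) - pure_log)) < 1e-3


@given(
    w=st.floats(0.0, 2.0),
    a=st.floats(0.0, 1.0),
    m=st.floats(3.5, 5.5),
)
@settings(max_examples=25, deadline=None)
def test_logicle_strictly_increasing(w, a, m):
    p = LogicleParams(T=1_048_576, M=m, W=min(w, m / 2), A=a)
    x = np.linspace(-2e4, p.T, 2000)
    y = to_logicle(x, p)
    assert np.all(np.diff(y) > 0)


@pytest.mark.parametrize(
    "kwargs", [dict(T=-1), dict(M=0), dict(W=-0.1), dict(W=3.0, M=4.0), dict(A=-1)]
)
def test_invalid_logicle_params_rejected(kwargs):
    with pytest.raises(ValueError):
        LogicleParams(**kwargs)


# ---------------------------------------------------------------------------
# flow gate
# ---------------------------------------------------------------------------

def test_flow_gate_keeps_uniform_stream(p01_table):
    mask = flow_gate(p01_table)
    assert mask.all()


def test_flow_gate_excludes_burst(profile, schema_by_id):
    import dataclasses

    prof = dataclasses.replace(profile, burst=(20.0, 2.0, 5.0))
    table = hf.simulate_panel_acquisition(prof, schema_by_id["P01"], 50_000, seed=4)
    mask = flow_gate(table)
    t = table.data[TIME].to_numpy()
    in_burst = (t >= 20.0) & (t < 22.0)
    assert mask[in_burst].mean() < 0.05  # burst windows excluded
    assert mask[~in_burst].mean() >= 0.99  # regular stream kept


def test_flow_gate_empty_and_short():
    empty = hf.EventTable(data=pd.DataFrame({
        TIME: [], FSC_INT: [], FSC_TOF: [], FSC_PEAK: [], SSC: []}))
    assert flow_gate(empty).shape == (0,)
    short = hf.EventTable(data=pd.DataFrame({
        TIME: np.linspace(0, 1.5, 50), FSC_INT: np.ones(50),
        FSC_TOF: np.ones(50), FSC_PEAK: np.ones(50), SSC: np.ones(50)}))
    with pytest.warns(UserWarning, match="shorter"):
        assert flow_gate(short).all()


# ---------------------------------------------------------------------------
# singlet gates
# ---------------------------------------------------------------------------

def test_singlet_gate_by_hidden_labels(p01_table):
    mask = singlet_gate(p01_table)
    labels = p01_table.labels
    singlets = ~np.isin(labels, ["doublet", "debris"])
    doublets = labels == "doublet"
    assert mask[singlets].mean() >= 0.99
    assert mask[doublets].mean() <= 0.05  # >=95% of doublets removed
    empty = hf.EventTable(data=pd.DataFrame({
        TIME: [], FSC_INT: [], FSC_TOF: [], FSC_PEAK: [], SSC: []}))
    assert singlet_gate(empty).shape == (0,)


# ---------------------------------------------------------------------------
# All Cells gate
# ---------------------------------------------------------------------------

def test_all_cells_excludes_debris_and_dead(p01_table):
    res = all_cells_gate(p01_table)
    labels = p01_table.labels
    expected = np.isin(labels, ["debris", "dead"]).mean()
    # doublets keep roughly normal scatter, so compare on exclusions only
    excluded = (~res.mask & np.isin(labels, ["debris", "dead"])).mean()
    assert abs(excluded - expected) < 0.005
    assert res.excluded_fraction("debris") == pytest.approx(
        (labels == "debris").mean(), abs=0.005
    )
    # scatter classes only on retained events
    assert set(res.scatter_class[res.mask]) <= {"PBL", "Mo", "Gr"}
    assert (res.scatter_class[~res.mask] == "").all()


def test_all_cells_zero_artifacts_keeps_all_leukocytes(profile, schema_by_id):
    prof = profile.zero_spread()
    table = hf.simulate_panel_acquisition(prof, schema_by_id["P01"], 20_000, seed=2)
    res = all_cells_gate(table)
    assert res.mask.all()


def test_all_cells_adapted_for_uncentrifuged_tube(profile, schema_by_id):
    table = hf.simulate_trucount_acquisition(profile, hf.BeadConfig(), 0.2, seed=9)
    res = all_cells_gate(table, QcConfig().adapted_for_p12())
    cells = ~np.isin(table.labels, ["debris", "dead", "doublet", "bead", "bead_doublet"])
    assert res.mask[cells].mean() >= 0.99
    # beads stay out of the All Cells gate
    beads = np.isin(table.labels, ["bead", "bead_doublet"])
    assert not res.mask[beads].any()


def test_qc_masks_compose_monotonically(p01_table):
    f = flow_gate(p01_table)
    s = singlet_gate(p01_table)
    a = all_cells_gate(p01_table).mask
    assert (f & s & a).sum() <= (f & s).sum() <= f.sum() <= len(p01_table)
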
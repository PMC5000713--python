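"""The synthetic whole-blood generator: determinism, composition, beads."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import hemoflow as hf
from hemoflow.core import FL_CHANNELS, ConfigurationError
from hemoflow.synthetic import default_spillover


def test_default_profile_structure(profile):
    assert sum(profile.frequencies.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0 <= f <= 1 for f in profile.frequencies.values())
    assert profile.dead_fraction < 0.01
    nk = {k: v for k, v in profile.frequencies.items() if k.startswith("nk.")}
    assert 0.85 <= nk["nk.nk1"] / sum(nk.values()) <= 0.95
    mo = {k: v for k, v in profile.frequencies.items() if k.startswith("mo.")}
    assert 0.80 <= mo["mo.mo1"] / sum(mo.values()) <= 0.90
    # circulating non-leukocytes are each below 0.01% of all cells
    assert all(f < 1e-4 for f in profile.nonleuk_frequencies.values())


def test_major_composition_within_normal_ranges(profile):
    majors = profile.major_frequencies()
    assert 0.20 <= majors["T"] <= 0.30
    assert 0.03 <= majors["B"] <= 0.07
    assert 0.03 <= majors["NK"] <= 0.05
    assert 0.07 <= majors["Mo"] <= 0.10
    assert majors["DC"] < 0.01


def test_seeded_runs_are_bit_identical(profile, schema_by_id):
    t1 = hf.simulate_panel_acquisition(profile, schema_by_id["P03"], 5_000, seed=3)
    t2 = hf.simulate_panel_acquisition(profile, schema_by_id["P03"], 5_000, seed=3)
    pd.testing.assert_frame_equal(t1.data, t2.data)
    np.testing.assert_array_equal(t1.labels, t2.labels)
    t3 = hf.simulate_panel_acquisition(profile, schema_by_id["P03"], 5_000, seed=4)
    assert not t3.data.equals(t1.data)


def test_adding_a_panel_does_not_perturb_others(profile, schema_by_id):
    # per-panel substreams: P03's events do not depend on whether P04 ran
    a = hf.simulate_panel_acquisition(profile, schema_by_id["P03"], 2_000, seed=8)
    hf.simulate_panel_acquisition(profile, schema_by_id["P04"], 2_000, seed=8)
    b = hf.simulate_panel_acquisition(profile, schema_by_id["P03"], 2_000, seed=8)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_label_frequencies_converge_to_profile(profile, schema_by_id):
    n = 100_000
    table = hf.simulate_panel_acquisition(profile, schema_by_id["P01"], n, seed=1)
    labels = table.labels
    cells = ~np.isin(labels, ["debris", "dead", "doublet"])
    n_cells = cells.sum()
    for leaf in ("t.th.naive.th2", "b.naive", "nk.nk1", "mo.mo1", "gr.neu", "gr.baso"):
        p = profile.leaf_probability(leaf)
        observed = (labels == leaf).sum()
        sigma = np.sqrt(n_cells * p * (1 - p))
        assert abs(observed - n_cells * p) <= 3 * sigma + 1


def test_dead_and_artifact_rates(profile, schema_by_id):
    table = hf.simulate_panel_acquisition(profile, schema_by_id["P01"], 100_000, seed=1)
    labels = table.labels
    assert (labels == "dead").mean() < 0.01
    assert (labels == "debris").mean() == pytest.approx(0.02, abs=0.005)
    assert (labels == "doublet").mean() == pytest.approx(0.02, abs=0.005)
    # dead cells carry a clearly reduced forward scatter
    fsc = table.data["FSC-INT"].to_numpy()
    assert np.median(fsc[labels == "dead"]) < 0.5 * np.median(fsc[labels == "gr.neu"])


def test_unknown_marker_in_panel_is_a_configuration_error(profile):
    with pytest.raises(ConfigurationError, match="unknown marker"):
        hf.simulate_panel_acquisition(
            profile,
            {"panel_id": "PX", "channel_map": {"FL1": "CD999"}},
            100,
            seed=0,
        )


def test_zero_spread_compensation_recovers_template_locations(profile, schema_by_id):
    # spillover mixing is exactly invertible: with deterministic templates
    # the compensated signal equals the template location
    prof = dataclasses.replace(profile.zero_spread(), spillover=default_spillover())
    schema = schema_by_id["P01"]
    table = hf.simulate_panel_acquisition(prof, schema, 5_000, seed=6)
    comp = hf.compensate(table, table.spillover)
    t_cells = np.array([l.startswith("t.") for l in table.labels])
    cd3 = comp.data["FL9"].to_numpy()[t_cells]
    np.testing.assert_allclose(cd3, 12_000.0, rtol=1e-6)
    b_cells = np.array([l.startswith("b.") for l in table.labels])
    cd8 = comp.data["FL1"].to_numpy()[b_cells]
    np.testing.assert_allclose(cd8, 30.0, rtol=1e-6)


def test_trucount_bead_conservation_without_doublets(profile):
    cfg = hf.BeadConfig(doublet_rate=0.0)
    table = hf.simulate_trucount_acquisition(profile, cfg, acquired_fraction=1.0, seed=2)
    beads = np.isin(table.labels, ["bead", "bead_doublet"])
    assert beads.sum() == cfg.beads_per_tube
    assert (table.labels[beads] == "bead").all()


def test_trucount_singlet_fraction_above_97_percent(profile):
    cfg = hf.BeadConfig(beads_per_tube=10_000, doublet_rate=0.02)
    table = hf.simulate_trucount_acquisition(profile, cfg, acquired_fraction=1.0, seed=5)
    labels = table.labels
    singlets = (labels == "bead").sum()
    doublets = (labels == "bead_doublet").sum()
    assert singlets / (singlets + doublets) > 0.97
    # each doublet holds two beads: total beads are conserved
    assert singlets + 2 * doublets == cfg.beads_per_tube


def test_trucount_truth_bookkeeping(profile):
    table = hf.simulate_trucount_acquisition(profile, hf.BeadConfig(), 0.25, seed=3)
    truth = table.truth
    t_frac = sum(
        profile.leaf_probability(k) for k in profile.all_leaves() if k.startswith("t.")
    )
    assert truth["cells_per_ul"]["T"] == pytest.approx(profile.leukocytes_per_ul * t_frac)
    assert truth["leukocytes_per_ul"] == profile.leukocytes_per_ul


def test_acquired_fraction_validation(profile):
    with pytest.raises(ValueError):
        hf.simulate_trucount_acquisition(profile, hf.BeadConfig(), 0.0, seed=1)
    with pytest.raises(ValueError):
        hf.simulate_panel_acquisition(profile, {"panel_id": "P01", "channel_map": {}}, 0, seed=1)


def test_profile_yaml_round_trip(tmp_path, profile):
    path = tmp_path / "profile.yaml"
    profile.to_yaml(path)
    jittered = profile.perturbed(0.1, np.random.default_rng(0))
    restored = jittered.updated_from_yaml(path)
    assert restored.frequencies == pytest.approx(profile.frequencies)


def test_invalid_profile_rejected(profile):
    with pytest.raises(ConfigurationError):
        profile.with_frequencies({"t.dnt": 0.5})  # does not sum to one
    with pytest.raises(ValueError):
        hf.BeadConfig(doublet_rate=0.5)
    with pytest.raises(ValueError):
        hf.BeadConfig(beads_per_tube=0)
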
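"""Schema content: subset counts, planted phenotypes, Boolean algebra,
linked gates and the sequential major-type classification."""

import numpy as np
import pytest
from conftest import plant, prep_and_masks

import hemoflow as hf
from hemoflow.core import ConfigurationError
from hemoflow.panels import PANEL_VOLUMES, build_diob_schema, subset_definitions


# ---------------------------------------------------------------------------
# structural fidelity
# ---------------------------------------------------------------------------

def test_schema_structure_counts(schemas):
    assert len(schemas) == 12
    defs = subset_definitions()
    assert len(defs) == 37
    assert sum(1 for d in defs if d.immune) == 34
    assert len(hf.activation_markers(schemas)) == 27
    assert len(hf.list_reported_populations(schemas)) == 208


def test_enumeration_is_deterministic_and_modular(schemas):
    pops = hf.list_reported_populations(schemas)
    assert pops == hf.list_reported_populations(schemas)
    # panel P09 contributes its neutrophil/eosinophil content
    p09 = [name for pid, name in pops if pid == "P09"]
    assert "Neutrophils" in p09 and "Eosinophils" in p09
    # dropping one panel removes exactly its entries, nothing else
    reduced = build_diob_schema({"panels": [p for p in hf.panels.ALL_PANEL_IDS if p != "P11"]})
    reduced_pops = hf.list_reported_populations(reduced)
    assert reduced_pops == [(p, n) for p, n in pops if p != "P11"]


def test_every_subset_definition_maps_to_a_reported_population(schemas):
    pops = set(hf.list_reported_populations(schemas))
    for d in subset_definitions():
        assert (d.panel_id, d.population) in pops, d.name


def test_rare_cell_panels_use_triple_blood_volume(schemas):
    assert PANEL_VOLUMES["P10"] == 300.0
    assert PANEL_VOLUMES["P11"] == 300.0
    assert PANEL_VOLUMES["P12"] == 50.0
    assert PANEL_VOLUMES["P01"] == 100.0


def test_missing_threshold_error_names_marker_and_panel():
    # removing a required cut must raise with marker and panel named
    import copy

    import hemoflow.panels as panels_mod

    thresholds = copy.deepcopy(panels_mod.DEFAULT_THRESHOLDS)
    del thresholds["CD3"]["pos"]
    orig = panels_mod.DEFAULT_THRESHOLDS
    panels_mod.DEFAULT_THRESHOLDS = thresholds
    try:
        with pytest.raises(ConfigurationError, match="CD3.*P0|P0.*CD3"):
            build_diob_schema()
    finally:
        panels_mod.DEFAULT_THRESHOLDS = orig


def test_threshold_override_moves_gate(profile, schema_by_id):
    # an absurdly high CD3 cut empties the T-cell gate
    strict = build_diob_schema(
        {"panels": ["P03"], "thresholds": {"CD3": {"pos": 500_000.0}}}
    )[0]
    table = hf.simulate_panel_acquisition(profile, strict, 3_000, seed=1)
    _, masks, _ = prep_and_masks(table, strict)
    assert masks["cd3pos"].sum() == 0


# ---------------------------------------------------------------------------
# linked gates and Boolean gates
# ---------------------------------------------------------------------------

def test_nk_gates_linked_between_p06_and_p07(schema_by_id):
    p06, p07 = schema_by_id["P06"], schema_by_id["P07"]
    for nid in ("cd3neg", "nk", "nk1", "nk2", "nk3"):
        a, b = p06.tree.nodes[nid], p07.tree.nodes[nid]
        assert a.link_id == b.link_id is not None
        assert a.geometry == b.geometry


def test_linked_gates_identical_masks_on_identical_table(profile, schema_by_id):
    table = hf.simulate_panel_acquisition(profile, schema_by_id["P06"], 8_000, seed=12)
    _, m06, _ = prep_and_masks(table, schema_by_id["P06"])
    # feed the same events through P07's tree (channels CD16/CD56/CD3 differ
    # only in unrelated detectors)
    table.panel_id = "P07"
    table.channel_map = dict(schema_by_id["P07"].channel_map)
    _, m07, _ = prep_and_masks(table, schema_by_id["P07"])
    for nid in ("cd3neg", "nk", "nk1", "nk2", "nk3"):
        np.testing.assert_array_equal(m06[nid], m07[nid])


@pytest.mark.parametrize("panel_id,node,expected", [
    ("P01", "tc", lambda m: m["t8hi"] | m["t8lo"]),
    ("P04", "b", lambda m: m["cd19b"] | m["cd20b"]),
    ("P04", "restb", lambda m: m["b"] & ~(
        m["prenaive"] | m["naive"] | m["memoryb"] | m["transitional"] | m["plasmablast"])),
    ("P06", "nkt", lambda m: m["cd3pos"] & (m["nkt_cd56"] | m["nkt_cd16"] | m["nkt_cd314"])),
    ("P07", "nkt", lambda m: m["cd3pos"] & (
        m["nkt_cd56"] | m["nkt_cd16"] | m["nkt_cd94"] | m["nkt_cd159a"] | m["nkt_cd159c"])),
    ("P10", "alldc", lambda m: m["mdc"] | m["pdc"]),
])
def test_boolean_gates_match_set_algebra(profile, schema_by_id, panel_id, node, expected):
    schema = schema_by_id[panel_id]
    table = hf.simulate_panel_acquisition(profile, schema, 8_000, seed=13)
    _, masks, _ = prep_and_masks(table, schema)
    np.testing.assert_array_equal(masks[node], expected(masks))


def test_p12_rest_chain_matches_set_algebra(profile, schema_by_id):
    table = hf.simulate_trucount_acquisition(profile, hf.BeadConfig(), 0.2, seed=14)
    schema = schema_by_id["P12"]
    _, masks, _ = prep_and_masks(table, schema)
    np.testing.assert_array_equal(masks["rest1"], masks["leu"] & ~masks["t12"])
    np.testing.assert_array_equal(masks["rest2"], masks["rest1"] & ~masks["b12"])
    np.testing.assert_array_equal(masks["rest3"], masks["rest2"] & ~(masks["mo12"] | masks["gr12"]))
    np.testing.assert_array_equal(masks["rest4"], masks["rest3"] & ~masks["nk12"])


# ---------------------------------------------------------------------------
# sequential P12 classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def p12_run(profile):
    table = hf.simulate_trucount_acquisition(profile, hf.BeadConfig(), 0.3, seed=21)
    stats = hf.classify_p12_majors(table)
    return table, {s.name: s for s in stats}


def test_p12_majors_partition_leukocytes(p12_run):
    _, by_name = p12_run
    majors = ["T cells", "B cells", "Monocytes", "Granulocytes", "NK cells", "Rest 4"]
    assert sum(by_name[m].count for m in majors) == by_name["Leukocytes (CD45+)"].count
    assert by_name["Rest of PBL"].count + by_name["Rest of cells"].count == by_name["Rest 4"].count


def test_p12_zero_spread_fractions_equal_profile(profile, schema_by_id):
    prof = profile.zero_spread()
    table = hf.simulate_trucount_acquisition(prof, hf.BeadConfig(doublet_rate=0.0), 0.3, seed=22)
    stats = {s.name: s for s in hf.classify_p12_majors(table)}
    labels = table.labels
    cells = ~np.isin(labels, ["bead", "bead_doublet"])
    for name, prefix in [
        ("T cells", "t."), ("B cells", "b."), ("Monocytes", "mo."), ("NK cells", "nk."),
    ]:
        truth = sum(1 for l in labels[cells] if l.startswith(prefix))
        assert stats[name].count == truth


def test_p12_granulocyte_cd16_split(p12_run):
    table, by_name = p12_run
    labels = table.labels
    n_neu = (labels == "gr.neu").sum()
    n_eos = (labels == "gr.eos").sum()
    # CD16 discriminates neutrophils from eosinophils inside the scatter gate
    assert by_name["Neutrophils (CD16+)"].count == pytest.approx(n_neu, rel=0.03)
    assert by_name["Eosinophils (CD16-)"].count == pytest.approx(n_eos, rel=0.05)


# ---------------------------------------------------------------------------
# planted phenotypes: every monitored subset lands where it belongs
# ---------------------------------------------------------------------------

#: populations that must stay (near-)empty when the subset is planted
_EXCLUSIONS = {
    "TH1": ["TH2", "TH17", "TH1-17", "TREG"],
    "TH2": ["TH1", "TH17", "TH1-17"],
    "TH17": ["TH1", "TH2", "TH1-17", "TREG"],
    "TREG": ["TH1", "TH17"],
    "Naive TH": ["Eff TH", "EM TH", "CM TH"],
    "Effector TH": ["Naive TH", "EM TH", "CM TH"],
    "EM TH": ["Naive TH", "Eff TH", "CM TH"],
    "CM TH": ["Naive TH", "Eff TH", "EM TH"],
    "Naive TC": ["Eff T8hi", "EM T8hi", "CM T8hi", "TH"],
    "Effector TC": ["Naive T8hi", "EM T8hi", "CM T8hi", "TH"],
    "EM TC": ["Naive T8hi", "Eff T8hi", "CM T8hi", "TH"],
    "CM TC": ["Naive T8hi", "Eff T8hi", "EM T8hi", "TH"],
    "TCRab T": ["TCRgd T"],
    "TCRgd T": ["TCRab T"],
    "Pre-naive B": ["Naive B", "Memory B", "Transitional B", "Plasmablasts", "BREG"],
    "Naive B": ["Pre-naive B", "Memory B", "Transitional B", "Plasmablasts", "BREG"],
    "Memory B": ["Pre-naive B", "Naive B", "Transitional B", "Plasmablasts", "BREG"],
    "Transitional B": ["Pre-naive B", "Naive B", "Memory B", "Plasmablasts", "BREG"],
    "Plasmablasts": ["Pre-naive B", "Naive B", "Memory B", "Transitional B", "BREG"],
    "BREG": ["Pre-naive B", "Naive B", "Memory B", "Transitional B", "Plasmablasts"],
    "NK1": ["NK2", "NK3", "NKT"],
    "NK2": ["NK1", "NK3", "NKT"],
    "NK3": ["NK1", "NK2", "NKT"],
    "NKT": ["NK cells"],
    "Neutrophils": ["Eosinophils"],
    "Eosinophils": ["Neutrophils"],
    "Basophils": ["pDC", "mDC-1", "mDC-2", "DCs (HLA-DR+)"],
    "pDC": ["mDC-1", "mDC-2", "Basophils"],
    "mDC-1": ["mDC-2", "pDC", "Basophils"],
    "mDC-2": ["mDC-1", "pDC", "Basophils"],
    "Mo1": ["Mo2", "Mo3", "Mo4"],
    "Mo2": ["Mo1", "Mo3", "Mo4"],
    "Mo3": ["Mo1", "Mo2", "Mo4"],
    "Mo4": ["Mo1", "Mo2", "Mo3"],
    "HSC": ["CEC", "CD146-CD133+ EPC"],
    "CEC": ["HSC", "CD146-CD133+ EPC"],
    "EPC": ["CEC", "HSC"],
}


@pytest.mark.parametrize("subset", subset_definitions(), ids=lambda d: d.name)
def test_planted_phenotype_lands_in_its_subset(profile, schema_by_id, subset):
    schema = schema_by_id[subset.panel_id]
    table, masks, planted = plant(profile, subset.plant_leaf, schema)
    assert planted.sum() > 500 if not subset.plant_leaf.startswith("nl.") else planted.sum() > 50
    by_name = {schema.tree.nodes[nid].display_name: nid for nid in schema.tree.order[1:]}
    target = masks[by_name[subset.population]]
    assert target[planted].mean() >= 0.98, f"{subset.name} not recovered"
    for other in _EXCLUSIONS.get(subset.name, []):
        stray = masks[by_name[other]]
        assert stray[planted].mean() <= 0.01, f"{subset.name} leaked into {other}"
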
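"""Shared fixtures: the default synthetic donor, the full schema, and
helpers to plant pure phenotype populations and evaluate panels."""

from __future__ import annotations

import numpy as np
import pytest

import hemoflow as hf
from hemoflow.preprocess import QcConfig, all_cells_gate, compensate, flow_gate, singlet_gate


@pytest.fixture(scope="session")
def profile():
    return hf.build_default_profile(1)


@pytest.fixture(scope="session")
def schemas():
    return hf.build_diob_schema()


@pytest.fixture(scope="session")
def schema_by_id(schemas):
    return {s.panel_id: s for s in schemas}


@pytest.fixture(scope="session")
def p01_table(profile, schema_by_id):
    return hf.simulate_panel_acquisition(profile, schema_by_id["P01"], 30_000, seed=11)


def prep_and_masks(table, schema, qc=None):
    """Compensate, QC-gate and evaluate a panel tree; returns
    (compensated table, node masks, root mask)."""
    cfg = qc or QcConfig()
    if schema.uncentrifuged:
        cfg = cfg.adapted_for_p12()
    if table.spillover is not None:
        table = compensate(table, table.spillover)
    root = flow_gate(table, cfg) & singlet_gate(table, cfg)
    root &= all_cells_gate(table, cfg).mask
    masks = schema.tree.evaluate(table, schema.transforms, root)
    return table, masks, root


def plant(profile, leaf: str, schema, n: int = 4000, seed: int = 77):
    """Simulate a pure population carrying one generator phenotype.

    Non-leukocyte leaves are mixed 1:1 with a marker-silent lymphoid
    filler because leukocyte frequencies must stay normalized.
    """
    if leaf.startswith("nl."):
        prof = profile.with_frequencies({"other.pbl": 1.0}, {leaf: 0.5})
    else:
        prof = profile.with_frequencies({leaf: 1.0}, {})
    table = hf.simulate_panel_acquisition(prof, schema, n, seed=seed)
    _, masks, root = prep_and_masks(table, schema)
    planted = (table.labels == leaf) & root
    return table, masks, planted
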
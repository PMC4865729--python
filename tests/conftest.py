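from __future__ import annotations

import pytest

from ptmtransfer import pipeline, synthetic
from ptmtransfer.alignment import SearchParams


def run_scenario(scn: synthetic.Scenario, mode: str = "both"):
    """Build the scenario's model and predict for every query protein."""
    model = pipeline.assemble_model(
        scn.known, scn.annotations, scn.query,
        w=scn.config.w, ptm_type=scn.config.ptm_type,
        residue_set=scn.config.residue_set,
    )
    rows = pipeline.predict(
        [p.id for p in scn.query], model, SearchParams(), mode=mode
    )
    return model, rows


@pytest.fixture(scope="session")
def selfinc():
    """The self-inclusive study condition: query proteome identical to the
    known proteome, every annotated site verbatim in the model."""
    scn = synthetic.scenario("self_inclusion", seed=42)
    model, rows = run_scenario(scn)
    return scn, model, rows


@pytest.fixture(scope="session")
def paralog():
    """Homolog queries plus one armed paralog trap."""
    scn = synthetic.scenario("paralog_trap", seed=42)
    model, rows = run_scenario(scn)
    return scn, model, rows


@pytest.fixture(scope="session")
def empty_rows():
    scn = synthetic.scenario("empty", seed=42)
    _, rows = run_scenario(scn)
    return rows


def cpe_set(rows):
    return {r.key() for r in rows if r.cpe_yes}


def evalue_set(rows):
    return {r.key() for r in rows if r.evalue_yes}
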
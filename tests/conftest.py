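import numpy as np
import pandas as pd
import pytest

from scope2 import simulate
from scope2.data_model import Channel, PsmTable, RunDesign, SetDesign


@pytest.fixture
def tiny_design() -> SetDesign:
    """One 8-channel run: carrier, reference, 4 single cells, control, unused."""
    return SetDesign(
        [
            RunDesign(
                "run1",
                [
                    Channel("RI1", "carrier"),
                    Channel("RI2", "reference"),
                    Channel("RI3", "single_cell", cell_type="macrophage"),
                    Channel("RI4", "single_cell", cell_type="macrophage"),
                    Channel("RI5", "single_cell", cell_type="monocyte"),
                    Channel("RI6", "single_cell", cell_type="monocyte"),
                    Channel("RI7", "control"),
                    Channel("RI8", "unused"),
                ],
            )
        ]
    )


def make_psm_df(
    rows: list[dict], channels: list[str], n_channels: int | None = None
) -> pd.DataFrame:
    """Build a PsmTable frame from compact row dicts (ri=list per channel)."""
    out = []
    for r in rows:
        base = {
            "sequence": r.get("sequence", "PEPTIDEA"),
            "leading_razor_protein": r.get("protein", "P1"),
            "run_id": r.get("run_id", "run1"),
            "pep": r.get("pep", 0.001),
            "pep_updated": r.get("pep_updated", r.get("pep", 0.001)),
            "pif": r.get("pif", 0.95),
            "rt": r.get("rt", 30.0),
            "is_reverse": r.get("is_reverse", False),
            "is_contaminant": r.get("is_contaminant", False),
        }
        ri = r.get("ri", [100.0] * len(channels))
        for lbl, v in zip(channels, ri):
            base[f"ri_{lbl}"] = v
        if "snr" in r:
            for lbl, v in zip(channels, r["snr"]):
                base[f"snr_{lbl}"] = v
        out.append(base)
    return pd.DataFrame(out)


@pytest.fixture
def tiny_psm(tiny_design) -> PsmTable:
    channels = tiny_design["run1"].labels
    rows = [
        {"sequence": f"PEP{i}", "protein": f"P{i % 3}", "ri": list(100.0 + np.arange(8) + i)}
        for i in range(6)
    ]
    return PsmTable(make_psm_df(rows, channels), channels, tiny_design)


@pytest.fixture(scope="session")
def synth_small():
    """Small seeded synthetic experiment shared across tests."""
    design = simulate.default_design(n_runs=4, seed=11)
    truth = simulate.make_truth(n_proteins=300, seed=11)
    psm, truth = simulate.simulate_scope2(design, truth, seed=11)
    return design, truth, psm
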
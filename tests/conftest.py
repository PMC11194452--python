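import numpy as np
import pandas as pd
import pytest

from leachresp import amplicon, image_quant as iq
from leachresp.simulate import (
    AsvExperimentParams,
    CellGroupSpec,
    FovParams,
    simulate_asv_experiment,
    simulate_fov_set,
)


@pytest.fixture(scope="session")
def experiment():
    """One default synthetic sequencing experiment, shared across tests."""
    return simulate_asv_experiment(AsvExperimentParams(), seed=7)


@pytest.fixture(scope="session")
def corrected_rel(experiment):
    cn = amplicon.CopyNumberTable(experiment["copy_numbers"])
    return amplicon.copy_number_correct(
        experiment["counts"], experiment["taxonomy"], cn
    )


@pytest.fixture(scope="session")
def two_group_panel():
    return iq.ProbePanel(
        targets={"EUB338": "Bacteria", "P1": "GroupA", "P2": "GroupB"},
        nesting={},
        universal="EUB338",
    )


@pytest.fixture(scope="session")
def two_group_fovs(two_group_panel):
    """Noiseless two-group community, equal abundance, 3:1 activity ratio."""
    groups = [
        CellGroupSpec("A", 0.5, ("P1", "EUB338"), 90.0),
        CellGroupSpec("B", 0.5, ("P2", "EUB338"), 30.0),
    ]
    params = FovParams(noise_sd=0.0, background=10.0, n_cells=80)
    fovs, truth = simulate_fov_set(
        params, n_fov=3, groups=groups, panel=two_group_panel,
        probes=["P1", "P2"], seed=11,
    )
    return fovs, truth


def quantify_fovs(fov_list):
    """Segment and gate a list of in-memory FOV triplets."""
    frames = []
    for fov in fov_list:
        labels = iq.segment_cells(fov["dapi"])
        frames.append(iq.gate_cells(labels, fov["dapi"], fov["boncat"], fov["fish"]))
    return pd.concat(frames, ignore_index=True)
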
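import pandas as pd
import pytest

import probescore as ps


def paired_design(n_male: int = 5, n_female: int = 4, age: str = "adolescent_PND43") -> ps.DesignTable:
    return ps.make_study_design(ages=(age,), pairs_per_sex={"M": n_male, "F": n_female})


@pytest.fixture(scope="session")
def one_pair_design() -> ps.DesignTable:
    return ps.DesignTable(
        pd.DataFrame(
            [
                dict(sample_id="T1", age_group="adolescent_PND43", sex="M",
                     treatment="ethanol", pair_id="p1"),
                dict(sample_id="C1", age_group="adolescent_PND43", sex="M",
                     treatment="control", pair_id="p1"),
            ]
        )
    )


@pytest.fixture(scope="session")
def null_chip_pair(one_pair_design):
    """5,000-cluster null simulation of a single treated/control chip pair."""
    spec = ps.SimulationSpec(n_clusters=5000, probes_per_cluster=4, n_de=0,
                             design=one_pair_design, seed=11)
    pm, design, truth = ps.simulate_probe_data(spec)
    return pm, design, truth


@pytest.fixture(scope="session")
def small_probe_matrix():
    """6 probes, 2 clusters, 4 samples; hand-sized for I/O tests."""
    probes = [f"P{i}" for i in range(1, 7)]
    intens = pd.DataFrame(
        [[100.0 + 10 * i + j for j in range(4)] for i in range(6)],
        index=pd.Index(probes, name="probe_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    cmap = pd.Series(["g1"] * 3 + ["g2"] * 3, index=probes, name="cluster_id")
    return ps.ProbeMatrix(intens, cmap)
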
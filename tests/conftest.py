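import numpy as np
import pandas as pd
import pytest

import ornameta as om


def make_toy_table() -> pd.DataFrame:
    """Eight handcrafted effects on four species / four studies."""
    rows = [
        # effect, study, experiment, species, r, n
        ("e1", "s1", "s1x1", "A", 0.10, 41),
        ("e2", "s1", "s1x1", "A", 0.30, 26),
        ("e3", "s2", "s2x1", "B", -0.20, 101),
        ("e4", "s2", "s2x2", "B", -0.05, 50),
        ("e5", "s3", "s3x1", "C", 0.00, 65),
        ("e6", "s3", "s3x1", "C", 0.15, 33),
        ("e7", "s4", "s4x1", "D", -0.40, 20),
        ("e8", "s4", "s4x1", "D", 0.05, 80),
    ]
    t = pd.DataFrame(
        rows, columns=["effect_id", "study_id", "experiment_id", "species", "r", "n"]
    )
    t["v"] = om.r_sampling_variance(t["r"].to_numpy(), t["n"].to_numpy())
    t["directionless"] = False
    t["uninfected_present"] = ["yes", "no", "yes", "no", "yes", "no", "yes", "no"]
    t["dynamism_score"] = ["2", "2", "1", "0", "2", "1", "0", "2"]
    t["dynamism_binary"] = [
        "dynamic" if s == "2" else "static" for s in t["dynamism_score"]
    ]
    return t


@pytest.fixture()
def toy_dataset() -> om.Dataset:
    return om.Dataset(make_toy_table(), ["toy"])


@pytest.fixture(scope="session")
def toy_tree():
    """Grafen-ultrametrized four-tip tree over species A-D."""
    raw = om.read_newick("((A,B),(C,D));")
    return om.grafen_transform(om.set_unit_branch_lengths(raw))


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated dataset (k ~ 60) with its truth and tree."""
    params = om.SimParams(
        n_species=12, studies_per_species=1.6, effects_per_study=2.5, seed=7
    )
    dataset, truth = om.simulate_dataset(params)
    tree = om.read_newick(truth.tree_newick)
    return dataset, truth, tree
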
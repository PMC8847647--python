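import numpy as np
import pandas as pd
import pytest

from lipidtraffic import (
    GeneratorConfig,
    LipidomicsDataset,
    TissueNetwork,
    default_network,
    parse_lipid_name,
)


@pytest.fixture
def star_network() -> TissueNetwork:
    return default_network()


@pytest.fixture
def two_compartment_network() -> TissueNetwork:
    return TissueNetwork(
        compartments=("serum", "liver"), edges=(("liver", "serum"),)
    )


def make_dataset(rows, variables):
    """Build a dataset from (sample_id, compartment, group, values) rows."""
    samples = pd.DataFrame(
        [(r[0], r[1], r[2]) for r in rows],
        columns=["sample_id", "compartment", "group"],
    ).set_index("sample_id")
    abundance = pd.DataFrame(
        [r[3] for r in rows], index=samples.index, columns=variables, dtype=float
    )
    return LipidomicsDataset(
        samples=samples,
        abundance=abundance,
        variables=[parse_lipid_name(v) for v in variables],
    )


@pytest.fixture
def toy_dataset():
    """2 groups x 2 compartments x 3 samples, 3 variables with clear patterns.

    TG(52:3): present everywhere (A-type in both groups).
    PC(34:1): present only in liver for both groups (U@liver).
    SM(39:1): present everywhere in lean, absent in obese.
    """
    rows = []
    for g in ("lean", "obese"):
        for c in ("serum", "liver"):
            for i in range(3):
                tg = 5.0
                pc = 2.0 if c == "liver" else 0.0
                sm = 1.5 if g == "lean" else 0.0
                rows.append((f"{g}_{c}_{i}", c, g, [tg, pc, sm]))
    return make_dataset(rows, ["TG(52:3)", "PC(34:1)", "SM(39:1)"])


@pytest.fixture
def small_config(star_network):
    """A reduced synthetic design that still exercises every category."""
    return GeneratorConfig(
        n_a_shared=6, n_a_control_only=2, n_a_case_only=1,
        n_u_shared=1, n_u_control_only=1, n_u_case_only=1,
        n_b_shared=2, n_b_control_only=1, n_b_case_only=1,
        n_regulated=4,
    )


def brute_force_classify(abundance, samples, network, threshold_num=66,
                         threshold_den=100):
    """Independent re-derivation of U/A/B sets straight from the raw matrix.

    Pure-python loops and integer arithmetic only; used as the oracle for
    classify_switch.
    """
    out = {}
    for g in sorted(samples["group"].unique()):
        present = {}
        for c in network.compartments:
            ids = [
                sid for sid in samples.index
                if samples.loc[sid, "group"] == g
                and samples.loc[sid, "compartment"] == c
            ]
            vars_present = set()
            for var in abundance.columns:
                k = sum(1 for sid in ids if abundance.loc[sid, var] > 0)
                if k * threshold_den >= threshold_num * len(ids):
                    vars_present.add(var)
            present[c] = vars_present
        u = {
            c: {
                v for v in present[c]
                if all(v not in present[o] for o in network.compartments if o != c)
            }
            for c in network.compartments
        }
        a = set.intersection(*(present[c] for c in network.compartments))
        b = {
            tuple(sorted(e)): present[e[0]] & present[e[1]]
            for e in network.edges
        }
        out[g] = {"U": u, "A": a, "B": b, "present": present}
    return out


def random_small_instance(rng: np.random.Generator):
    """A random dataset on a random small connected network."""
    n_comp = int(rng.integers(2, 6))
    comps = tuple(f"c{i}" for i in range(n_comp))
    edges = [(comps[i], comps[i + 1]) for i in range(n_comp - 1)]  # path: connected
    extra = [
        (comps[i], comps[j])
        for i in range(n_comp) for j in range(i + 2, n_comp)
        if rng.random() < 0.3
    ]
    network = TissueNetwork(compartments=comps, edges=tuple(edges + extra))
    n_vars = int(rng.integers(3, 51))
    variables = [f"TG({40 + i}:{i % 5})" for i in range(n_vars)]
    n = int(rng.integers(3, 7))
    rows = []
    for g in ("g1", "g2"):
        for c in comps:
            for i in range(n):
                vals = np.where(
                    rng.random(n_vars) < 0.6, rng.lognormal(0, 1, n_vars), 0.0
                )
                rows.append((f"{g}_{c}_{i}", c, g, vals))
    return make_dataset(rows, variables), network
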
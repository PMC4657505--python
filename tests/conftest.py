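import warnings

import numpy as np
import pytest

from cbmfrax.mesh import make_canonical_mesh
from cbmfrax import synth

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def mesh_small():
    """~600-vertex canonical surface for fast unit tests."""
    return make_canonical_mesh(600, seed=0)


@pytest.fixture(scope="session")
def mesh_1000():
    """~1000-vertex canonical surface for surface-statistics tests."""
    return make_canonical_mesh(1000, seed=0)


@pytest.fixture(scope="session")
def outcome_population(mesh_1000):
    """Default-spec cohort with hazard-linked fracture outcomes."""
    pop = synth.simulate_population(mesh_1000, 800, seed=11)
    return synth.simulate_fracture_outcomes(pop, seed=12)


def planted_case_control(mesh, n=400, n_cases=100, effect=-0.10,
                         region="trochanter_superolateral",
                         case_type="trochanteric", seed=0, spec=None):
    """Label-first planted-deficit dataset for surface-statistics calibration.

    Returns (subjects, Y) where ``n_cases`` subjects carry the relative
    ``effect`` on the combined CM field inside ``region`` and are labelled
    with ``case_type`` (half of them ``neck`` when case_type is 'both').
    """
    import pandas as pd

    spec = spec or synth.TrueEffectSpec(
        effect_fraction={"CTh": 0.0, "CBMD": 0.0, "ECTD": 0.0})
    pop = synth.simulate_population(mesh, n, spec=spec, seed=seed)
    rng = np.random.default_rng(seed + 1)
    idx = rng.choice(n, n_cases, replace=False)
    labels = np.array(["none"] * n, dtype=object)
    labels[idx] = case_type
    # the other fracture type must be represented for a full-rank design;
    # it carries no planted effect
    other = "neck" if case_type == "trochanteric" else "trochanteric"
    labels[idx[: n_cases // 3]] = other
    subjects = pop.subjects.copy()
    subjects["fracture_type"] = pd.Categorical(
        labels, categories=["none", "trochanteric", "neck"])
    Y = pop.combined_fields("CM")
    if effect:
        Y = synth.plant_group_deficit(Y, labels == case_type,
                                      mesh.region_mask(region), effect)
    return subjects, Y
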
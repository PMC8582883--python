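"""Shared fixtures: small synthetic datasets and model specifications."""

import numpy as np
import pandas as pd
import pytest

import hetlogit as hl
from hetlogit.spec import CoefficientSet, CoefficientSlot, ModelSpec, RandomSlotSpec


@pytest.fixture
def tiny_dataset():
    """Six crashes, one covariate, all four severities present."""
    df = pd.DataFrame(
        {
            "severity": [1, 1, 2, 3, 4, 2],
            "truck": [0, 1, 0, 1, 1, 0],
        }
    )
    return hl.CrashDataset.from_dataframe(df, ["truck"])


@pytest.fixture
def mnl_spec():
    """A no-random-slot spec: two covariates in every non-baseline function."""
    slots = [
        CoefficientSlot(cov, sev)
        for cov in ("x1", "x2")
        for sev in (2, 3, 4)
    ]
    return ModelSpec(slots)


@pytest.fixture
def mnl_dgp(mnl_spec):
    true = CoefficientSet.from_values(
        mnl_spec,
        constants={2: 0.4, 3: -0.3, 4: -0.9},
        betas={
            ("x1", 2): 0.5,
            ("x1", 3): -0.6,
            ("x1", 4): 0.3,
            ("x2", 2): -0.4,
            ("x2", 3): 0.7,
            ("x2", 4): -0.2,
        },
    )
    return hl.DGPConfig(
        n=800,
        covariate_probs={"x1": 0.5, "x2": 0.4},
        spec=mnl_spec,
        true_params=true,
        seed=11,
    )


@pytest.fixture
def mixed_spec():
    """One random slot with one mean link and one variance link."""
    return ModelSpec(
        fixed_slots=[CoefficientSlot("truck", 4)],
        random_slots=[
            RandomSlotSpec(
                CoefficientSlot("xr", 3, "random"),
                mean_covariates=("z",),
                variance_covariates=("w",),
            )
        ],
    )


@pytest.fixture
def mixed_true(mixed_spec):
    return CoefficientSet.from_values(
        mixed_spec,
        constants={2: 1.0, 3: -0.5, 4: -1.0},
        betas={("truck", 4): 0.8},
        means={("xr", 3): -2.0},
        sds={("xr", 3): 2.0},
        thetas={("xr", 3, "z"): 1.5},
        omegas={("xr", 3, "w"): 0.5},
    )


@pytest.fixture
def mixed_dgp(mixed_spec, mixed_true):
    return hl.DGPConfig(
        n=1200,
        covariate_probs={"truck": 0.2, "xr": 0.5, "z": 0.5, "w": 0.5},
        spec=mixed_spec,
        true_params=mixed_true,
        seed=5,
    )
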
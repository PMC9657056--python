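"""Shared fixtures: default materials/geometry and generator outputs.

Generator fixtures are session-scoped; every test that mutates a table
must copy it first.
"""

import numpy as np
import pandas as pd
import pytest

from ossishield import (
    DEFAULT_MATERIALS,
    GeometryConfig,
    LoadCase,
    PairedFields,
    generate_paired,
)
from ossishield.femur import FIELD_COLUMNS


@pytest.fixture(scope="session")
def materials():
    return dict(DEFAULT_MATERIALS)


@pytest.fixture(scope="session")
def geometry():
    return GeometryConfig()


@pytest.fixture(scope="session")
def load_2300():
    return LoadCase(2300.0)


@pytest.fixture(scope="session")
def paired_ti(geometry, materials, load_2300):
    return generate_paired(geometry, materials, load_2300, "ti6al4v", seed=7)


@pytest.fixture(scope="session")
def paired_peek(geometry, materials, load_2300):
    return generate_paired(geometry, materials, load_2300, "peek", seed=7)


def make_table(vm, comp_strain=None, zone=1, side="medial", volume=None, density=1.64):
    """Minimal element-field table for hand-computed examples."""
    vm = np.asarray(vm, dtype=float)
    n = len(vm)
    return pd.DataFrame(
        {
            "element_id": np.arange(1, n + 1),
            "zone": zone if np.ndim(zone) else [zone] * n,
            "z_mm": np.linspace(0, 10, n),
            "side": side if isinstance(side, (list, np.ndarray)) else [side] * n,
            "material": ["cortical"] * n,
            "volume_mm3": volume if volume is not None else np.ones(n),
            "density_g_per_ml": [density] * n,
            "vm_stress_mpa": vm,
            "comp_strain": (
                np.asarray(comp_strain, dtype=float)
                if comp_strain is not None
                else -vm / 16700.0
            ),
        }
    )[FIELD_COLUMNS]


def make_paired(intact_vm, implanted_vm, stem="ti6al4v", **kw):
    return PairedFields(make_table(intact_vm, **kw), make_table(implanted_vm, **kw), stem)
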
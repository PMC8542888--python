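"""Shared fixtures: synthetic tables and small reference columns."""

import numpy as np
import pytest
from hypothesis import settings

from sorbfate.io import BatchDataset, BatchRecord
from sorbfate.transport import ColumnLayer, FilterColumn

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def batch_record():
    """One canonical batch observation: 10 mg sorbent in 50 mL at 1 mg/L."""
    return BatchRecord(
        compound="ACM", sorbent="CH", c0=1.0, ce=0.6, volume=0.05, mass=1e-5
    )


@pytest.fixture
def small_dataset():
    """Two compounds x two sorbents, triplicates at 200 mg/L loading."""
    records = []
    for compound, base in (("TC", 0.2), ("ATR", 0.6)):
        for sorbent, shift in (("CH", 0.0), ("RS", 0.1)):
            for rep_offset in (-0.01, 0.0, 0.01):
                records.append(
                    BatchRecord(
                        compound=compound,
                        sorbent=sorbent,
                        c0=1.0,
                        ce=base + shift + rep_offset,
                        volume=0.05,
                        mass=1e-5,
                    )
                )
    return BatchDataset(records)


def make_homogeneous_column(
    depth=0.2, velocity=1e-3, porosity=0.4, bulk_density=1.6,
    dispersivity=0.001, sand_fraction=0.0, biochar_fraction=0.0,
    conditioning_time=0.0, pad_factor=1.0,
):
    """Single-layer column with prescribed depth and pore velocity.

    ``pad_factor`` > 1 lengthens the column beyond ``depth`` (useful when
    comparing interior concentrations against semi-infinite solutions).
    """
    total = depth * pad_factor
    area = 1.0 / (bulk_density * 1000.0 * total)  # => mass 1 kg gives depth `total`
    layer = ColumnLayer(
        "medium", mass=1.0, bulk_density=bulk_density, porosity=porosity,
        sand_fraction=sand_fraction, biochar_fraction=biochar_fraction,
    )
    flow = porosity * area * velocity * 60000.0  # L/min giving pore velocity v
    return FilterColumn(
        layers=(layer,), cross_section=area, flow_rate=flow,
        dispersivity=dispersivity, molecular_diffusion=0.0,
        conditioning_time=conditioning_time,
    )


@pytest.fixture
def homogeneous_column_factory():
    return make_homogeneous_column


def seconds(curve, column):
    """Convert a curve's cumulative volumes to elapsed seconds."""
    return curve.volumes / column.flow_rate * 60.0
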
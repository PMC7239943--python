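"""Shared fixtures and independent oracles for the icmet test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icmet import (
    FeatureTable,
    SimulationConfig,
    simulate_feature_table,
    simulate_library,
)
from icmet.chem import ISOTOPES, ElementalComposition, adduct_mz, get_adduct


# ---------------------------------------------------------------------------
# independent oracle: brute-force isotope envelope by atom-at-a-time expansion
# ---------------------------------------------------------------------------

def brute_force_envelope(comp: ElementalComposition, n_peaks: int = 5) -> np.ndarray:
    """Isotopologue abundances by naive one-atom-at-a-time polynomial expansion.

    Pure-Python dict convolution, one atom per step — deliberately different
    from the package's binary-exponentiation path.  Returns abundances for
    shifts 0..n_peaks-1 normalised to the base peak.
    """
    dist: dict[int, float] = {0: 1.0}
    for element, count in comp.counts.items():
        isotopes = [(shift, ab) for shift, _m, ab in ISOTOPES[element]]
        for _ in range(count):
            new: dict[int, float] = {}
            for shift_so_far, prob in dist.items():
                for shift, ab in isotopes:
                    key = shift_so_far + shift
                    new[key] = new.get(key, 0.0) + prob * ab
            dist = new
    out = np.array([dist.get(k, 0.0) for k in range(n_peaks)])
    return out / out.max()


@pytest.fixture(scope="session")
def standards_library():
    return simulate_library(50, seed=11)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_dataset(standards_library, sim_config):
    """A full synthetic dataset: (table, ground truth) at the default design."""
    return simulate_feature_table(standards_library, sim_config)


@pytest.fixture()
def tiny_table() -> FeatureTable:
    """A 4-feature, 2x3-sample + 2-QC table with hand-set intensities."""
    intensities = pd.DataFrame(
        {
            "a1": [100.0, 10.0, 50.0, np.nan],
            "a2": [110.0, 12.0, 55.0, np.nan],
            "a3": [90.0, 11.0, 45.0, np.nan],
            "b1": [25.0, 40.0, 50.0, 5.0],
            "b2": [24.0, 44.0, 55.0, np.nan],
            "b3": [26.0, 36.0, 45.0, np.nan],
            "QC_1": [60.0, 25.0, 50.0, 5.0],
            "QC_2": [66.0, 25.0, 50.0, 5.0],
        },
        index=["10.00_100.0000", "11.00_200.0000", "12.00_300.0000", "13.00_400.0000"],
    )
    meta = pd.DataFrame(
        {
            "group": ["A", "A", "A", "B", "B", "B", "QC", "QC"],
            "batch": ["1"] * 8,
            "role": ["sample"] * 6 + ["QC"] * 2,
        },
        index=intensities.columns,
    )
    return FeatureTable(intensities=intensities, meta=meta)


def glutamate_mz() -> float:
    from icmet.chem import parse_formula

    return adduct_mz(parse_formula("C5H9NO4"), "[M-H]-")
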
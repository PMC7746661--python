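"""Shared helpers: run the full pipeline on a simulated bundle and compare
its output with the generator's ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from polyphagy import SimConfig, simulate_dataset, write_dataset
from polyphagy.pipeline import PipelineConfig, run_build

DS2_INT_COLUMNS = [
    "NumberSampledMothSpecies",
    "TotalMothSpecies",
    "TotalNumberGenus",
    "TotalNumberFamilies",
    "TotalNumberOrders",
]
DS2_REAL_COLUMNS = [
    "AverageNumberGenus",
    "AverageNumberFamilies",
    "AverageNumberOrders",
    "PD_score",
]


def build_from_simulation(config: SimConfig, tmp_path, write: bool = True):
    """Simulate a bundle, write it out, run the pipeline on the files."""
    ds = simulate_dataset(config)
    paths = write_dataset(ds, tmp_path)
    result = run_build(PipelineConfig.from_yaml(paths["config"]), write=write)
    return ds, result


def assert_matches_truth(ds, result, rtol: float = 0.0, atol: float = 1e-9) -> None:
    """Pipeline DS1/DS2 must equal the generator's ledger: counts and name
    lists exactly, averages and PD within atol."""
    truth1 = ds.truth.to_ds1_frame().astype(str)
    out1 = result.ds1.reset_index(drop=True).astype(str)
    pd.testing.assert_frame_equal(out1, truth1)

    truth2 = ds.truth.to_ds2_frame(ds.checklist)
    out2 = result.ds2.reset_index(drop=True)
    assert len(out2) == len(truth2)
    for col in ["Family", "Subfamily", "Tribe", "Moth_Genus_Name"]:
        assert out2[col].tolist() == truth2[col].tolist(), col
    for col in DS2_INT_COLUMNS:
        a = out2[col].astype(float).to_numpy()
        b = truth2[col].astype(float).to_numpy()
        assert np.array_equal(a, b, equal_nan=True), col
    for col in DS2_REAL_COLUMNS:
        a = out2[col].astype(float).to_numpy()
        b = truth2[col].astype(float).to_numpy()
        assert np.array_equal(np.isnan(a), np.isnan(b)), f"{col}: defined/undefined mismatch"
        mask = ~np.isnan(b)
        assert np.allclose(a[mask], b[mask], rtol=rtol, atol=atol), col


def random_config(rng: np.random.Generator) -> SimConfig:
    """A random desk-scale study shape (<=200 moth species, <=50 families)."""
    n_fam = int(rng.integers(6, 51))
    return SimConfig(
        n_plant_families=n_fam,
        n_plant_genera=int(rng.integers(n_fam, 3 * n_fam + 1)),
        n_moth_genera=int(rng.integers(3, 31)),
        n_moth_species=int(rng.integers(10, 201)),
        n_sources=int(rng.integers(1, 5)),
        host_breadth_mean=float(rng.uniform(1.0, 6.0)),
        duplicate_rate=float(rng.uniform(0.0, 0.4)),
        captive_rate=float(rng.uniform(0.0, 0.3)),
        gymnosperm_fraction=float(rng.uniform(0.0, 0.25)),
        synonym_noise_rate=float(rng.uniform(0.0, 0.3)),
        seed=int(rng.integers(2**31)),
    )
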
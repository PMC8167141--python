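import numpy as np
import pandas as pd
import pytest

from oeac import simulate
from oeac.io import validate_cohort
from oeac.transform import AgeTransform


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale nine-species synthetic cohort (seed 1)."""
    return simulate.generate_cohort(simulate.default_config(seed=1))


def small_config(seed=7, **overrides):
    """Three species, ~90 samples, 150 probes: fast but structured."""
    species = (
        simulate.SpeciesSim("dolphin_a", 25, 0.0, 40.0, 8.0, 1.0, ("blood", "skin")),
        simulate.SpeciesSim("whale_b", 15, 0.0, 50.0, 10.0, 1.3, ("blood", "skin")),
        simulate.SpeciesSim("porpoise_c", 10, 0.0, 20.0, 5.0, 0.9, ("skin",)),
    )
    cfg = simulate.SimConfig(
        species=species,
        n_probes=150,
        n_shared_aging=15,
        n_private_aging=6,
        n_sex=4,
        n_tissue=10,
        n_species_offset=10,
        noise_sd=0.02,
        seed=seed,
    )
    from dataclasses import replace

    return replace(cfg, **overrides)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate.generate_cohort(small_config())


@pytest.fixture
def tiny_cohort_builder():
    """Build a hand-specified cohort from probe rows and per-sample metadata."""

    def build(values, sample_meta, params=None, annotation=None):
        values = np.asarray(values, dtype=float)
        n_probes, n_samples = values.shape
        probe_ids = [f"cg{j:03d}" for j in range(n_probes)]
        sheet = pd.DataFrame(sample_meta)
        if "sample_id" not in sheet:
            sheet["sample_id"] = [f"s{i}" for i in range(n_samples)]
        if "animal_id" not in sheet:
            sheet["animal_id"] = sheet["sample_id"]
        for col, default in [
            ("species", "dolphin_a"),
            ("tissue", "blood"),
            ("sex", "F"),
            ("age_status", "known"),
            ("origin", "zoo"),
        ]:
            if col not in sheet:
                sheet[col] = default
        if params is None:
            params = pd.DataFrame(
                {
                    "species": sorted(sheet["species"].unique()),
                    "asm_years": 9.0,
                    "gestation_years": 1.0,
                }
            )
        beta = pd.DataFrame(values, index=probe_ids, columns=sheet["sample_id"])
        return validate_cohort(beta, sheet, params, annotation)

    return build


@pytest.fixture
def std_transform():
    """The m = 9, g = 1 transform used in hand-computed examples."""
    return AgeTransform(asm_years=9.0, gestation_years=1.0)
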
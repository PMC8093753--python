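import numpy as np
import pandas as pd
import pytest

from microtraits.condense import RANKS
from microtraits.synthetic_data import SyntheticConfig, generate_dataset


def make_taxonomy(species_groups):
    """Hand-build 7-rank tuples from (phylum, class, order, family, genus, species)
    shorthand; superkingdom defaults to Bacteria."""
    out = []
    for g in species_groups:
        if len(g) == 7:
            out.append(tuple(g))
        else:
            out.append(("Bacteria",) + tuple(g))
    return out


def complete_config(n_species, seed, **overrides):
    """Synthetic config with no missingness: every species carries every trait."""
    kw = dict(
        n_species=n_species,
        seed=seed,
        species_missing_prob={
            "growth": 0.0,
            "cell_diameter_um": 0.0,
            "genome_size_bp": 0.0,
            "rrn_copies": 0.0,
            "habitat": 0.0,
            "shape": 0.0,
        },
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


def clean_record_config(n_species, seed, **overrides):
    """Config whose record layer adds no noise, outliers, gaps or flips."""
    kw = dict(
        record_noise_sd={
            "cell_diameter_um": 0.0,
            "genome_size_bp": 0.0,
            "mu_max_per_h": 0.0,
            "rrn_copies": 0.0,
        },
        temp_record_sd=0.0,
        outlier_prob=0.0,
        record_missing_prob=0.0,
        categorical_flip_prob=0.0,
        intracellular_prob=0.0,
        mycoplasma_prob=0.0,
    )
    kw.update(overrides)
    return complete_config(n_species, seed, **kw)


@pytest.fixture(scope="session")
def toy_records():
    """A tiny hand-written record table exercising averaging and majority rule."""
    base = dict(zip(RANKS[:-1], ["Bacteria", "P1", "C1", "O1", "F1", "G1"]))
    rows = []
    for i, (sp, d, hab, shape) in enumerate(
        [
            ("S one", 2.0, "soil", "rod"),
            ("S one", 4.0, "soil", "coccus"),
            ("S one", np.nan, "thermal", np.nan),
            ("S two", 1.0, "marine_water", "coccus"),
        ]
    ):
        rows.append(
            {
                "record_id": f"r{i}",
                **base,
                "species": sp,
                "cell_diameter_um": d,
                "genome_size_bp": 4e6,
                "mu_max_per_h": 0.5,
                "growth_temp_C": 30.0,
                "rrn_copies": 4,
                "habitat": hab,
                "shape": shape,
                "trophic": "none",
                "intracellular": False,
                "mycoplasma": False,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size generated dataset shared across read-only tests."""
    return generate_dataset(SyntheticConfig(seed=7))
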
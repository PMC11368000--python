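import numpy as np
import pytest

from cardiopop.calcium_features import phenotype_table
from cardiopop.plate_qc import normalize_to_vehicle
from cardiopop.synthetic_study import (
    ChemicalSpec,
    StudyConfig,
    TrueHill,
    generate_study,
)


def small_chemical_set() -> list[ChemicalSpec]:
    """Five chemicals covering all phenotype classes plus an inert one."""
    return [
        ChemicalSpec(
            "CHEM_NEG", "PFCA",
            {"negative_chronotrope": TrueHill(5.0, 0.5, 1.5, "decrease")},
            exposure_median=1e-6, exposure_upper95=1e-5,
        ),
        ChemicalSpec(
            "CHEM_QT", "ALCOHOL",
            {
                "qt_prolongation": TrueHill(10.0, 0.4, 1.0, "increase"),
                "cytotoxicity": TrueHill(50.0, 0.8, 2.0, "decrease"),
            },
        ),
        ChemicalSpec("CHEM_INERT", "Other", {}),
        ChemicalSpec(
            "CHEM_ASYS", "PFSA",
            {"asystole": TrueHill(30.0, 1.0, 3.0, "decrease")},
        ),
        ChemicalSpec(
            "CHEM_POS", "PFECA",
            {"positive_chronotrope": TrueHill(2.0, 0.4, 1.2, "increase")},
        ),
    ]


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    return StudyConfig(
        n_donors=3,
        chemicals=small_chemical_set(),
        intra_plate_replicate_chemicals=("CHEM_NEG",),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_bundle):
    return phenotype_table(
        small_bundle.wells, small_bundle.traces, small_bundle.nuclei
    )


@pytest.fixture(scope="session")
def small_normalized(small_bundle, small_phenotypes):
    return normalize_to_vehicle(small_phenotypes, small_bundle.wells)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
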
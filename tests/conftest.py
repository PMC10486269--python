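import pandas as pd
import pytest

from phenoconv.knowledge_base import default_allele_tables, default_drug_kb
from phenoconv.uku import default_item_set


@pytest.fixture(scope="session")
def kb():
    return default_drug_kb()


@pytest.fixture(scope="session")
def allele_tables():
    return default_allele_tables()


@pytest.fixture(scope="session")
def item_set():
    return default_item_set()


@pytest.fixture()
def tiny_cohort():
    """Three genotyped patients; one takes a strong CYP2D6 inhibitor."""
    genotype = pd.DataFrame(
        [
            ("A", "CYP2C19", "*1", "*1"),
            ("A", "CYP2D6", "*1", "*1"),
            ("B", "CYP2C19", "*1", "*2"),
            ("B", "CYP2D6", "*4", "*4"),
            ("C", "CYP2C19", "*17", "*17"),
            ("C", "CYP2D6", "*1", "*4"),
        ],
        columns=["patient_id", "gene", "allele1", "allele2"],
    )
    medication = pd.DataFrame(
        [
            ("A", "fluoxetine", 20.0),
            ("A", "comed_01", 50.0),
            ("B", "citalopram", 20.0),
        ],
        columns=["patient_id", "drug", "dose_mg_per_day"],
    )
    return genotype, medication
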
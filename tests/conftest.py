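from pathlib import Path

import pandas as pd
import pytest

from polypharm import load_ddi_kb, load_formulary
from polypharm.cli import DEFAULT_DDI, DEFAULT_FORMULARY, DEFAULT_PRODUCTS


@pytest.fixture(scope="session")
def formulary():
    return load_formulary(DEFAULT_FORMULARY, DEFAULT_PRODUCTS)


@pytest.fixture(scope="session")
def kb(formulary):
    return load_ddi_kb(DEFAULT_DDI, formulary)


@pytest.fixture(scope="session")
def toy_formulary(tmp_path_factory):
    """Tiny 6-class formulary with one combination product and one
    excluded device class, written as delimited files."""
    tmp_path = tmp_path_factory.mktemp("toy_formulary")
    classes = tmp_path / "classes.tsv"
    classes.write_text(
        "code\tname\tchapter\texcluded\n"
        "2.4\tbeta blockers\t2\t0\n"
        "2.9.1\taspirin\t2\t0\n"
        "2.9.2\tclopidogrel\t2\t0\n"
        "4.7.2\topioids\t4\t0\n"
        "10.1.1\tNSAIDs\t10\t0\n"
        "13.13\tdressings\t13\t1\n"
    )
    products = tmp_path / "products.tsv"
    products.write_text(
        "product_code\tclass_codes\tcombination\n"
        "PA\t2.4\t0\n"
        "PB\t2.9.1\t0\n"
        "PC\t2.9.2\t0\n"
        "PD\t4.7.2\t0\n"
        "PE\t10.1.1\t0\n"
        "PF\t13.13\t0\n"
        "CO-X\t2.9.1;2.9.2\t1\n"
    )
    return load_formulary(classes, products)


def make_records(rows):
    """rows: iterable of (patient_id, iso_date, product_code)."""
    df = pd.DataFrame(rows, columns=["patient_id", "dispense_date", "product_code"])
    df["dispense_date"] = pd.to_datetime(df["dispense_date"]).dt.date
    return df
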
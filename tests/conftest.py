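from pathlib import Path

import pytest

from faersig.faers_io import QuarterRange, RawTableSet
from faersig.meddra import load_hierarchy
from faersig.preprocess import SynonymDictionary
from faersig.synthetic import DrugSpec, EventSpec, PlantedSignal, SyntheticConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def hierarchy():
    return load_hierarchy(DATA_DIR / "pt_soc_fixture.tsv")


@pytest.fixture(scope="session")
def hierarchy_path():
    return DATA_DIR / "pt_soc_fixture.tsv"


@pytest.fixture(scope="session")
def synonyms():
    return SynonymDictionary.load(DATA_DIR / "synonyms.tsv")


@pytest.fixture(scope="session")
def synonyms_path():
    return DATA_DIR / "synonyms.tsv"


def make_config(seed=1, n_reports=2000, rho=None, pt="Event 00", drug="drugx",
                n_events=25, share=0.3, duplicate_rate=0.0, female_mult=1.0,
                male_mult=1.0, **overrides):
    """Small synthetic configuration helper used across test modules."""
    events = [EventSpec(f"Event {i:02d}", f"SOC {i % 5}", 1.0 / n_events)
              for i in range(n_events)]
    planted = []
    if rho is not None:
        planted = [PlantedSignal(drug, pt, float(rho),
                                 female_mult=female_mult, male_mult=male_mult)]
    defaults = dict(
        seed=seed,
        n_reports=n_reports,
        quarter_range=QuarterRange("2015Q1", "2016Q4"),
        drugs=[DrugSpec(drug, "2015Q1", share)],
        events=events,
        planted=planted,
        duplicate_rate=duplicate_rate,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def tiny_rawset():
    """Two reports, one PS-target with a single event each."""
    return RawTableSet(
        quarter="2017Q3",
        demo_rows=[
            {"PRIMARYID": "1001", "CASEID": "1", "FDA_DT": "20170801", "SEX": "F"},
            {"PRIMARYID": "2001", "CASEID": "2", "FDA_DT": "20170802", "SEX": "M"},
        ],
        drug_rows=[
            {"PRIMARYID": "1001", "DRUG_SEQ": "1", "ROLE_COD": "PS",
             "DRUGNAME": "EMEND"},
            {"PRIMARYID": "2001", "DRUG_SEQ": "1", "ROLE_COD": "PS",
             "DRUGNAME": "ONDANSETRON"},
        ],
        reac_rows=[
            {"PRIMARYID": "1001", "PT": "Hiccups"},
            {"PRIMARYID": "2001", "PT": "Nausea"},
        ],
        outc_rows=[
            {"PRIMARYID": "1001", "OUTC_COD": "HO"},
        ],
    )
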
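import pandas as pd
import pytest

import herdcast as hc


@pytest.fixture()
def tiny_herd() -> hc.HerdDataset:
    """Hand-built 5-animal herd: two sire lines (2 + 3), no slaughter table."""
    animals = pd.DataFrame(
        {
            "animal_id": ["A1", "A2", "A3", "A4", "A5"],
            "sex": "M",
            "sire_line": ["L1", "L1", "L2", "L2", "L2"],
            "bloodline": ["B1", "B2", "B1", "B2", "B1"],
            "dam_live_weight_kg": [500.0, 512.0, 520.0, 508.0, 515.0],
        }
    )
    rows = []
    birth = {"A1": 20.0, "A2": 26.0, "A3": 32.0, "A4": 25.0, "A5": 27.0}
    month18 = {"A1": 400.5, "A2": 425.7, "A3": 455.0, "A4": 420.0, "A5": 430.0}
    for aid in animals["animal_id"]:
        rows.append({"animal_id": aid, "trait": "live_weight_kg", "age_months": 0, "value": birth[aid]})
        rows.append({"animal_id": aid, "trait": "live_weight_kg", "age_months": 18, "value": month18[aid]})
        rows.append({"animal_id": aid, "trait": "height_withers_cm", "age_months": 0, "value": 65.0 + birth[aid] / 5.0})
    return hc.HerdDataset(animals, pd.DataFrame(rows))


@pytest.fixture(scope="session")
def big_herd() -> hc.HerdDataset:
    """Default study conditions at n = 5000, frozen seed."""
    return hc.generate_herd(hc.default_config(n_animals=5000, seed=20231))


@pytest.fixture(scope="session")
def big_config():
    return hc.default_config(n_animals=5000, seed=20231)


@pytest.fixture(scope="session")
def big_tables(big_herd):
    return hc.build_tables_from_herd(big_herd)
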
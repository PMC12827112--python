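import numpy as np
import pandas as pd
import pytest

from faerskit.faers_io import CleanDataset
from faerskit.meddra import PtSocMap


def make_dataset(spec: dict, socs: dict | None = None) -> CleanDataset:
    """Build a CleanDataset from {caseid: (exposed, sex, pts)} by hand."""
    case_rows, reac_rows = [], []
    exposed = set()
    for caseid, (is_exposed, sex, pts) in spec.items():
        case_rows.append(
            {
                "caseid": caseid,
                "sex_norm": sex,
                "age_years": np.nan,
                "age_bin": "Unknown",
                "weight_kg": np.nan,
                "reporter": "Unknown",
                "country": "Unknown",
                "route": "Unknown",
                "year": 2023,
                "onset_days": np.nan,
            }
        )
        if is_exposed:
            exposed.add(caseid)
        for pt in pts:
            reac_rows.append({"caseid": caseid, "pt": pt})
    return CleanDataset(
        cases=pd.DataFrame(case_rows),
        reactions=pd.DataFrame(reac_rows, columns=["caseid", "pt"]),
        outcomes=pd.DataFrame(columns=["caseid", "outc_cod"]),
        exposed=frozenset(exposed),
    )


@pytest.fixture
def toy_dataset() -> CleanDataset:
    """Six hand-enumerable cases: three exposed, three not."""
    return make_dataset(
        {
            "E1": (True, "F", {"X"}),
            "E2": (True, "M", {"X", "Y"}),
            "E3": (True, "M", {"Y"}),
            "U1": (False, "F", {"X"}),
            "U2": (False, "M", {"Y"}),
            "U3": (False, "Unknown", {"Z"}),
        }
    )


@pytest.fixture
def toy_soc_map() -> PtSocMap:
    return PtSocMap.from_pairs([("X", "SOC_1"), ("Y", "SOC_1"), ("Z", "SOC_2")])
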
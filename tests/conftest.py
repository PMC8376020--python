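import numpy as np
import pandas as pd
import pytest

import synoptic as sy


def toy_frame() -> pd.DataFrame:
    """Two-network toy: a convergent network with a flagged outlet plus a
    non-convergent valley pair (one of them an area-0 point source)."""
    rows = []
    sites = [
        # site, network, category, area, outlet
        ("P0", "Provo", "MixedDammed", 100.0, True),
        ("P1", "Provo", "MixedDammed", 10.0, False),
        ("P2", "Provo", "MixedDammed", 30.0, False),
        ("V1", "MillRace", "ValleyTributaries", 5.0, False),
        ("V2", "MillRace", "ValleyTributaries", 0.0, False),
    ]
    conc = {
        ("P0", "Spring"): {"DOC": 1.0, "Cl": 10.0},
        ("P1", "Spring"): {"DOC": 2.0, "Cl": 12.0},
        ("P2", "Spring"): {"DOC": 5.0, "Cl": 8.0},
        ("V1", "Spring"): {"DOC": 3.0, "Cl": 40.0},
        ("V2", "Spring"): {"DOC": 9.0, "Cl": 80.0},
        ("P0", "Summer"): {"DOC": 2.0, "Cl": 10.0},
        ("P1", "Summer"): {"DOC": 4.0, "Cl": 11.0},
        ("P2", "Summer"): {"DOC": None, "Cl": 9.0},
        ("V1", "Summer"): {"DOC": 1.0, "Cl": 39.0},
        ("V2", "Summer"): {"DOC": 8.0, "Cl": 77.0},
    }
    for (sid, season), c in conc.items():
        sid_, net, cat, area, outlet = next(s for s in sites if s[0] == sid)
        rows.append(
            {
                "site_id": sid,
                "network": net,
                "category": cat,
                "area_km2": area,
                "season": season,
                "forest": 0.5,
                "developed": 0.2,
                "impervious": 0.05,
                "herbaceous": 0.1,
                "is_outlet": outlet,
                "DOC": c["DOC"],
                "Cl": c["Cl"],
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def frame() -> pd.DataFrame:
    return toy_frame()


@pytest.fixture
def table(frame) -> sy.SiteTable:
    return sy.site_table_from_frame(frame)


@pytest.fixture
def csv_path(tmp_path, frame):
    p = tmp_path / "sites.csv"
    frame.to_csv(p, index=False)
    return p


@pytest.fixture(scope="session")
def watershed():
    """One default 200-site synthetic watershed shared across tests."""
    cfg = sy.WatershedConfig(seed=11)
    table, truth = sy.generate_watershed(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def skeleton():
    return sy.generate_network(sy.WatershedConfig(seed=11))
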
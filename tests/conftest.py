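import numpy as np
import pandas as pd
import pytest

import dwkit


@pytest.fixture(scope="session")
def packaged_catalog():
    return dwkit.packaged_catalog()


@pytest.fixture(scope="session")
def survey_dws():
    return dwkit.packaged_survey_dws()


@pytest.fixture(scope="session")
def small_catalog():
    """Ten synthetic states, four anchors."""
    return dwkit.make_catalog(10, n_anchors=4, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_catalog):
    """A small clean cohort with known ground truth."""
    truth = dwkit.sample_true_dws(small_catalog, seed=5)
    cfg = dwkit.SurveyConfig(seed=17)
    resp, pc, phe = dwkit.generate_cohort(
        small_catalog, truth, n_household=150, n_web=150, config=cfg
    )
    return {"truth": truth, "config": cfg, "respondents": resp, "pc": pc, "phe": phe}


def catalog_frame(n, anchors=()):
    """Helper: a minimal valid catalog DataFrame with n states."""
    rows = []
    for i in range(1, n + 1):
        row = {
            "state_id": i,
            "label": f"S{i}",
            "lay_description": f"desc {i}",
            **{c: (i + j) % 2 for j, c in enumerate(dwkit.FLAG_COLUMNS)},
            "is_phe_anchor": int(i in anchors),
            "dw_available": 1,
        }
        rows.append(row)
    return pd.DataFrame(rows)
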
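import numpy as np
import pandas as pd
import pytest

import screenaudit as sa
from screenaudit import normalize, simdata


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured simulated experiment (fast, reused across tests)."""
    params = sa.SimulationParams(
        n_genes=120,
        reagents_per_gene=2,
        n_true_hits=20,
        reagent_fn_rate=0.1,
        reagent_fp_rate=0.01,
        seed=7,
    )
    reagent_map, truth = simdata.generate_library(params)
    readings = simdata.generate_screen_plates(reagent_map, truth, params)
    return params, reagent_map, truth, readings


@pytest.fixture(scope="session")
def small_zmatrix(small_sim):
    _, _, _, readings = small_sim
    normalized = normalize.normalize_plates(readings)
    return normalize.assemble_profile_matrix(normalized)


def per_screen_matrix(zmat: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns into one column per screen."""
    cols: dict[str, list[str]] = {}
    for c in zmat.columns:
        cols.setdefault(c.split(":")[0], []).append(c)
    return pd.DataFrame({s: zmat[cc].mean(axis=1) for s, cc in cols.items()})


@pytest.fixture(scope="session")
def one_plate():
    """A single 16x24 plate with an empty perimeter and known sample values."""
    rng = np.random.default_rng(11)
    rows = []
    for r in range(1, 17):
        for c in range(1, 25):
            perim = r in (1, 16) or c in (1, 24)
            rows.append(
                {
                    "screen_id": "s1",
                    "replicate": 1,
                    "plate_id": "P001",
                    "row": r,
                    "col": c,
                    "well_role": "empty" if perim else "sample",
                    "reagent_id": "" if perim else f"rg{r:02d}{c:02d}",
                    "value": 100.0 if perim else float(rng.normal(10, 2)),
                }
            )
    return pd.DataFrame(rows)
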
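import numpy as np
import pandas as pd
import pytest

from otocarb import synthetic as syn
from otocarb.panel import COLUMNS, OtolithPanel
from otocarb.params import GenerativeParams


def make_flat_panel(
    n_fish: int,
    max_age: int = 7,
    stock: str = "ICE",
    capture_year: int = 2000,
    tl: float | np.ndarray = 95.0,
    milled_ages: tuple[int, ...] = (),
    n_stocks: int = 1,
) -> OtolithPanel:
    """Minimal panel skeleton built vectorized (no trait values)."""
    frames = []
    stocks = ["ICE", "NEA"][:n_stocks] if n_stocks > 1 else [stock]
    for s in stocks:
        fish = np.repeat(np.arange(n_fish), max_age)
        age = np.tile(np.arange(1, max_age + 1), n_fish)
        tl_arr = np.broadcast_to(np.asarray(tl, float), (n_fish,))
        frames.append(pd.DataFrame({
            "fish_id": [f"{s}{i:05d}" for i in fish],
            "stock": s,
            "sex": "F",
            "tl_cm": tl_arr[fish],
            "age_at_capture": max_age,
            "capture_year": capture_year,
            "age": age,
            "year": capture_year - (max_age - age),
            "width_um": np.nan,
            "spawning_zone": False,
            "d13c_permil": np.nan,
            "milled": np.isin(age, milled_ages),
            "excluded": (age == 1) | (age == max_age),
        }))
    data = pd.concat(frames, ignore_index=True)[COLUMNS]
    return OtolithPanel(data)


@pytest.fixture(scope="session")
def study_params() -> GenerativeParams:
    return GenerativeParams(seed=42)


@pytest.fixture(scope="session")
def study_env(study_params):
    return syn.simulate_temperature(study_params)


@pytest.fixture(scope="session")
def study_panel(study_params, study_env):
    """Full study-scale synthetic panel with both traits filled."""
    panel = syn.generate_cohort(study_params)
    panel = syn.simulate_widths(panel, study_params, study_env)
    panel = syn.simulate_d13c_lmm(panel, study_params)
    return panel
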
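"""Bundled reference datasets.

`load_condition_means` returns the per-condition summary of the reference
photobioreactor study (nine incident infrared irradiances, 0–350 W m^-2,
with end-of-reaction biomass, residual acetate and specific growth rates),
transcribed from the published summary table so the headline logistic fit is
reproducible offline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_condition_means"]


def load_condition_means() -> pd.DataFrame:
    """Nine-condition study summary (one row per irradiance).

    Columns: irradiance_W_m2, biomass_gVSS_L, biomass_sd, acetate_mmol_L,
    acetate_sd, mu_h, mu_sd, acetate_bdl (below detection limit flag).
    """
    ref = resources.files("ppblight").joinpath("data/condition_means.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    df["acetate_bdl"] = df["acetate_bdl"].astype(str).str.lower() == "true"
    return df
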
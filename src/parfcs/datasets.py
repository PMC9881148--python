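"""Bundled reference tables.

The package ships one small dataset: reported diffusion times for
size-fractionated poly(ADP-ribose), wildtype (WT, ~1% branching) and
hyperbranched (HB), 13-50 ADP-ribose units.  ``tau_calc_us`` is the
sphere-equivalent diffusion time predicted from the chain's mass via the
globular-protein calibration; ``tau_exp_*_us`` the measured values; the
``h_*_reported`` columns carry the aspect ratios reported alongside them
(rounded to one decimal), used as cross-checks for the shape solver.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_par_diffusion_times() -> pd.DataFrame:
    """Reference diffusion-time comparison for fractionated PAR chains.

    Columns: n_units, mass_kda, tau_calc_us, tau_exp_wt_us, tau_exp_hb_us,
    h_wt_reported, h_hb_reported.  Missing cells (chains not measured in one
    variant) are NaN.
    """
    ref = resources.files("parfcs").joinpath("data/par_diffusion_times.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
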
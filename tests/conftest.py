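import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from parfcs import (
    FocusGeometry,
    SizeStandard,
    fit_size_calibration,
)
from parfcs.datasets import load_par_diffusion_times


@pytest.fixture(scope="session")
def reference_table():
    """Bundled diffusion-time comparison for fractionated PAR chains."""
    return load_par_diffusion_times()


@pytest.fixture(scope="session")
def reference_pairs(reference_table):
    """All populated (tau_calc, tau_exp, reported H) triples, in seconds."""
    pairs = []
    for _, row in reference_table.iterrows():
        for exp_col, h_col in (
            ("tau_exp_wt_us", "h_wt_reported"),
            ("tau_exp_hb_us", "h_hb_reported"),
        ):
            if not np.isnan(row[exp_col]):
                pairs.append(
                    (row["tau_calc_us"] * 1e-6, row[exp_col] * 1e-6, row[h_col])
                )
    return pairs


@pytest.fixture(scope="session")
def focus():
    """Reference-dye-calibrated focus: 284 nm lateral radius, kappa 5."""
    return FocusGeometry(omega_xy=284.25e-9, kappa=5.0)


@pytest.fixture(scope="session")
def mass_calibration(reference_table):
    """Power-law calibration fitted to the bundled (mass, tau_calc) pairs."""
    standards = [
        SizeStandard(f"n{int(r.n_units)}", r.mass_kda, r.tau_calc_us * 1e-6)
        for r in reference_table.itertuples()
    ]
    with pytest.warns(UserWarning, match="decade"):
        return fit_size_calibration(standards)
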
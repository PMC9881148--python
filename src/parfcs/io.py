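"""Readers and writers for the package's delimited-text formats.

File-boundary units follow lab convention — µs for diffusion times, nM for
concentrations, kDa for masses — while the in-memory objects use SI (seconds,
mol/L).  All formats are whitespace/comma-delimited text with ``#`` comments;
histogram files carry their metadata as ``# key: value`` header lines.
"""

from __future__ import annotations

import io as _io
import json
import re
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .binding import BindingFit, TitrationSeries
from .calibration import SizeStandard
from .correlation import CorrelationCurve, FCSFitResult
from .errors import InvalidParameterError
from .pch import PCHistogram

PathLike = Union[str, Path]


# -- correlation curves ------------------------------------------------------


def read_correlation_curve(path: PathLike) -> CorrelationCurve:
    """Two or three columns: lag_s, g2[, sd]; '#' comments allowed."""
    raw = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if raw.shape[1] not in (2, 3):
        raise InvalidParameterError("curve file needs 2 or 3 columns")
    lags = raw.iloc[:, 0].astype(float).to_numpy()
    vals = raw.iloc[:, 1].astype(float).to_numpy()
    sd = raw.iloc[:, 2].astype(float).to_numpy() if raw.shape[1] == 3 else None
    return CorrelationCurve(lags, vals, sd=sd, meta=str(path))


def write_correlation_curve(curve: CorrelationCurve, path: PathLike) -> None:
    cols = [curve.lags, curve.values] + ([curve.sd] if curve.sd is not None else [])
    header = "# lag_s g2" + (" sd" if curve.sd is not None else "")
    np.savetxt(path, np.column_stack(cols), header=header.lstrip("# "), comments="# ")


# -- titrations --------------------------------------------------------------


def read_titration(path: PathLike, probe_conc: float = 10e-9) -> TitrationSeries:
    """Columns: conc_nM, tau_us[, sd_us[, n_rep]]."""
    raw = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if raw.shape[1] < 2:
        raise InvalidParameterError("titration file needs >= 2 columns")
    conc = raw.iloc[:, 0].astype(float).to_numpy() * 1e-9
    tau = raw.iloc[:, 1].astype(float).to_numpy() * 1e-6
    sd = raw.iloc[:, 2].astype(float).to_numpy() * 1e-6 if raw.shape[1] >= 3 else None
    reps = int(raw.iloc[0, 3]) if raw.shape[1] >= 4 else 1
    return TitrationSeries(conc, tau, tau_sd=sd, probe_conc=probe_conc,
                           replicates=reps, meta=str(path))


def write_titration(series: TitrationSeries, path: PathLike) -> None:
    cols = [series.concentrations * 1e9, series.tau_mean * 1e6]
    header = "conc_nM tau_us"
    if series.tau_sd is not None:
        cols.append(series.tau_sd * 1e6)
        header += " sd_us"
    np.savetxt(path, np.column_stack(cols), header=header, comments="# ")


# -- photon-count histograms -------------------------------------------------


def read_histogram(path: PathLike) -> PCHistogram:
    """Columns: count, frequency; header keys bin_time_us and duration_s."""
    text = Path(path).read_text()
    meta = dict(
        re.findall(r"#\s*(bin_time_us|duration_s)\s*[:=]\s*([0-9.eE+-]+)", text)
    )
    raw = pd.read_csv(_io.StringIO(text), sep=None, engine="python",
                      comment="#", header=None)
    return PCHistogram(
        counts_axis=raw.iloc[:, 0].astype(int).to_numpy(),
        frequency=raw.iloc[:, 1].astype(float).to_numpy(),
        bin_time=float(meta.get("bin_time_us", 40.0)) * 1e-6,
        duration=float(meta.get("duration_s", 300.0)),
    )


def write_histogram(hist: PCHistogram, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_time_us: {hist.bin_time * 1e6:g}\n")
        fh.write(f"# duration_s: {hist.duration:g}\n")
        fh.write("# count frequency\n")
        for k, f in zip(hist.counts_axis, hist.frequency):
            fh.write(f"{int(k)} {f:g}\n")


# -- size standards ----------------------------------------------------------


def read_size_standards(path: PathLike) -> List[SizeStandard]:
    """Columns: name, mass_kDa, tau_us."""
    raw = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                      names=["name", "mass_kda", "tau_us"])
    return [
        SizeStandard(name=str(n), mass=float(m), tau_d=float(t) * 1e-6)
        for n, m, t in raw.itertuples(index=False)
    ]


# -- shape (diffusion-time comparison) tables --------------------------------

SHAPE_COLUMNS = ["n_units", "mass_kda", "tau_calc_us", "tau_exp_us"]


def read_shape_table(path: PathLike) -> pd.DataFrame:
    """Columns n_units, mass_kDa, tau_calc_us, tau_exp_us; '-' marks missing."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     header=None, names=SHAPE_COLUMNS, na_values=["-"])
    return df.apply(pd.to_numeric, errors="coerce")


# -- nucleoside tables -------------------------------------------------------


def read_nucleosides(path: PathLike) -> pd.DataFrame:
    """Columns: fraction label, ado, r_ado, r2_ado (amounts, any unit)."""
    return pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                       names=["fraction", "ado", "r_ado", "r2_ado"])


# -- JSON fit reports --------------------------------------------------------


def fcs_fit_report(result: FCSFitResult) -> str:
    return json.dumps(
        {
            "g0": result.g0,
            "tau_d_us": result.tau_d * 1e6,
            "kappa": result.kappa,
            "kappa_fixed": result.kappa_fixed,
            "chi2": result.residual_chi2,
            "fit_window_s": list(result.fit_window),
            "n_points": result.n_points,
            "covariance": None
            if result.covariance is None
            else np.asarray(result.covariance).tolist(),
            "parameters": list(result.param_names),
        },
        indent=2,
    )


def binding_fit_report(fit: BindingFit) -> str:
    return json.dumps(
        {
            "kd_nM": fit.kd * 1e9,
            "kd_ci95_nM": [fit.ci[0] * 1e9, fit.ci[1] * 1e9],
            "tau_free_us": fit.tau_free * 1e6,
            "tau_bound_us": fit.tau_bound * 1e6,
            "window_nM": [fit.window[0] * 1e9, fit.window[1] * 1e9],
            "estimable": fit.estimable,
            "chi2": fit.chi2,
            "n_points": fit.n_points,
        },
        indent=2,
    )
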
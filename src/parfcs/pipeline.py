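"""Batch workflows: shape tables and binding-suite summaries.

These are the end-to-end entry points the CLI wraps: turn a diffusion-time
comparison table into per-row aspect ratios, and a batch of titrations into a
Kd/onset/stoichiometry summary with per-file error isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binding import TitrationSeries, detect_onset, estimate_stoichiometry, fit_kd
from .calibration import SizeCalibration
from .errors import ParFCSError
from .shape import solve_aspect_ratio

log = logging.getLogger("parfcs")


def run_shape_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add an aspect-ratio column to a (tau_calc, tau_exp) comparison table.

    Expects columns ``tau_calc_us`` and one or more ``tau_exp*`` columns
    (µs); for each a matching ``H*`` column is appended.  Missing cells
    propagate as NaN; malformed rows log a diagnostic and continue.
    """
    out = table.copy()
    exp_cols = [c for c in table.columns if c.startswith("tau_exp")]
    for col in exp_cols:
        suffix = col[len("tau_exp"):].replace("_us", "")
        h_col = "H" + suffix
        hs = np.full(len(table), np.nan)
        for i, (tc, te) in enumerate(zip(table["tau_calc_us"], table[col])):
            if pd.isna(tc) or pd.isna(te):
                continue
            try:
                hs[i] = solve_aspect_ratio(float(te), float(tc))
            except ParFCSError as exc:
                log.warning("row %d (%s): %s", i, col, exc)
        out[h_col] = hs
    return out


@dataclass(frozen=True)
class BindingSuiteRow:
    """One titration's summary line (concentrations in nM, 'N.D.' when not estimable)."""

    label: str
    kd_nM: Optional[float]
    kd_ci_nM: Tuple[float, float]
    onset_nM: Optional[float]
    n_bound: Optional[float]
    estimable: bool
    error: Optional[str] = None


def run_binding_suite(
    titrations: Sequence[Tuple[str, TitrationSeries]],
    window: Optional[Tuple[float, float]] = None,
    cal: Optional[SizeCalibration] = None,
    probe_mass: Optional[float] = None,
    unit_mass: Optional[float] = None,
    onset_z: float = 3.0,
) -> pd.DataFrame:
    """Fit Kd + onset (+ stoichiometry when a calibration is given) per series.

    One failing series never aborts the batch; its row carries the error
    message instead.  The summary mirrors the qualitative comparison table of
    a binding study: Kd (or N.D.), onset concentration, bound-protein count.
    """
    rows = []
    for label, series in titrations:
        try:
            fit = fit_kd(series, window=window)
            onset = detect_onset(series, z=onset_z)
            n_bound = None
            if cal is not None and probe_mass and unit_mass:
                tau_top = float(series.tau_mean[np.argmax(series.concentrations)])
                n_bound = estimate_stoichiometry(
                    tau_top, cal, probe_mass, unit_mass
                ).n_bound
            rows.append(
                BindingSuiteRow(
                    label=label,
                    kd_nM=fit.kd * 1e9 if fit.estimable else None,
                    kd_ci_nM=(fit.ci[0] * 1e9, fit.ci[1] * 1e9),
                    onset_nM=onset * 1e9 if onset is not None else None,
                    n_bound=n_bound,
                    estimable=fit.estimable,
                )
            )
        except ParFCSError as exc:
            log.warning("titration %s failed: %s", label, exc)
            rows.append(
                BindingSuiteRow(
                    label=label, kd_nM=None, kd_ci_nM=(float("nan"), float("nan")),
                    onset_nM=None, n_bound=None, estimable=False, error=str(exc),
                )
            )
    columns = ["label", "kd_nM", "kd_ci_nM", "onset_nM", "n_bound", "estimable", "error"]
    df = pd.DataFrame([r.__dict__ for r in rows], columns=columns)
    df["kd_display"] = [
        f"{k:.3g}" if k is not None and not pd.isna(k) else "N.D."
        for k in df["kd_nM"]
    ]
    return df
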
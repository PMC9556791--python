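"""Readers for the delimited-text table formats the analysis consumes.

All readers accept CSV or TSV (delimiter sniffed by pandas) and return the
package's in-memory containers.  Column conventions:

- relaxation series: ``delay_s, intensity``
- dephasing curves: ``time, signal[, sigma]`` or ``time, S0, S1`` (REDOR)
- 2D spectra: first row holds the f2 ppm axis, first column the f1 ppm
  axis, the remaining block the intensity matrix
- MPL intensity tables: ``i_fibril, i_bg_fibril, i_tmv, i_bg_tmv``
- chemical-shift tables: ``residue, ca, cb, co`` (blank cells allowed)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .assays import ThTTrace
from .dipolar import DephasingCurve, redor_from_s0_s1
from .mpl import MPLMeasurement
from .relaxation import RelaxationSeries
from .spindiff import ShiftRecord, Spectrum2D


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_relaxation_series(
    path, kind: str, temperature: float = 298.0, label: str = ""
) -> RelaxationSeries:
    df = _read_table(path)
    return RelaxationSeries(
        kind=kind,
        delays=df["delay_s"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        temperature=temperature,
        label=label or str(path),
    )


def read_dephasing_curve(path, experiment: str) -> DephasingCurve:
    df = _read_table(path)
    if {"S0", "S1"}.issubset(df.columns):
        return redor_from_s0_s1(
            df["time"].to_numpy(), df["S0"].to_numpy(), df["S1"].to_numpy()
        )
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return DephasingCurve(
        experiment=experiment,
        times=df["time"].to_numpy(),
        signal=df["signal"].to_numpy(),
        sigma=sigma,
        label=str(path),
    )


def read_spectrum2d(path, label: str = "") -> Spectrum2D:
    raw = pd.read_csv(path, header=None, sep=None, engine="python").to_numpy(float)
    return Spectrum2D(
        axis_f1=raw[1:, 0],
        axis_f2=raw[0, 1:],
        intensity=raw[1:, 1:],
        label=label or str(path),
    )


def write_spectrum2d(path, spec: Spectrum2D) -> None:
    block = np.zeros((spec.axis_f1.size + 1, spec.axis_f2.size + 1))
    block[0, 1:] = spec.axis_f2
    block[1:, 0] = spec.axis_f1
    block[1:, 1:] = spec.intensity
    np.savetxt(path, block, delimiter=",")


def read_mpl_intensities(path) -> list[MPLMeasurement]:
    df = _read_table(path)
    return [
        MPLMeasurement(
            i_fibril=row.i_fibril,
            i_bg_fibril=row.i_bg_fibril,
            i_tmv=row.i_tmv,
            i_bg_tmv=row.i_bg_tmv,
        )
        for row in df.itertuples()
    ]


def read_shift_table(path) -> list[ShiftRecord]:
    df = _read_table(path)

    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [
        ShiftRecord(
            residue=str(row.residue),
            delta_ca=_opt(getattr(row, "ca", np.nan)),
            delta_cb=_opt(getattr(row, "cb", np.nan)),
            delta_co=_opt(getattr(row, "co", np.nan)),
        )
        for row in df.itertuples()
    ]


def read_tht_trace(path, replicate_id: str = "") -> ThTTrace:
    df = _read_table(path)
    return ThTTrace(
        times=df["time_h"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
        replicate_id=replicate_id or str(path),
    )
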
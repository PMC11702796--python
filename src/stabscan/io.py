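"""Readers and writers for every table the pipeline touches.

Formats are deliberately plain and fixed (no dialect sniffing):

* spectra CSV — ``#key=value`` metadata header lines (at least
  ``#condition_kind=`` and ``#direction=``), then a ``wavelength_nm`` column
  plus one column per condition named by its numeric value.  Comma separated,
  UTF-8, dot decimal.  Condition values are kelvin (thermal) or molar
  (chemical); no unit auto-conversion.
* trajectory TSV — columns step, replica_id, temperature_K, energy_kcal_mol,
  rg_angstrom, helix_fraction; optional exchange-log TSV with step,
  replica_a, replica_b, accepted (plus temp_a_K/temp_b_K when available).
* predictor TSV — columns mutation, tool, ddg_kcal_mol with the convention
  ddG = dG(WT) - dG(mutant), negative = destabilising.
* reference TSV — columns mutation, score.

Instrument-native exports (e.g. Fluorolog) must be pre-converted to the
spectra CSV above; :func:`convert_instrument_export` is a stub documenting
that boundary.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .denaturation import DenaturationSeries
from .errors import ValidationError
from .rex import EXCHANGE_COLUMNS, FRAME_COLUMNS, ReplicaExchangeDataset

log = logging.getLogger("stabscan")

_KNOWN_KINDS = ("temperature", "denaturant")


# ---------------------------------------------------------------------------
# spectra CSV
# ---------------------------------------------------------------------------

def read_spectra_csv(path) -> DenaturationSeries:
    """Read a denaturation spectra series; conditions are sorted ascending."""
    path = Path(path)
    meta: dict[str, str] = {}
    header_rows = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                header_rows += 1
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
            else:
                break
    kind = meta.get("condition_kind")
    if kind not in _KNOWN_KINDS:
        raise ValidationError(f"unknown condition kind: {kind!r}")
    direction = meta.get("direction", "unfolding")

    df = pd.read_csv(path, skiprows=header_rows)
    if "wavelength_nm" not in df.columns:
        raise ValidationError("missing wavelength column 'wavelength_nm'")
    if df.isna().any().any():
        raise ValidationError("missing intensity cells (ragged columns)")
    wavelengths = df["wavelength_nm"].to_numpy(float)
    if not np.all(np.diff(wavelengths) > 0):
        raise ValidationError("non-monotonic wavelength grid")
    cond_cols = [c for c in df.columns if c != "wavelength_nm"]
    try:
        conditions = np.array([float(c) for c in cond_cols])
    except ValueError as exc:
        raise ValidationError(f"non-numeric condition column name: {exc}") from exc
    intensities = df[cond_cols].to_numpy(float).T
    extra = {k: v for k, v in meta.items()
             if k not in ("condition_kind", "direction")}
    return DenaturationSeries(kind, conditions, wavelengths, intensities,
                              direction, meta=extra)


def write_spectra_csv(series: DenaturationSeries, path) -> Path:
    """Write a series in the spectra CSV dialect (10 significant digits)."""
    if len(series) == 0:
        raise ValidationError("refusing to write an empty series")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#condition_kind={series.condition_kind}\n")
        fh.write(f"#direction={series.direction}\n")
        for k, v in series.meta.items():
            fh.write(f"#{k}={v}\n")
        cols = ",".join(f"{c:.10g}" for c in series.conditions)
        fh.write(f"wavelength_nm,{cols}\n")
        for i, wl in enumerate(series.wavelengths):
            row = ",".join(f"{v:.10g}" for v in series.intensities[:, i])
            fh.write(f"{wl:.10g},{row}\n")
    return path


def convert_instrument_export(path) -> DenaturationSeries:
    """Placeholder for instrument-native exports.

    Raw fluorimeter exports vary by vendor and are not parsed here; convert
    them to the spectra CSV dialect first.
    """
    raise NotImplementedError(
        "instrument-native exports are not parsed; pre-convert to the "
        "spectra CSV dialect (see module docstring)")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def read_trajectory_table(path, exchange_path=None) -> ReplicaExchangeDataset:
    """Read frame (and optional exchange-log) TSVs into a dataset."""
    frames = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise ValidationError(f"missing frame columns: {missing}")
    exchange = None
    if exchange_path is not None:
        exchange = pd.read_csv(Path(exchange_path), sep="\t")
        miss = [c for c in EXCHANGE_COLUMNS if c not in exchange.columns]
        if miss:
            raise ValidationError(f"missing exchange-log columns: {miss}")
    return ReplicaExchangeDataset(frames, None, exchange)


def write_trajectory_table(data: ReplicaExchangeDataset, path,
                           exchange_path=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data.frames.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if exchange_path is not None and data.exchange is not None:
        data.exchange.to_csv(Path(exchange_path), sep="\t", index=False,
                             float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# predictor and reference tables
# ---------------------------------------------------------------------------

def read_predictor_table(path) -> pd.DataFrame:
    """Per-(mutation, tool) predicted ddG table; duplicate keys rejected."""
    df = pd.read_csv(Path(path), sep="\t")
    required = ["mutation", "tool", "ddg_kcal_mol"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing predictor columns: {missing}")
    if len(df) == 0:
        warnings.warn("predictor table is empty", stacklevel=2)
        log.warning("predictor table %s is empty", path)
        return df
    if not pd.api.types.is_numeric_dtype(df["ddg_kcal_mol"]):
        raise ValidationError("non-numeric ddg_kcal_mol values")
    dup = df.duplicated(subset=["mutation", "tool"])
    if dup.any():
        first = df.loc[dup, ["mutation", "tool"]].iloc[0]
        raise ValidationError(
            f"duplicate (mutation, tool) key: ({first['mutation']}, {first['tool']})")
    return df


def write_predictor_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_reference_scores(path) -> pd.Series:
    """Per-mutation reference pathogenicity scores (columns mutation, score)."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in ("mutation", "score") if c not in df.columns]
    if missing:
        raise ValidationError(f"missing reference columns: {missing}")
    if df["mutation"].duplicated().any():
        raise ValidationError("duplicate mutation in reference scores")
    return df.set_index("mutation")["score"].astype(float)


def write_reference_scores(scores: pd.Series, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scores.rename("score").rename_axis("mutation").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g")
    return path
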
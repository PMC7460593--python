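"""CSV readers/writers for the pipeline's file interfaces.

All tables are plain CSV with fixed column schemas:

* colony counts: ``mode, position, dose_gy, run, well, seeded, colonies``
* endpoint measurements: ``endpoint, mode, position, dose_gy, time_h,
  run, replicate, value``
* LET spectra: ``species, let_kev_um, dose_weight`` (+ ``mode, position``)
* neutron spectra: ``energy_mev, weight`` (+ ``mode, position``)

Every writer round-trips through its reader.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .letd import LETSpectrum, NeutronSpectrum
from .synthetic import COLONY_COLUMNS, ENDPOINT_COLUMNS

LET_COLUMNS = ["species", "let_kev_um", "dose_weight", "mode", "position"]
NEUTRON_COLUMNS = ["energy_mev", "weight", "mode", "position"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns: {sorted(missing)}")


def write_colony_counts(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, COLONY_COLUMNS, "colony count")
    df[COLONY_COLUMNS].to_csv(path, index=False)


def read_colony_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, COLONY_COLUMNS, "colony count")
    return df


def write_endpoint_data(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, ENDPOINT_COLUMNS, "endpoint")
    df[ENDPOINT_COLUMNS].to_csv(path, index=False)


def read_endpoint_data(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ENDPOINT_COLUMNS, "endpoint")
    return df


def write_let_spectra(spectra, path: str | Path) -> None:
    """Write a collection (or mapping) of LET spectra to one CSV."""
    if hasattr(spectra, "values"):
        spectra = list(spectra.values())
    rows = []
    for spec in spectra:
        for let, w in zip(spec.let, spec.dose_weight):
            rows.append((spec.species, let, w, spec.mode, spec.position))
    pd.DataFrame(rows, columns=LET_COLUMNS).to_csv(path, index=False)


def read_let_spectra(path: str | Path) -> dict[str, LETSpectrum]:
    """Read LET spectra CSV into a mapping species -> spectrum."""
    df = pd.read_csv(path)
    _check_columns(df, LET_COLUMNS[:3], "LET spectrum")
    out: dict[str, LETSpectrum] = {}
    for species, grp in df.groupby("species", sort=False):
        mode = grp["mode"].iloc[0] if "mode" in grp else None
        position = grp["position"].iloc[0] if "position" in grp else None
        out[str(species)] = LETSpectrum(
            str(species),
            grp["let_kev_um"].to_numpy(float),
            grp["dose_weight"].to_numpy(float),
            position=None if pd.isna(position) else int(position),
            mode=None if pd.isna(mode) else str(mode),
        )
    return out


def write_neutron_spectrum(spectrum: NeutronSpectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "energy_mev": spectrum.energy,
            "weight": spectrum.weight,
            "mode": spectrum.mode,
            "position": spectrum.position,
        }
    )
    df.to_csv(path, index=False)


def read_neutron_spectrum(path: str | Path) -> NeutronSpectrum:
    df = pd.read_csv(path)
    _check_columns(df, NEUTRON_COLUMNS[:2], "neutron spectrum")
    mode = df["mode"].iloc[0] if "mode" in df else None
    position = df["position"].iloc[0] if "position" in df else None
    return NeutronSpectrum(
        df["energy_mev"].to_numpy(float),
        df["weight"].to_numpy(float),
        position=None if pd.isna(position) else int(position),
        mode=None if pd.isna(mode) else str(mode),
    )
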
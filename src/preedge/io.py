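"""Plain-text interchange formats.

* XY spectrum files: two columns (energy eV, intensity), whitespace or
  comma separated, with ``#``-prefixed header lines carrying
  ``key: value`` metadata.  Round-trips exactly at printed precision.
* Stick tables: delimited text with header
  ``model_id,site,energy_eV,intensity``, one row per transition;
  dialect-tolerant (comma, tab or whitespace) so externally deposited
  transition tables can be adapted.
* Ranking tables: CSV with per-model RMSD, rank, exclusion flags and
  the calibration/kernel provenance columns.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibrate import CalibrationParams
from .rank import ModelEntry, RankingResult
from .spectra import MN_SITES, BroadeningKernel, Spectrum, StickSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_stick_table",
    "write_stick_table",
    "write_ranking_csv",
]

_STICK_COLUMNS = ("model_id", "site", "energy_eV", "intensity")


def read_spectrum(path) -> Spectrum:
    """Parse a two-column XY file; malformed lines are reported with
    their line numbers, non-monotone energies and NaNs are rejected."""
    path = Path(path)
    meta: dict = {}
    energies: list[float] = []
    intensities: list[float] = []
    prev = -np.inf
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}: {line!r}"
                )
            try:
                e, y = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value: {line!r}") from exc
            if not (np.isfinite(e) and np.isfinite(y)):
                raise ValueError(f"{path}:{lineno}: non-finite value: {line!r}")
            if e <= prev:
                raise ValueError(
                    f"{path}:{lineno}: energies must be strictly increasing "
                    f"({e} after {prev})"
                )
            prev = e
            energies.append(e)
            intensities.append(y)
    if not energies:
        raise ValueError(f"{path}: no data rows")
    return Spectrum(np.asarray(energies), np.asarray(intensities), meta)


def write_spectrum(s: Spectrum, path) -> None:
    """Write an XY file with metadata header; shortest-round-trip float
    formatting makes ``read_spectrum(write_spectrum(s))`` exact."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in s.meta.items():
            fh.write(f"# {key}: {value}\n")
        for e, y in zip(s.energies, s.intensities):
            fh.write(f"{float(e)!r} {float(y)!r}\n")


def _sniff_table(path: Path) -> pd.DataFrame:
    text = path.read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    kwargs = {"float_precision": "round_trip"}  # exact round trips
    if "," in first:
        return pd.read_csv(_io.StringIO(text), **kwargs)
    if "\t" in first:
        return pd.read_csv(_io.StringIO(text), sep="\t", **kwargs)
    return pd.read_csv(_io.StringIO(text), sep=r"\s+", **kwargs)


def read_stick_table(path) -> list[ModelEntry]:
    """Read transition rows grouped by model and site.

    Rows may appear in any order; every model must provide all four Mn
    sites (a site with no transitions may be listed with zero rows only
    if another model defines it — in practice emit explicit rows).
    """
    path = Path(path)
    df = _sniff_table(path)
    missing = [c for c in _STICK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must "
                         f"contain {_STICK_COLUMNS}")
    bad_sites = sorted(set(df["site"].astype(str)) - set(MN_SITES))
    if bad_sites:
        raise ValueError(f"{path}: unknown site label(s) {bad_sites}; "
                         f"expected one of {MN_SITES}")
    classes = {}
    if "binding_mode_class" in df.columns:
        classes = (
            df.groupby("model_id")["binding_mode_class"].first().astype(str).to_dict()
        )
    models = []
    for model_id, grp in df.groupby("model_id", sort=True):
        sticks = []
        for site in MN_SITES:
            rows = grp[grp["site"] == site]
            sticks.append(
                StickSpectrum(
                    site,
                    rows["energy_eV"].to_numpy(dtype=float),
                    rows["intensity"].to_numpy(dtype=float),
                )
            )
        models.append(
            ModelEntry(
                str(model_id),
                tuple(sticks),
                binding_mode_class=classes.get(model_id, "unknown"),
            )
        )
    return models


def write_stick_table(models: Iterable[ModelEntry], path) -> None:
    path = Path(path)
    rows = []
    for m in models:
        for st in m.site_sticks:
            for e, y in zip(st.energies, st.intensities):
                rows.append(
                    {
                        "model_id": m.model_id,
                        "site": st.site,
                        "energy_eV": repr(float(e)),
                        "intensity": repr(float(y)),
                        "binding_mode_class": m.binding_mode_class,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ranking_csv(
    results: Sequence[RankingResult],
    path,
    calibration: CalibrationParams | None = None,
    kernel: BroadeningKernel | None = None,
) -> None:
    """Ranking table with full provenance: every row records the
    calibration and broadening it was produced with."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "model_id",
                "binding_mode_class",
                "rmsd",
                "rank",
                "excluded",
                "exclusion_reason",
                "calibration_shift_eV",
                "calibration_scale",
                "kernel_fwhm_eV",
            ]
        )
        for r in sorted(
            results, key=lambda r: (r.rank is None, r.rank or 0, r.model_id)
        ):
            writer.writerow(
                [
                    r.model_id,
                    r.binding_mode_class,
                    f"{r.rmsd:.6e}" if np.isfinite(r.rmsd) else "nan",
                    "" if r.rank is None else r.rank,
                    str(bool(r.excluded)),
                    r.exclusion_reason,
                    "" if calibration is None else f"{calibration.shift:.4f}",
                    "" if calibration is None else f"{calibration.scale:.6g}",
                    "" if kernel is None else f"{kernel.fwhm:.3f}",
                ]
            )
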
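"""Reading and writing of force curves and derived tables.

Formats
-------
* **HDF5 container** — ``/curves/<id>/{time,extension,force}`` with
  attributes ``pulling_speed_nm_s`` and ``configuration``; simulated data
  may carry an optional ``/ground_truth`` table group.
* **TSV** — one curve per file, tab-separated with header
  ``time_s<TAB>extension_nm<TAB>force_pN`` and optional ``# key = value``
  metadata lines (``pulling_speed_nm_s``, ``configuration``) before it.
* **CSV** — events, master histogram and ground-truth tables (pandas).

Malformed curves are skipped with a logged warning; an input yielding zero
valid curves is an error.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .curve_processing import ContourLengthHistogram, ForceCurve

logger = logging.getLogger("forcespec")

__all__ = [
    "read_curves",
    "write_curves_h5",
    "write_curve_tsv",
    "read_curve_tsv",
    "write_events_csv",
    "write_histogram_csv",
    "read_ground_truth",
]

TSV_HEADER = "time_s\textension_nm\tforce_pN"


def write_curve_tsv(path: str | Path, curve: ForceCurve) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# pulling_speed_nm_s = {curve.pulling_speed!r}\n")
        fh.write(f"# configuration = {curve.configuration}\n")
        fh.write(TSV_HEADER + "\n")
        for t, x, f in zip(curve.time, curve.extension, curve.force):
            fh.write(f"{float(t)!r}\t{float(x)!r}\t{float(f)!r}\n")


def read_curve_tsv(path: str | Path) -> ForceCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("#").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: expected 3 tab-separated columns")
            rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    return ForceCurve(
        time=arr[:, 0],
        extension=arr[:, 1],
        force=arr[:, 2],
        pulling_speed=float(meta.get("pulling_speed_nm_s", "nan")),
        curve_id=path.stem,
        configuration=meta.get("configuration", "unknown"),
    )


def write_curves_h5(
    path: str | Path,
    curves: Iterable[ForceCurve],
    ground_truth: pd.DataFrame | None = None,
) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("curves")
        for curve in curves:
            g = grp.create_group(curve.curve_id)
            g.create_dataset("time", data=curve.time)
            g.create_dataset("extension", data=curve.extension)
            g.create_dataset("force", data=curve.force)
            g.attrs["pulling_speed_nm_s"] = curve.pulling_speed
            g.attrs["configuration"] = curve.configuration
        if ground_truth is not None:
            gt = h5.create_group("ground_truth")
            for col in ground_truth.columns:
                data = ground_truth[col].to_numpy()
                if data.dtype == object or data.dtype.kind in "US":
                    data = np.array(
                        [str(v) for v in data], dtype=h5py.string_dtype("utf-8")
                    )
                gt.create_dataset(col, data=data)


def read_ground_truth(path: str | Path) -> pd.DataFrame | None:
    with h5py.File(path, "r") as h5:
        if "ground_truth" not in h5:
            return None
        gt = h5["ground_truth"]
        cols = {}
        for name in gt:
            data = gt[name][()]
            if data.dtype.kind in ("O", "S"):
                data = np.array([v.decode() if isinstance(v, bytes) else v for v in data])
            cols[name] = data
        return pd.DataFrame(cols)


def _read_curves_h5(path: Path) -> list[ForceCurve]:
    curves: list[ForceCurve] = []
    with h5py.File(path, "r") as h5:
        if "curves" not in h5:
            raise ValueError(f"{path}: no /curves group")
        for cid in sorted(h5["curves"]):
            g = h5["curves"][cid]
            try:
                curves.append(
                    ForceCurve(
                        time=g["time"][()],
                        extension=g["extension"][()],
                        force=g["force"][()],
                        pulling_speed=float(g.attrs.get("pulling_speed_nm_s", np.nan)),
                        curve_id=cid,
                        configuration=str(g.attrs.get("configuration", "unknown")),
                    )
                )
            except (ValueError, KeyError) as exc:
                logger.warning("skipping malformed curve %s: %s", cid, exc)
    return curves


def read_curves(path: str | Path, format: str | None = None) -> list[ForceCurve]:
    """Read force curves from an HDF5 container or TSV file(s).

    ``path`` may be an ``.h5``/``.hdf5`` container, a single ``.tsv`` file,
    or a directory of ``.tsv`` files. Malformed curves are skipped with a
    warning; zero valid curves is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "tsv"
        elif path.suffix.lower() in (".h5", ".hdf5"):
            format = "hdf5"
        else:
            format = "tsv"
    if format == "hdf5":
        curves = _read_curves_h5(path)
    elif format == "tsv":
        files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
        curves = []
        for f in files:
            try:
                curves.append(read_curve_tsv(f))
            except (ValueError, OSError) as exc:
                logger.warning("skipping malformed curve file %s: %s", f, exc)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not curves:
        raise ValueError(f"{path}: no valid curves found")
    return curves


def write_events_csv(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def write_histogram_csv(path: str | Path, hist: ContourLengthHistogram) -> None:
    pd.DataFrame(
        {
            "bin_left_nm": hist.bin_edges[:-1],
            "bin_right_nm": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(path, index=False)
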
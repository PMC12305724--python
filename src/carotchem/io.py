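"""File formats: delimited spectra/tables, JCAMP-DX, model JSON, YAML config.

Delimited dialect is comma-separated UTF-8 with '.' decimal and a
mandatory header row.  Spectra matrices are written wide: first column
the wavenumber (cm^-1, ascending), one column per replicate scan with
header ``sample_id.replicate``.  JCAMP-DX support covers single-spectrum
files with ``XYDATA=(X++(Y..Y))`` (AFFN, equidistant X) and
``XYPOINTS=(XY..XY)`` blocks.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from carotchem.pls import CalibrationModel
from carotchem.spectra import SpectraSet

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_jcamp",
    "read_jcamp",
    "save_model",
    "load_model",
    "write_table",
    "read_table",
    "load_config_file",
    "config_hash",
]

_FLOAT_FMT = "%.10g"


def write_spectra(path: str | Path, spectra: SpectraSet) -> None:
    """Write a spectra set as a wide CSV (wavenumber + one column per scan)."""
    df = pd.DataFrame(
        spectra.absorbance.T,
        columns=spectra.column_labels(),
    )
    df.insert(0, "wavenumber", spectra.wavenumbers)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _parse_scan_label(label: str) -> tuple[str, int]:
    """Split 'sample.rep' column headers; a missing suffix means replicate 1."""
    if "." in label:
        stem, _, suffix = label.rpartition(".")
        if suffix.isdigit():
            return stem, int(suffix)
    return label, 1


def read_spectra(path: str | Path, format: str = "auto") -> SpectraSet:
    """Read spectra from a delimited matrix or a JCAMP-DX file.

    ``format`` is 'delimited', 'jcamp', or 'auto' (by file extension:
    .jdx/.dx/.jcamp are JCAMP, everything else delimited).
    """
    path = Path(path)
    if format == "auto":
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcamp"} else "delimited"
    if format == "jcamp":
        x, y, title = read_jcamp(path)
        return SpectraSet(
            wavenumbers=x,
            absorbance=y[None, :],
            sample_ids=np.array([title or path.stem]),
            replicate_ids=np.array([1]),
        )
    if format != "delimited":
        raise ValueError(f"unknown spectra format {format!r}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectra file needs a wavenumber column plus >= 1 scan")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wn) <= 0):
        raise ValueError("wavenumber grid in file is not strictly increasing")
    labels = [_parse_scan_label(c) for c in df.columns[1:]]
    return SpectraSet(
        wavenumbers=wn,
        absorbance=df.iloc[:, 1:].to_numpy(dtype=float).T,
        sample_ids=np.array([s for s, _ in labels]),
        replicate_ids=np.array([r for _, r in labels]),
    )


# ---------------------------------------------------------------------------
# JCAMP-DX

def write_jcamp(
    path: str | Path,
    wavenumbers: np.ndarray,
    absorbance: np.ndarray,
    title: str = "spectrum",
) -> None:
    """Write one spectrum as JCAMP-DX with XYDATA=(X++(Y..Y)) encoding.

    Requires an equidistant grid (the DELTAX convention); raises otherwise.
    """
    x = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(absorbance, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("grid and absorbance lengths differ")
    steps = np.diff(x)
    if x.size < 2 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * abs(steps[0])):
        raise ValueError("JCAMP XYDATA export needs an equidistant grid")
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NEAR INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={x[0]:.6f}",
        f"##LASTX={x[-1]:.6f}",
        f"##DELTAX={steps[0]:.6f}",
        f"##NPOINTS={x.size}",
        f"##FIRSTY={y[0]:.8g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for start in range(0, x.size, per_line):
        chunk = y[start : start + per_line]
        vals = " ".join(f"{v:.8g}" for v in chunk)
        lines.append(f"{x[start]:.4f} {vals}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_jcamp(path: str | Path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a single-spectrum JCAMP-DX file.

    Supports ``XYDATA=(X++(Y..Y))`` (per-line abscissa + DELTAX-implied
    spacing, XFACTOR/YFACTOR applied) and ``XYPOINTS=(XY..XY)`` pairs.
    Returns (x, y, title); x is forced ascending.
    """
    text = Path(path).read_text(encoding="utf-8")
    fields: dict[str, str] = {}
    mode = None
    data_lines: list[str] = []
    for raw in text.splitlines():
        line = raw.split("$$")[0].strip()  # strip comments
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                mode = "xydata"
                continue
            if key == "XYPOINTS":
                mode = "xypoints"
                continue
            if key == "END":
                break
            fields[key] = value
            mode = None
        elif mode in ("xydata", "xypoints"):
            data_lines.append(line)
    if mode is None and not data_lines:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS block found")
    title = fields.get("TITLE", "")
    xfac = float(fields.get("XFACTOR", 1.0))
    yfac = float(fields.get("YFACTOR", 1.0))
    if mode == "xypoints" or (data_lines and ("," in data_lines[0] and mode != "xydata")):
        pairs = []
        for line in data_lines:
            for token in re.split(r"[;\s]+", line):
                if token:
                    pairs.append(token)
        values = [float(v) for chunk in pairs for v in chunk.split(",") if v]
        arr = np.asarray(values, dtype=float).reshape(-1, 2)
        x, y = arr[:, 0] * xfac, arr[:, 1] * yfac
    else:
        deltax = fields.get("DELTAX")
        npoints = int(fields["NPOINTS"]) if "NPOINTS" in fields else None
        if deltax is None:
            if "FIRSTX" not in fields or "LASTX" not in fields or npoints is None:
                raise ValueError(f"{path}: XYDATA needs DELTAX or FIRSTX/LASTX/NPOINTS")
            dx = (float(fields["LASTX"]) - float(fields["FIRSTX"])) / (npoints - 1)
        else:
            dx = float(deltax)
        xs: list[float] = []
        ys: list[float] = []
        for line in data_lines:
            tokens = line.replace(",", " ").split()
            x0 = float(tokens[0]) * xfac
            yvals = [float(t) * yfac for t in tokens[1:]]
            xs.extend(x0 + dx * xfac * i for i in range(len(yvals)))
            ys.extend(yvals)
        x, y = np.asarray(xs), np.asarray(ys)
        if npoints is not None and x.size != npoints:
            raise ValueError(f"{path}: NPOINTS={npoints} but parsed {x.size} points")
    if x.size >= 2 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return x, y, title


# ---------------------------------------------------------------------------
# models, tables, config

def save_model(path: str | Path, model: CalibrationModel) -> None:
    """Serialize a calibration model (chain included) to JSON text."""
    d = model.to_dict()
    d["config_hash"] = model.config_hash()
    Path(path).write_text(json.dumps(d, sort_keys=True), encoding="utf-8")


def load_model(path: str | Path) -> CalibrationModel:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    stored = d.pop("config_hash", None)
    model = CalibrationModel.from_dict(d)
    if stored is not None and model.config_hash() != stored:
        raise ValueError(f"{path}: model config hash mismatch (file corrupted?)")
    return model


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Load a YAML (or JSON) run-configuration mapping."""
    import yaml

    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
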
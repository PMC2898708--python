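"""Text and image file plumbing.

Sinograms, angle assignments, and evaluation reports are stored as
delimited text with ``#`` comment headers carrying the provenance
(configuration hash, seed, shapes).  True view angles are written to a
separate truth file only, so the estimation stages can never read them
by accident.  Images round-trip through PNG/TIFF (grayscale, rescaled to
``[0, 1]``) or plain delimited text for lossless comparison.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .angles import AngleAssignment
from .metrics import EvalReport
from .phantoms import Sinogram

__all__ = [
    "write_sinogram", "read_sinogram",
    "write_truth_angles", "read_truth_angles",
    "write_assignment", "read_assignment",
    "write_image", "read_image",
    "write_report", "read_report",
]

_FMT = "%.12g"


def _header_lines(meta: dict) -> str:
    return "\n".join(f"# {k} = {v}" for k, v in meta.items())


def _parse_header(path: Path) -> dict:
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, value = line[1:].split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def write_sinogram(path: str | Path, sino: Sinogram,
                   meta: dict | None = None) -> None:
    """CSV sinogram, one projection per row.  Hidden angles are NOT
    written here — use :func:`write_truth_angles`."""
    path = Path(path)
    header = {"n_projections": sino.n_projections,
              "n_samples": sino.n_samples,
              "detector_spacing": f"{sino.detector_spacing:.12g}",
              "snr_db": sino.noise_snr_db}
    header.update(meta or {})
    with path.open("w") as fh:
        fh.write(_header_lines(header) + "\n")
        np.savetxt(fh, sino.rows, fmt=_FMT, delimiter=",")


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    meta = _parse_header(path)
    rows = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    snr = meta.get("snr_db")
    snr_db = None if snr in (None, "None") else float(snr)
    n = rows.shape[1]
    return Sinogram(rows=rows, detector_coords=np.linspace(-1.0, 1.0, n),
                    noise_snr_db=snr_db)


def write_truth_angles(path: str | Path, angles: np.ndarray,
                       meta: dict | None = None) -> None:
    """Evaluation-only file of true view angles (radians, one per line)."""
    path = Path(path)
    header = {"content": "true view angles (radians)",
              "n_projections": len(angles)}
    header.update(meta or {})
    with path.open("w") as fh:
        fh.write(_header_lines(header) + "\n")
        np.savetxt(fh, np.asarray(angles), fmt=_FMT)


def read_truth_angles(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), comments="#")


def write_assignment(path: str | Path, assignment: AngleAssignment,
                     meta: dict | None = None) -> None:
    """Columns: projection_index, raw_angle_rad, refined_angle_rad, rank."""
    path = Path(path)
    n = assignment.n
    rank = np.empty(n, dtype=int)
    rank[assignment.order] = np.arange(n)
    table = np.column_stack([np.arange(n), assignment.raw_angles,
                             assignment.refined_angles, rank])
    header = {"columns": "projection_index,raw_angle_rad,refined_angle_rad,rank",
              "period": f"{assignment.period:.12g}",
              "n_projections": n}
    header.update(meta or {})
    with path.open("w") as fh:
        fh.write(_header_lines(header) + "\n")
        np.savetxt(fh, table, fmt=["%d", _FMT, _FMT, "%d"], delimiter=",")


def read_assignment(path: str | Path) -> AngleAssignment:
    path = Path(path)
    meta = _parse_header(path)
    table = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    rank = table[:, 3].astype(int)
    order = np.empty(len(rank), dtype=int)
    order[rank] = np.arange(len(rank))
    return AngleAssignment(raw_angles=table[:, 1], order=order,
                           refined_angles=table[:, 2],
                           period=float(meta.get("period", 2 * np.pi)))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """PNG/TIFF (16-bit gray, [0,1] rescaled by clipping) or plain text."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if path.suffix.lower() in (".txt", ".csv", ".tsv"):
        delim = {"": ",", ".csv": ",", ".tsv": "\t", ".txt": " "}[path.suffix.lower()]
        np.savetxt(path, image, fmt=_FMT, delimiter=delim)
        return
    scaled = np.clip(image, 0.0, 1.0)
    iio.imwrite(path, (scaled * 65535).round().astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    """Load as float in [0, 1] (images) or raw floats (delimited text)."""
    path = Path(path)
    if path.suffix.lower() in (".txt", ".csv", ".tsv"):
        delim = {".csv": ",", ".tsv": "\t", ".txt": None}[path.suffix.lower()]
        return np.loadtxt(path, delimiter=delim, comments="#", ndmin=2)
    data = np.asarray(iio.imread(path), dtype=float)
    if data.ndim == 3:  # collapse accidental channels
        data = data.mean(axis=2)
    if data.max() > 1.0:
        data /= 65535.0 if data.max() > 255 else 255.0
    return data


def write_report(path: str | Path, report: EvalReport,
                 meta: dict | None = None) -> None:
    """Flat key=value text block plus a machine-readable .json twin."""
    path = Path(path)
    payload = dict(meta or {})
    payload.update(report.to_dict())
    lines = [f"{k} = {v}" for k, v in payload.items()]
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(payload, indent=2, default=str) + "\n")


def read_report(path: str | Path) -> dict:
    data = {}
    for line in Path(path).read_text().splitlines():
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        key, value = key.strip(), value.strip()
        try:
            data[key] = json.loads(value)
        except json.JSONDecodeError:
            data[key] = {"True": True, "False": False,
                         "None": None, "inf": np.inf}.get(value, value)
    return data
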
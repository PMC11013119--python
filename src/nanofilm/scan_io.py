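"""Scan-image container and file I/O.

A :class:`ScanImage` is a calibrated 2-D scalar field produced by a
scanning-probe instrument: a topography map in nanometres (AFM) or an
electrical surface-potential map in millivolts (KPFM).  Two on-disk
dialects are supported:

* ``ascii_matrix`` — whitespace-separated rows with an optional
  ``#``-prefixed header (``# key: value``), the shape of common SPM
  ASCII exports (e.g. Gwyddion).  Values are written with 9 significant
  digits, so round trips agree to ≤1e-8 relative.
* ``float_tiff`` — single-channel uncompressed 32-bit float TIFF;
  round trips are bit-exact for float32-representable data.

Coordinate convention, used everywhere in the package: row 0 is the top
scan line, the column index increases rightward (fast axis), and pixel
centres sit at ``(i + 0.5, j + 0.5) * pixel_size``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

__all__ = [
    "CHANNELS",
    "ScanImage",
    "Report",
    "ScanParseError",
    "read_scan",
    "write_scan",
    "write_report",
    "read_report",
    "config_hash",
]

CHANNELS = ("topography", "potential")

#: physical unit attached to each channel
CHANNEL_UNITS = {"topography": "nm", "potential": "mV"}


class ScanParseError(ValueError):
    """Raised when a scan file cannot be parsed under the named dialect."""


@dataclass
class ScanImage:
    """A calibrated 2-D scan: height (nm) or surface potential (mV).

    Parameters
    ----------
    values
        2-D array of finite reals; units are nm for ``channel="topography"``
        and mV for ``channel="potential"``.
    pixel_size
        Isotropic pixel size in nm; must be positive.
    channel
        Either ``"topography"`` or ``"potential"``.
    metadata
        Free-form string map (instrument, surface pressure, composition...).
    """

    values: np.ndarray
    pixel_size: float
    channel: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 2:
            raise ValueError(f"grid too small: {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scan contains non-finite values")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def units(self) -> str:
        return CHANNEL_UNITS[self.channel]

    def with_values(self, values: np.ndarray) -> "ScanImage":
        """Copy of this image with ``values`` replaced, metadata kept."""
        return ScanImage(values, self.pixel_size, self.channel, dict(self.metadata))

    def require_channel(self, channel: str) -> None:
        """Raise if this image is not of the requested channel."""
        if self.channel != channel:
            raise ValueError(
                f"operation requires a {channel} image, got {self.channel}"
            )


@dataclass
class Report:
    """Summary of one paired-image analysis.

    Coverages are percentages with 95% margins; ``delta_h`` (nm) and
    ``delta_v`` (mV) are domain contrasts with 95% margins.  Optional
    fields are ``None`` when the corresponding stage did not run.
    """

    coverage_histogram: Optional[tuple[float, float]] = None
    coverage_particle: Optional[tuple[float, float]] = None
    coverage_model_average: Optional[tuple[float, float]] = None
    delta_h: Optional[tuple[float, float]] = None
    delta_v: Optional[tuple[float, float]] = None
    n_profiles: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("coverage_histogram", "coverage_particle", "coverage_model_average"):
            pair = getattr(self, name)
            if pair is not None:
                value, margin = pair
                if not (0.0 <= value <= 100.0):
                    raise ValueError(f"{name} out of [0, 100]: {value}")
                if margin < 0:
                    raise ValueError(f"{name} margin < 0: {margin}")
        for name in ("delta_h", "delta_v"):
            pair = getattr(self, name)
            if pair is not None and pair[1] < 0:
                raise ValueError(f"{name} margin < 0: {pair[1]}")
        if (self.delta_h is not None or self.delta_v is not None) and self.n_profiles < 2:
            raise ValueError("n_profiles must be >= 2 when contrasts carry CIs")


_FIELD_UNITS = {
    "coverage_histogram": "%",
    "coverage_particle": "%",
    "coverage_model_average": "%",
    "delta_h": "nm",
    "delta_v": "mV",
}


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_scan(
    path,
    dialect: str = "ascii_matrix",
    pixel_size: float = 1.0,
    channel: str = "topography",
) -> ScanImage:
    """Read a scan image from ``path`` under the named dialect.

    Header keys in an ASCII file (``# pixel_size_nm: 10``, ``# channel:
    potential``) override the ``pixel_size`` / ``channel`` arguments.
    """
    path = Path(path)
    if dialect == "ascii_matrix":
        return _read_ascii(path, pixel_size, channel)
    if dialect == "float_tiff":
        values = tifffile.imread(path)
        if values.ndim != 2:
            raise ScanParseError(f"{path}: expected single-channel 2-D TIFF, got shape {values.shape}")
        img = ScanImage(np.asarray(values, dtype=float), pixel_size, channel)
        if not np.all(np.isfinite(img.values)):  # pragma: no cover - caught by ScanImage
            raise ScanParseError(f"{path}: non-finite entries")
        return img
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_ascii(path: Path, pixel_size: float, channel: str) -> ScanImage:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        data_row = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip()] = val.strip()
                continue
            data_row += 1
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise ScanParseError(f"{path}: row {data_row}: {exc}") from None
            if rows and len(row) != len(rows[0]):
                raise ScanParseError(
                    f"{path}: ragged matrix at row {data_row}: "
                    f"expected {len(rows[0])} columns, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise ScanParseError(f"{path}: no data rows")
    values = np.array(rows, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ScanParseError(f"{path}: non-finite entries")
    if "pixel_size_nm" in header:
        pixel_size = float(header["pixel_size_nm"])
    if "channel" in header:
        channel = header["channel"]
    meta = {k: v for k, v in header.items() if k not in ("pixel_size_nm", "channel", "units")}
    return ScanImage(values, pixel_size, channel, meta)


def write_scan(image: ScanImage, path, dialect: str = "ascii_matrix") -> None:
    """Write ``image`` to ``path``; readable back by :func:`read_scan`."""
    path = Path(path)
    if dialect == "ascii_matrix":
        with open(path, "w") as fh:
            fh.write(f"# pixel_size_nm: {image.pixel_size!r}\n")
            fh.write(f"# channel: {image.channel}\n")
            fh.write(f"# units: {image.units}\n")
            for key, val in sorted(image.metadata.items()):
                fh.write(f"# {key}: {val}\n")
            np.savetxt(fh, image.values, fmt="%.8e")
    elif dialect == "float_tiff":
        tifffile.imwrite(path, image.values.astype(np.float32), compression=None)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _pair_to_json(pair: Optional[tuple[float, float]]):
    if pair is None:
        return None
    return {"value": float(pair[0]), "margin": float(pair[1])}


def write_report(report: Report, path) -> None:
    """Serialize a report as JSON (``path``) and CSV (``path`` with .csv).

    Field order is deterministic; empty optional fields serialize as
    empty cells in the CSV and ``null`` in the JSON, never as zero.
    """
    path = Path(path)
    payload = {
        name: _pair_to_json(getattr(report, name)) for name in _FIELD_UNITS
    }
    payload["n_profiles"] = report.n_profiles
    payload["provenance"] = report.provenance
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
    with open(path.with_suffix(".csv"), "w") as fh:
        fh.write("quantity,value,margin,units\n")
        for name, units in _FIELD_UNITS.items():
            pair = getattr(report, name)
            if pair is None:
                fh.write(f"{name},,,{units}\n")
            else:
                fh.write(f"{name},{pair[0]!r},{pair[1]!r},{units}\n")
        fh.write(f"n_profiles,{report.n_profiles},,count\n")


def read_report(path) -> Report:
    """Re-load a JSON report written by :func:`write_report`."""
    with open(Path(path).with_suffix(".json")) as fh:
        payload = json.load(fh)
    kwargs = {}
    for name in _FIELD_UNITS:
        entry = payload.get(name)
        kwargs[name] = None if entry is None else (entry["value"], entry["margin"])
    return Report(
        n_profiles=payload.get("n_profiles", 0),
        provenance=payload.get("provenance", {}),
        **kwargs,
    )
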
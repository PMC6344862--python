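"""Readers and writers for the plain-text formats used across the package.

Traces and chromatograms travel as delimited text with a commented header
of ``# key: value`` lines followed by a ``# columns:`` declaration and
whitespace-separated data.  SAXS curves use the conventional 3-column
``q I sigma`` whitespace layout with ``#`` comments.  Images can be plain
text arrays, PNG, or single-image MRC (mode 2, float32); the MRC codec
implemented here covers exactly that minimal subset of the format.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .kinetics import KineticTrace
from .saxs import SaxsCurve
from .simulate.detectors import Chromatogram
from .symmetry import RingImage

__all__ = [
    "read_trace",
    "write_trace",
    "read_chromatogram",
    "write_chromatogram",
    "read_saxs",
    "write_saxs",
    "read_image",
    "write_image",
    "read_config",
]

PathLike = Union[str, Path]


def _parse_header(lines: list[str]) -> tuple[dict, list[str], int]:
    """Metadata dict, declared column names and index of first data line."""
    meta: dict = {}
    columns: list[str] = []
    i = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped.startswith("#"):
            break
        body = stripped.lstrip("#").strip()
        if body.lower().startswith("columns:"):
            columns = body.split(":", 1)[1].split()
        elif ":" in body:
            key, value = body.split(":", 1)
            meta[key.strip()] = yaml.safe_load(value.strip())
    else:
        i += 1
    return meta, columns, i


def _read_table(path: PathLike) -> tuple[dict, list[str], np.ndarray]:
    text = Path(path).read_text()
    lines = [ln for ln in text.replace("\r\n", "\n").split("\n") if ln.strip()]
    meta, columns, start = _parse_header(lines)
    data = np.array(
        [[float(v) for v in ln.split()] for ln in lines[start:]], dtype=float
    )
    return meta, columns, data


def _format_header(meta: dict, columns: list[str]) -> str:
    out = []
    for key, value in meta.items():
        out.append(f"# {key}: {value}")
    out.append(f"# columns: {' '.join(columns)}")
    return "\n".join(out)


def write_trace(path: PathLike, trace: KineticTrace) -> None:
    meta = dict(trace.metadata)
    meta.update(
        calibrated=bool(trace.calibrated),
        mcrB_conc_um=float(trace.mcrB_conc_um),
        mcrC_conc_um=float(trace.mcrC_conc_um),
        gtp_conc_mm=float(trace.gtp_conc_mm),
    )
    header = _format_header(meta, ["time_s", "signal"])
    body = "\n".join(
        f"{t:.10g} {s:.10g}" for t, s in zip(trace.time_s, trace.signal)
    )
    Path(path).write_text(header + "\n" + body + "\n")


def read_trace(path: PathLike) -> KineticTrace:
    meta, columns, data = _read_table(path)
    if columns and "time_s" not in columns:
        raise ValueError(f"{path}: missing required column 'time_s' (found {columns})")
    if columns:
        if "signal" not in columns:
            raise ValueError(f"{path}: missing required column 'signal'")
        t_idx, s_idx = columns.index("time_s"), columns.index("signal")
    else:
        t_idx, s_idx = 0, 1
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two data columns")

    def _num(key, default=float("nan")):
        v = meta.get(key, default)
        return float(v) if v is not None else default

    return KineticTrace(
        time_s=data[:, t_idx],
        signal=data[:, s_idx],
        calibrated=bool(meta.get("calibrated", False)),
        mcrB_conc_um=_num("mcrB_conc_um"),
        mcrC_conc_um=_num("mcrC_conc_um"),
        gtp_conc_mm=_num("gtp_conc_mm"),
        metadata={
            k: v
            for k, v in meta.items()
            if k not in {"calibrated", "mcrB_conc_um", "mcrC_conc_um", "gtp_conc_mm"}
        },
    )


def write_chromatogram(path: PathLike, chrom: Chromatogram) -> None:
    header = _format_header(dict(chrom.metadata), ["volume_ml", "signal"])
    body = "\n".join(
        f"{v:.10g} {s:.10g}" for v, s in zip(chrom.volume_ml, chrom.signal)
    )
    Path(path).write_text(header + "\n" + body + "\n")


def read_chromatogram(path: PathLike) -> Chromatogram:
    meta, columns, data = _read_table(path)
    if columns and "volume_ml" not in columns:
        raise ValueError(
            f"{path}: missing required column 'volume_ml' (found {columns})"
        )
    v_idx = columns.index("volume_ml") if columns else 0
    s_idx = columns.index("signal") if columns else 1
    return Chromatogram(
        volume_ml=data[:, v_idx], signal=data[:, s_idx], metadata=meta
    )


def write_saxs(path: PathLike, curve: SaxsCurve, meta: Optional[dict] = None) -> None:
    lines = [f"# {k}: {v}" for k, v in (meta or {}).items()]
    lines.append("# columns: q_invA I sigma" if curve.sigma is not None
                 else "# columns: q_invA I")
    for i in range(len(curve.q)):
        if curve.sigma is not None:
            lines.append(
                f"{curve.q[i]:.8g} {curve.intensity[i]:.8g} {curve.sigma[i]:.8g}"
            )
        else:
            lines.append(f"{curve.q[i]:.8g} {curve.intensity[i]:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_saxs(path: PathLike, units: str = "invA") -> SaxsCurve:
    """Read a 3-column (or 2-column) scattering profile.

    ``units`` is ``"invA"`` (default) or ``"invnm"``; reciprocal-nanometre
    q values are divided by 10 on read so the in-memory curve is always in
    1/A.  Non-monotone q is sorted with a warning.
    """
    if units not in {"invA", "invnm"}:
        raise ValueError("units must be 'invA' or 'invnm'")
    _, _, data = _read_table(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 or 3 numeric columns (q, I[, sigma])")
    q = data[:, 0]
    if units == "invnm":
        q = q / 10.0
    intensity = data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if np.any(np.diff(q) <= 0):
        warnings.warn(f"{path}: q not strictly increasing; sorting", stacklevel=2)
        order = np.argsort(q, kind="stable")
        q, intensity = q[order], intensity[order]
        if sigma is not None:
            sigma = sigma[order]
        keep = np.concatenate([[True], np.diff(q) > 0])
        q, intensity = q[keep], intensity[keep]
        if sigma is not None:
            sigma = sigma[keep]
    return SaxsCurve(q=q, intensity=intensity, sigma=sigma)


# ---------------------------------------------------------------------------
# images

_MRC_HEADER_BYTES = 1024


def _write_mrc(path: Path, data: np.ndarray, pixel_size_a: float) -> None:
    ny, nx = data.shape
    arr = np.ascontiguousarray(data, dtype="<f4")
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, 1)  # nx ny nz
    struct.pack_into("<i", header, 12, 2)  # mode 2 = float32
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx my mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size_a, ny * pixel_size_a, pixel_size_a
    )  # cell dimensions
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc mapr maps
    struct.pack_into(
        "<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean())
    )
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(arr.std()))
    path.write_bytes(bytes(header) + arr.tobytes())


def _read_mrc(path: Path) -> tuple[np.ndarray, float]:
    raw = path.read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode != 2:
        raise ValueError(f"{path}: only MRC mode 2 (float32) is supported, got {mode}")
    if nz != 1:
        raise ValueError(f"{path}: only single-image MRC supported, got nz={nz}")
    cell_x, _, _ = struct.unpack_from("<3f", raw, 40)
    (mx,) = struct.unpack_from("<i", raw, 28)
    pixel = cell_x / mx if mx > 0 and cell_x > 0 else 1.0
    n = nx * ny
    data = np.frombuffer(
        raw, dtype="<f4", count=n, offset=_MRC_HEADER_BYTES
    ).reshape(ny, nx)
    return data.astype(float), float(pixel)


def write_image(path: PathLike, image: RingImage) -> None:
    """Write an image as plain text (.txt/.dat), PNG (.png) or MRC (.mrc)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".txt", ".dat"}:
        header = f"# pixel_size_a: {image.pixel_size_a}\n"
        body = "\n".join(" ".join(f"{v:.8g}" for v in row) for row in image.data)
        path.write_text(header + body + "\n")
    elif suffix == ".png":
        import imageio.v3 as iio

        lo, hi = float(image.data.min()), float(image.data.max())
        scaled = (
            np.zeros_like(image.data)
            if hi == lo
            else (image.data - lo) / (hi - lo)
        )
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))
    elif suffix == ".mrc":
        _write_mrc(path, image.data, image.pixel_size_a)
    else:
        raise ValueError(f"unsupported image format: {suffix!r}")


def read_image(path: PathLike, pixel_size_a: Optional[float] = None) -> RingImage:
    """Read a plain-text, PNG or MRC (mode 2) image.

    ``pixel_size_a`` overrides any pixel size stored in the file; PNG
    carries none, so the override (or the 1.33 A default) applies.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".txt", ".dat"}:
        meta, _, data = _read_table(path)
        px = float(meta.get("pixel_size_a", 1.33))
    elif suffix == ".png":
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path), dtype=float)
        if data.ndim == 3:
            data = data.mean(axis=2)
        px = 1.33
    elif suffix == ".mrc":
        data, px = _read_mrc(path)
    else:
        raise ValueError(f"unsupported image format: {suffix!r}")
    if pixel_size_a is not None:
        px = pixel_size_a
    return RingImage(data=np.asarray(data, dtype=float), pixel_size_a=px)


def read_config(path: PathLike) -> dict:
    """Load a structured key/value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
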
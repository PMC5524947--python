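"""Readers/writers for the formats the tool touches: MRC volumes/stacks,
STAR particle tables, and CSV/JSON/STAR report outputs.

The MRC code implements the MRC2014 subset used by single-particle software
(modes 0/1/2/6, cubic or square-image stacks, voxel size from the cell
header).  The STAR code handles the ``data_``/``loop_`` dialect of deposited
particle tables, including both the legacy pixel-origin convention
(``rlnOriginX/Y``) and the Angstrom-origin convention
(``rlnOriginXAngst/YAngst``), auto-detected by column name.  Unknown columns
are carried through untouched.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Orientation
from .imageops import CTFParams, MapVolume, ParticleImage

logger = logging.getLogger("alignval")

__all__ = [
    "FormatError",
    "ParticleRecord",
    "read_map",
    "write_map",
    "read_stack",
    "write_stack",
    "parse_star",
    "write_star",
    "read_particles_star",
    "write_particles_star",
    "write_report",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# MRC

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def _read_mrc(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise FormatError(f"{path}: truncated MRC header ({len(raw)} bytes)")
    nx, ny, nz, mode = struct.unpack("<4i", raw[0:16])
    mx, my, mz = struct.unpack("<3i", raw[28:40])
    cella = struct.unpack("<3f", raw[40:52])
    nsymbt = struct.unpack("<i", raw[92:96])[0]
    if mode not in _MRC_MODES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")
    if min(nx, ny, nz) < 1 or max(nx, ny, nz) > 100000:
        raise FormatError(f"{path}: implausible dimensions nx={nx} ny={ny} nz={nz}")
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    start = 1024 + max(0, nsymbt)
    need = nx * ny * nz * dtype.itemsize
    if len(raw) < start + need:
        raise FormatError(
            f"{path}: truncated MRC data (need {need} bytes after header, have {len(raw) - start})"
        )
    data = np.frombuffer(raw[start : start + need], dtype=dtype).reshape(nz, ny, nx)
    voxel = cella[0] / mx if mx > 0 and cella[0] > 0 else 1.0
    return np.ascontiguousarray(data.astype(np.float64)), float(voxel)


def _write_mrc(data: np.ndarray, voxel_size: float, path) -> None:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    nz, ny, nx = data.shape
    h = bytearray(1024)
    struct.pack_into("<4i", h, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", h, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", h, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size)
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", h, 64, 1, 2, 3)  # axis order x, y, z
    struct.pack_into("<3f", h, 76, float(data.min()), float(data.max()), float(data.mean()))
    h[208:212] = b"MAP "
    h[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", h, 216, float(data.std()))
    Path(path).write_bytes(bytes(h) + data.astype("<f4").tobytes())


def read_map(path) -> MapVolume:
    """Read a cubic MRC volume; voxel size taken from the cell header."""
    data, voxel = _read_mrc(path)
    if len(set(data.shape)) != 1:
        raise FormatError(f"{path}: map is not cubic (shape {data.shape})")
    return MapVolume(data, voxel)


def write_map(vol: MapVolume, path) -> None:
    _write_mrc(vol.data, vol.voxel_size, path)


def read_stack(path) -> list[ParticleImage]:
    """Read an MRC/MRCS image stack as a list of square particle images."""
    data, pixel = _read_mrc(path)
    if data.shape[1] != data.shape[2]:
        raise FormatError(f"{path}: stack images are not square (shape {data.shape[1:]})")
    return [ParticleImage(img, pixel) for img in data]


def write_stack(images, path, pixel_size: float | None = None) -> None:
    if len(images) == 0:
        raise ValueError("empty stack")
    if isinstance(images, np.ndarray):
        if pixel_size is None:
            raise ValueError("pixel_size required for array input")
        _write_mrc(images, pixel_size, path)
        return
    arr = np.stack([im.data for im in images])
    _write_mrc(arr, images[0].pixel_size, path)


# ---------------------------------------------------------------------------
# STAR


def _star_cast(col: pd.Series) -> pd.Series:
    for caster in (pd.to_numeric,):
        try:
            return caster(col)
        except (ValueError, TypeError):
            pass
    return col


def parse_star(path) -> dict[str, pd.DataFrame]:
    """Parse a STAR file into ``{block_name: DataFrame}``.

    ``loop_`` blocks become multi-row frames; bare key-value blocks become a
    single-row frame.  Values are numeric where they parse as such.
    """
    path = Path(path)
    blocks: dict[str, pd.DataFrame] = {}
    name = None
    mode = "idle"  # idle | loop_header | loop_rows | pairs
    cols: list[str] = []
    rows: list[list[str]] = []
    pairs: dict[str, str] = {}

    def flush():
        nonlocal cols, rows, pairs
        if name is not None and (cols or pairs):
            if cols:
                df = pd.DataFrame(rows, columns=cols)
            else:
                df = pd.DataFrame([pairs])
            blocks[name] = df.apply(_star_cast)
        cols, rows, pairs = [], [], {}

    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            flush()
            name = line[5:] or "root"
            mode = "idle"
        elif line == "loop_":
            flush_needed = bool(cols or pairs)
            if flush_needed:
                flush()
            mode = "loop_header"
        elif line.startswith("_"):
            tag = line.split()[0].lstrip("_")
            if mode == "loop_header":
                cols.append(tag)
            else:
                parts = line.split(None, 1)
                pairs[tag] = parts[1] if len(parts) > 1 else ""
                mode = "pairs"
        else:
            if mode in ("loop_header", "loop_rows"):
                mode = "loop_rows"
                vals = line.split()
                if len(vals) != len(cols):
                    raise FormatError(
                        f"{path}: row has {len(vals)} values for {len(cols)} columns"
                    )
                rows.append(vals)
            else:
                raise FormatError(f"{path}: unexpected line {line!r}")
    flush()
    if not blocks:
        raise FormatError(f"{path}: no data blocks found")
    return blocks


def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, (float, np.floating)):
        return "." if np.isnan(v) else f"{v:.6f}"
    s = str(v)
    return s if s.strip() else "."  # STAR fields cannot be empty tokens


def write_star(blocks: dict[str, pd.DataFrame], path) -> None:
    lines: list[str] = []
    for name, df in blocks.items():
        lines += [f"data_{name}", "", "loop_"]
        lines += [f"_{c} #{i + 1}" for i, c in enumerate(df.columns)]
        for _, row in df.iterrows():
            lines.append(" ".join(_fmt(v) for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# particle records

_ANGLE_COLS = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")


@dataclass
class ParticleRecord:
    """One particle table row: image reference, alignment, CTF."""

    index: int
    image_name: str | None = None
    orientation: Orientation | None = None
    ctf: CTFParams | None = None
    pixel_size: float | None = None
    row: dict = field(default_factory=dict)  # original columns, preserved on write


def _particles_block(blocks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    if "particles" in blocks:
        return blocks["particles"]
    for df in blocks.values():
        if any(c in df.columns for c in _ANGLE_COLS) or "rlnImageName" in df.columns:
            return df
    return next(iter(blocks.values()))


def read_particles_star(
    path, pixel_size: float | None = None, require_orientations: bool = False
) -> list[ParticleRecord]:
    """Read a particle table into :class:`ParticleRecord` objects.

    Shifts in Angstrom (``rlnOrigin{X,Y}Angst``) are converted to pixels using
    the per-row pixel size, an optics-block pixel size, or the ``pixel_size``
    argument.  Missing CTF columns fall back to the identity CTF (logged).
    """
    blocks = parse_star(path)
    df = _particles_block(blocks)
    optics_px = None
    if "optics" in blocks and "rlnImagePixelSize" in blocks["optics"].columns:
        optics_px = float(blocks["optics"]["rlnImagePixelSize"].iloc[0])

    have_angles = all(c in df.columns for c in _ANGLE_COLS)
    if require_orientations and not have_angles:
        missing = [c for c in _ANGLE_COLS if c not in df.columns]
        raise FormatError(
            f"{path}: missing orientation columns {missing}; required for accuracy estimation"
        )
    have_ctf = "rlnDefocusU" in df.columns
    if not have_ctf:
        logger.warning("%s: no CTF columns (rlnDefocusU ...); assuming identity CTF", path)

    angst_shifts = "rlnOriginXAngst" in df.columns
    records: list[ParticleRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        px = row.get("rlnImagePixelSize", optics_px) or pixel_size
        orientation = None
        if have_angles:
            if angst_shifts:
                if not px:
                    raise FormatError(
                        f"{path}: Angstrom-unit origins need a pixel size "
                        "(rlnImagePixelSize column, optics block, or argument)"
                    )
                sx = float(row.get("rlnOriginXAngst", 0.0)) / px
                sy = float(row.get("rlnOriginYAngst", 0.0)) / px
            else:
                sx = float(row.get("rlnOriginX", 0.0))
                sy = float(row.get("rlnOriginY", 0.0))
            orientation = Orientation(
                rot=float(row["rlnAngleRot"]),
                tilt=float(row["rlnAngleTilt"]),
                psi=float(row["rlnAnglePsi"]),
                shift_x=sx,
                shift_y=sy,
            )
        ctf = None
        if have_ctf:
            ctf = CTFParams(
                defocus_u=float(row["rlnDefocusU"]),
                defocus_v=float(row.get("rlnDefocusV", row["rlnDefocusU"])),
                defocus_angle=float(row.get("rlnDefocusAngle", 0.0)),
                voltage=float(row.get("rlnVoltage", 300.0)),
                cs=float(row.get("rlnSphericalAberration", 2.7)),
                amplitude_contrast=float(row.get("rlnAmplitudeContrast", 0.1)),
                phase_shift=float(row.get("rlnPhaseShift", 0.0)),
            )
        records.append(
            ParticleRecord(
                index=i,
                image_name=row.get("rlnImageName"),
                orientation=orientation,
                ctf=ctf,
                pixel_size=float(px) if px else None,
                row=row,
            )
        )
    return records


def write_particles_star(records: list[ParticleRecord], path, block: str = "particles") -> None:
    """Write records back to a STAR table; original columns are preserved,
    alignment columns refreshed from the record's orientation."""
    rows = []
    for r in records:
        row = dict(r.row)
        if r.orientation is not None:
            o = r.orientation
            row["rlnAngleRot"], row["rlnAngleTilt"], row["rlnAnglePsi"] = o.rot, o.tilt, o.psi
            if "rlnOriginXAngst" in row and r.pixel_size:
                row["rlnOriginXAngst"] = o.shift_x * r.pixel_size
                row["rlnOriginYAngst"] = o.shift_y * r.pixel_size
            else:
                row["rlnOriginX"], row["rlnOriginY"] = o.shift_x, o.shift_y
        if r.ctf is not None and "rlnDefocusU" not in row:
            row["rlnDefocusU"] = r.ctf.defocus_u
            row["rlnDefocusV"] = r.ctf.defocus_v
            row["rlnDefocusAngle"] = r.ctf.defocus_angle
            row["rlnVoltage"] = r.ctf.voltage
            row["rlnSphericalAberration"] = r.ctf.cs
            row["rlnAmplitudeContrast"] = r.ctf.amplitude_contrast
            row["rlnPhaseShift"] = r.ctf.phase_shift
        if r.pixel_size is not None and "rlnImagePixelSize" not in row:
            row["rlnImagePixelSize"] = r.pixel_size
        if r.image_name is not None:
            row.setdefault("rlnImageName", r.image_name)
        rows.append(row)
    write_star({block: pd.DataFrame(rows)}, path)


# ---------------------------------------------------------------------------
# reports


def write_report(report, out_prefix, records: list[ParticleRecord] | None = None, prune_output: bool = False):
    """Serialize a validation report.

    Writes ``<prefix>_scores.csv`` and ``.star`` (per-particle alpha, chi,
    q_p, q_a, flags), ``<prefix>_summary.json`` (Q, percentages, parameters,
    seed), and — when ``records`` are given and pruning is requested —
    ``<prefix>_pruned.star`` with the passing subset.  Returns the list of
    paths written.
    """
    from .scoring import prune  # local import; scoring depends on imageops only

    out_prefix = str(out_prefix)
    df = report.to_dataframe()
    paths = []
    csv_path = out_prefix + "_scores.csv"
    df.to_csv(csv_path, index=False)
    paths.append(csv_path)
    star_path = out_prefix + "_scores.star"
    write_star({"particle_scores": df}, star_path)
    paths.append(star_path)

    p = report.params
    summary = {
        "Q": report.Q,
        "percent_precise": report.percent_precise,
        "percent_accurate": report.percent_accurate,
        "mean_q_p": report.mean_q_p,
        "mean_q_a": report.mean_q_a,
        "n_particles": report.n_particles,
        "grid_size": report.grid_size,
        "alpha_noise_hat": report.references.alpha_noise_hat,
        "chi_noise_hat": report.references.chi_noise_hat,
        "params": {
            "xi": p.xi,
            "delta": p.delta,
            "M": p.M,
            "tau": p.tau,
            "rot_step": p.rot_step,
            "max_shift": p.max_shift,
            "sym": p.sym,
            "seed": p.seed,
            "mode": p.mode,
        },
    }
    json_path = out_prefix + "_summary.json"
    Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths.append(json_path)

    if prune_output and records is not None:
        kept = prune(report)
        pruned_path = out_prefix + "_pruned.star"
        write_particles_star([records[i] for i in kept], pruned_path)
        paths.append(pruned_path)
    return paths
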
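"""File I/O, run configuration and manifests.

Image stacks travel as multi-page TIFF (one file per channel), boundaries
and profiles as tab-separated text with header rows (0-based A-scan and
row indices), configuration as YAML, and each run writes a JSON manifest
with the config hash and seed for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .phantom import MultiChannelStack, ScanPattern

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_boundary_table",
    "read_boundary_table",
    "write_profile_table",
    "write_metrics_table",
    "write_manifest",
]

log = logging.getLogger("mdoct")

DEFAULT_PITCH_UM = 3.5


@dataclass
class RunConfig:
    """Structured run configuration with strict keys and round-trip I/O."""

    seed: int = 0
    pattern_kind: str = "circumpapillary"
    ascans: int = 1024
    bscans: int = 10
    depth: int = 384
    noise_sigma: float = 30.0
    rnfl_modulation: float = 0.3
    pr_kappa: float = 1.5
    hfl_power: float = 2.0
    channel_depth_offsets: tuple[int, int, int] = (0, 0, 0)
    smoothing_method: str = "lowess"
    smoothing_span: float = 0.05
    n_eval_bscans: int = 10
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "channel_depth_offsets" in raw:
            raw["channel_depth_offsets"] = tuple(raw["channel_depth_offsets"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["channel_depth_offsets"] = list(d["channel_depth_offsets"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["channel_depth_offsets"] = list(d["channel_depth_offsets"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def write_stack(stack: MultiChannelStack, out_dir: str | Path, prefix: str = "channel") -> list[Path]:
    """Write one multi-page TIFF per channel plus a metadata JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(3):
        p = out_dir / f"{prefix}_{c + 1}.tif"
        tifffile.imwrite(p, stack.data[c].astype(np.float32))
        paths.append(p)
    meta = {
        "axial_pixel_pitch_um": stack.axial_pixel_pitch_um,
        "channel_azimuths_deg": list(stack.channel_azimuths_deg),
        "pattern_kind": stack.pattern.kind,
        "ascans_per_bscan": stack.pattern.ascans_per_bscan,
        "bscans": stack.pattern.bscans,
        "registered": stack.registered,
        "azimuth_convention": "0-based A-scan i at 360*i/N degrees, half-open [0, 360)",
    }
    meta_path = out_dir / f"{prefix}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths.append(meta_path)
    return paths


def read_stack(paths: list[str | Path], meta_path: str | Path | None = None) -> MultiChannelStack:
    """Read three per-channel multi-page TIFF stacks into a MultiChannelStack.

    Missing metadata falls back to defaults with a warning.
    """
    arrays = [np.asarray(tifffile.imread(p), dtype=float) for p in paths]
    arrays = [a[None] if a.ndim == 2 else a for a in arrays]
    shapes = {a.shape for a in arrays}
    if len(arrays) != 3 or len(shapes) != 1:
        raise ValueError(f"need 3 equally sized channel stacks, got shapes {shapes}")
    meta = {}
    if meta_path is not None and Path(meta_path).exists():
        meta = json.loads(Path(meta_path).read_text())
    else:
        warnings.warn("no stack metadata found; applying defaults", stacklevel=2)
    nb, depth, na = arrays[0].shape
    pattern = ScanPattern(
        kind=meta.get("pattern_kind", "circumpapillary"),
        ascans_per_bscan=meta.get("ascans_per_bscan", na),
        bscans=meta.get("bscans", nb),
    )
    return MultiChannelStack(
        data=np.stack(arrays),
        pattern=pattern,
        axial_pixel_pitch_um=meta.get("axial_pixel_pitch_um", DEFAULT_PITCH_UM),
        channel_azimuths_deg=tuple(meta.get("channel_azimuths_deg", (90.0, 210.0, 330.0))),
        registered=meta.get("registered", False),
    )


def write_boundary_table(
    path: str | Path,
    boundaries: dict[str, np.ndarray],
    flags: np.ndarray | None = None,
) -> Path:
    """Tab-separated boundary table: one row per A-scan, one column per boundary.

    Indices are 0-based (A-scan index and depth rows).
    """
    path = Path(path)
    names = list(boundaries)
    n = len(np.atleast_1d(boundaries[names[0]]))
    cols = [np.arange(n)] + [np.atleast_1d(np.asarray(boundaries[k], dtype=float)) for k in names]
    header = ["ascan_0based"] + [f"{k}_row_0based" for k in names]
    if flags is not None:
        cols.append(np.asarray(flags, dtype=int))
        header.append("vessel_flag")
    table = np.column_stack(cols)
    np.savetxt(path, table, delimiter="\t", header="\t".join(header), comments="", fmt="%.3f")
    return path


def read_boundary_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a boundary table back into {name: rows} (supports manual input)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    out = {}
    for i, name in enumerate(header):
        if name == "ascan_0based":
            continue
        key = name.replace("_row_0based", "")
        out[key] = data[:, i]
    return out


def write_profile_table(path: str | Path, profiles) -> Path:
    """Profile table: azimuth + raw/normalized/smoothed per channel (10 columns)."""
    path = Path(path)
    header = ["azimuth_deg"]
    cols = [profiles[0].azimuth_deg]
    for p in profiles:
        for kind in ("raw", "normalized", "smoothed"):
            header.append(f"ch{p.channel + 1}_{kind}")
            cols.append(getattr(p, kind))
    np.savetxt(
        path, np.column_stack(cols), delimiter="\t",
        header="\t".join(header), comments="", fmt="%.6g",
    )
    return path


def write_metrics_table(path: str | Path, rows: list[tuple[str, object]]) -> Path:
    """Metrics table mirroring the per-channel / mean / averaged-image layout."""
    path = Path(path)
    lines = ["image\tSNR_dB\tCNR\tENL"]
    for name, m in rows:
        lines.append(f"{name}\t{m.snr_db:.2f}\t{m.cnr:.3f}\t{m.enl:.1f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_manifest(out_dir: str | Path, config: RunConfig, files: list[Path]) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_sha256_16": config.digest(),
        "files": sorted(str(Path(f).name) for f in files),
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    return p
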
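"""Shared I/O: TIFF stacks with physical metadata, result tables, manifests.

Stacks are written as multi-page TIFF with axes ``Z,C,Y,X`` plus a JSON
sidecar (``<stem>.json``) recording pixel size and channel roles; the
sidecar is authoritative on read, with TIFF ImageJ metadata and an explicit
override as fallbacks.  Result writers emit UTF-8 CSV with a header row and
'.' decimals, a provenance JSON (inputs, parameters, seed, package version —
deliberately no timestamps, so reruns are byte-identical) and a manifest
with SHA-256 checksums of every artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .containers import ImageStack
from .errors import ConfigError

SIDECAR_SUFFIX = ".json"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + SIDECAR_SUFFIX)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as ZCYX TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.values.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "ZCYX"},
    )
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "channel_roles": list(stack.channel_roles),
        "axes": "ZCYX",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_stack(
    path: str | Path,
    role_map: dict | None = None,
    pixel_size_override: float | None = None,
) -> ImageStack:
    """Read a TIFF as a ZCYX stack.

    Singleton axes are inserted for 2-D (one channel, one slice) and 3-D
    (one slice) files.  Channel roles come from the sidecar or ``role_map``
    (role -> channel index); pixel size from the sidecar, then the override.
    A missing pixel size raises an error naming the ``--pixel-size`` flag.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such file: {path}")
    values = np.asarray(tifffile.imread(path), dtype=float)
    if values.ndim == 2:
        values = values[None, None]
    elif values.ndim == 3:
        # a 3-D TIFF is interpreted as (C, Y, X) with a single z-slice
        values = values[None]
    elif values.ndim != 4:
        raise ConfigError(f"cannot interpret TIFF with {values.ndim} axes as Z,C,Y,X")

    sidecar_file = _sidecar_path(path)
    meta = {}
    if sidecar_file.exists():
        meta = json.loads(sidecar_file.read_text())

    pixel_size = pixel_size_override or meta.get("pixel_size_um")
    if pixel_size is None:
        raise ConfigError(
            f"pixel size not recorded for {path.name}; pass --pixel-size "
            "(pixel_size_override) in μm per pixel"
        )

    n_channels = values.shape[1]
    if role_map:
        roles = [None] * n_channels
        for role, idx in role_map.items():
            if not 0 <= idx < n_channels:
                raise ConfigError(
                    f"role map points {role!r} at channel {idx}, "
                    f"but the stack has {n_channels} channels"
                )
            roles[idx] = role
        roles = [r if r is not None else f"channel{i}" for i, r in enumerate(roles)]
    elif "channel_roles" in meta:
        roles = list(meta["channel_roles"])
        if len(roles) != n_channels:
            raise ConfigError(
                f"sidecar lists {len(roles)} channel roles for {n_channels} channels"
            )
    else:
        roles = [f"channel{i}" for i in range(n_channels)]
    return ImageStack(values, tuple(roles), float(pixel_size))


def write_mask_tiff(mask, path: str | Path) -> Path:
    """Persist a binary mask as single-channel 8-bit TIFF (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (mask.values.astype(np.uint8) * 255))
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    provenance: dict | None = None,
) -> dict:
    """Write CSV tables + provenance JSON + checksum manifest; return manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
    prov = dict(provenance or {})
    prov["software_version"] = __version__
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=1, sort_keys=True, default=str))
    written.append(prov_path)
    manifest = {
        "artifacts": {p.name: sha256_file(p) for p in sorted(written)},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
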
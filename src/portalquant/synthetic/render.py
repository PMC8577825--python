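"""Rendering of analytic scenes to noisy multi-channel image stacks.

The imaging model is deliberately simple but physically ordered:

1. objects are painted as anti-aliased unit-coverage shapes (disks of their
   stated radius, thin polylines) on a per-channel float canvas;
2. the canvas is blurred with a Gaussian point-spread proxy
   (``nucleus_sigma_px``) and scaled to ``background + amplitude * paint``;
3. out-of-focus z-slices are blurred with a Gaussian whose σ grows linearly
   with slice distance from the focal plane (organoid stacks);
4. Poisson shot noise is applied to the noiseless signal, then additive
   Gaussian read noise.

All randomness flows from the single integer seed in :class:`RenderConfig`;
rendering the same (scene, config) pair twice is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..containers import ImageStack
from ..errors import ConfigError
from .scenes import Disk, OrganoidScene, TissueScene

TISSUE_ROLES = ("nuclei", "opn", "sca1", "pdgfra_gfp", "desmin")
ORGANOID_ROLES = ("brightfield", "gfp", "tomato")

_DEFAULT_TISSUE_AMPLITUDES = {
    "nuclei": 120.0, "opn": 100.0, "sca1": 90.0, "pdgfra_gfp": 110.0, "desmin": 80.0,
}
_DEFAULT_ORGANOID_AMPLITUDES = {"brightfield": 100.0, "gfp": 120.0, "tomato": 110.0}


@dataclass
class RenderConfig:
    """Acquisition model for rendering a scene to an image stack."""

    shape: tuple[int, int, int, int]          # (n_z, n_channels, H, W)
    pixel_size_um: float
    channel_order: tuple[str, ...]
    amplitudes: dict = field(default_factory=dict)      # role -> signal level
    background: dict = field(default_factory=dict)      # role -> offset
    nucleus_sigma_px: float = 1.0                       # PSF proxy
    shot_noise: bool = True
    read_noise_sd: float = 3.0
    defocus_sigma_per_slice_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_order = tuple(self.channel_order)
        if len(self.shape) != 4:
            raise ConfigError("shape must be (n_z, n_channels, H, W)")
        if self.shape[1] != len(self.channel_order):
            raise ConfigError("channel_order length must match shape[1]")
        if self.nucleus_sigma_px <= 0 or self.defocus_sigma_per_slice_um < 0:
            raise ConfigError("sigmas must be positive")
        if self.read_noise_sd < 0:
            raise ConfigError("read_noise_sd must be non-negative")
        for role in self.channel_order:
            amp = self.amplitudes.get(role, 0.0)
            bg = self.background.get(role, 0.0)
            if bg < 0 or (amp <= bg and amp != 0.0):
                raise ConfigError(
                    f"channel {role!r}: require amplitude > background >= 0"
                )

    @classmethod
    def for_tissue(
        cls, scene: TissueScene, n_z: int = 1, seed: int = 0, **overrides
    ) -> "RenderConfig":
        H, W = scene.field_shape_px
        kw = dict(
            shape=(n_z, len(TISSUE_ROLES), H, W),
            pixel_size_um=scene.pixel_size_um,
            channel_order=TISSUE_ROLES,
            amplitudes=dict(_DEFAULT_TISSUE_AMPLITUDES),
            background={r: 10.0 for r in TISSUE_ROLES},
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def for_organoid(cls, scene: OrganoidScene, seed: int = 0, **overrides) -> "RenderConfig":
        H, W = scene.field_shape_px
        kw = dict(
            shape=(scene.n_z, len(ORGANOID_ROLES), H, W),
            pixel_size_um=scene.pixel_size_um,
            channel_order=ORGANOID_ROLES,
            amplitudes=dict(_DEFAULT_ORGANOID_AMPLITUDES),
            background={r: 10.0 for r in ORGANOID_ROLES},
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# painting primitives

def _paint_disk(canvas: np.ndarray, disk: Disk) -> None:
    """Anti-aliased unit-coverage disk (coverage ramps over one pixel)."""
    r = disk.radius_px
    x0 = max(int(math.floor(disk.cx - r - 2)), 0)
    x1 = min(int(math.ceil(disk.cx + r + 2)) + 1, canvas.shape[1])
    y0 = max(int(math.floor(disk.cy - r - 2)), 0)
    y1 = min(int(math.ceil(disk.cy + r + 2)) + 1, canvas.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - disk.cx, yy - disk.cy)
    cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
    np.maximum(canvas[y0:y1, x0:x1], cov, out=canvas[y0:y1, x0:x1])


def _paint_polyline(canvas: np.ndarray, line, half_width_px: float = 0.75) -> None:
    """Thin anti-aliased polyline (total width <= 2 px at unit coverage)."""
    pts = np.asarray(line, dtype=float)
    if len(pts) < 2:
        return
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        seg = math.hypot(x1 - x0, y1 - y0)
        n = max(2, int(math.ceil(seg / 0.3)) + 1)
        for s in np.linspace(0.0, 1.0, n):
            _paint_disk(canvas, Disk(x0 + s * (x1 - x0), y0 + s * (y1 - y0), half_width_px))


def _finish_channel(paint: np.ndarray, role: str, cfg: RenderConfig) -> np.ndarray:
    amp = cfg.amplitudes.get(role, 0.0)
    bg = cfg.background.get(role, 0.0)
    blurred = ndimage.gaussian_filter(paint, sigma=cfg.nucleus_sigma_px, mode="reflect")
    return bg + amp * blurred


def _apply_noise(stack: np.ndarray, cfg: RenderConfig, rng: np.random.Generator) -> np.ndarray:
    out = stack
    if cfg.shot_noise:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
    if cfg.read_noise_sd > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# tissue

def render_tissue(scene: TissueScene, cfg: RenderConfig) -> ImageStack:
    """Render a portal-tract scene to a (z, c, y, x) stack.

    Channel contents: ``nuclei`` all nuclei and debris; ``opn`` duct nuclei
    and debris; ``sca1`` somata of SCA1+ mesenchymal cells plus protrusions;
    ``pdgfra_gfp`` all mesenchymal nuclei; ``desmin`` protrusions only.
    """
    _check_roles(cfg, TISSUE_ROLES)
    _check_field(cfg, scene)
    H, W = scene.field_shape_px
    paint = {role: np.zeros((H, W)) for role in TISSUE_ROLES}

    for d in scene.duct_nuclei:
        _paint_disk(paint["nuclei"], d)
        _paint_disk(paint["opn"], d)
    for d in scene.debris:
        _paint_disk(paint["nuclei"], d)
        _paint_disk(paint["opn"], d)
    soma_extra_px = 1.0 / scene.pixel_size_um
    for m in scene.msc_nuclei:
        _paint_disk(paint["nuclei"], m)
        _paint_disk(paint["pdgfra_gfp"], m)
        if m.sca1_positive:
            _paint_disk(paint["sca1"], Disk(m.cx, m.cy, m.radius_px + soma_extra_px))
    for line in scene.protrusions:
        _paint_polyline(paint["desmin"], line)
        _paint_polyline(paint["sca1"], line)

    planes = {role: _finish_channel(paint[role], role, cfg) for role in cfg.channel_order}
    n_z = cfg.shape[0]
    noiseless = np.stack(
        [np.stack([planes[role] for role in cfg.channel_order]) for _ in range(n_z)]
    )
    rng = np.random.default_rng(cfg.seed)
    values = _apply_noise(noiseless, cfg, rng)
    return ImageStack(values, cfg.channel_order, cfg.pixel_size_um)


# ---------------------------------------------------------------------------
# organoid

def render_organoid(scene: OrganoidScene, cfg: RenderConfig) -> ImageStack:
    """Render a chimeric-organoid scene to a defocus-graded z-stack.

    The brightfield channel is textured (high local variance) inside the
    organoid and flat outside; GFP and tomato channels render their regions;
    every slice other than ``focus_z`` is blurred with
    ``defocus_sigma_per_slice_um * |z - focus_z|``.
    """
    _check_roles(cfg, ORGANOID_ROLES)
    _check_field(cfg, scene)
    if cfg.shape[0] != scene.n_z:
        raise ConfigError(f"config has {cfg.shape[0]} z-slices, scene has {scene.n_z}")
    H, W = scene.field_shape_px
    ps = scene.pixel_size_um
    rng = np.random.default_rng(cfg.seed)

    yy, xx = np.mgrid[0:H, 0:W]
    inside = (scene.organoid.quad(xx.astype(float), yy.astype(float)) <= 1.0).astype(float)

    # texture: smoothed white noise, normalized to [0, 1], masked to organoid;
    # drawn once so every slice shows the same structure at different blur
    tex = rng.normal(size=(H, W))
    tex = ndimage.gaussian_filter(tex, sigma=1.0, mode="reflect")
    span = float(np.ptp(tex))
    if span > 0:
        tex = (tex - tex.min()) / span
    bf_paint = inside * (0.4 + 0.6 * tex)

    gfp_paint = np.zeros((H, W))
    if scene.gfp_region is not None:
        gfp_paint = (scene.gfp_region.quad(xx.astype(float), yy.astype(float)) <= 1.0).astype(float)
    tom_paint = np.zeros((H, W))
    for c in scene.tomato_clusters:
        _paint_disk(tom_paint, c)

    focal = {
        "brightfield": _finish_channel(bf_paint, "brightfield", cfg),
        "gfp": _finish_channel(gfp_paint, "gfp", cfg),
        "tomato": _finish_channel(tom_paint, "tomato", cfg),
    }
    slices = []
    for z in range(scene.n_z):
        sigma_px = cfg.defocus_sigma_per_slice_um * abs(z - scene.focus_z) / ps
        chans = []
        for role in cfg.channel_order:
            plane = focal[role]
            if sigma_px > 0:
                plane = ndimage.gaussian_filter(plane, sigma=sigma_px, mode="reflect")
            chans.append(plane)
        slices.append(np.stack(chans))
    values = _apply_noise(np.stack(slices), cfg, rng)
    return ImageStack(values, cfg.channel_order, cfg.pixel_size_um)


def _check_roles(cfg: RenderConfig, required) -> None:
    missing = set(required) - set(cfg.channel_order)
    if missing:
        raise ConfigError(f"channel_order missing required roles: {sorted(missing)}")


def _check_field(cfg: RenderConfig, scene) -> None:
    if cfg.shape[2:] != tuple(scene.field_shape_px):
        raise ConfigError(
            f"config field {cfg.shape[2:]} does not match scene {scene.field_shape_px}"
        )
    if not math.isclose(cfg.pixel_size_um, scene.pixel_size_um):
        raise ConfigError("config pixel size does not match scene")
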
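"""Ground-truth scene generation for portal-tract tissue and chimeric organoids.

A *scene* is a fully analytic description of a field of view: object
positions, sizes, classes, planted distances, protrusion routes and contact
flags.  Scenes are rendered to noisy image stacks by
:mod:`portalquant.synthetic.render`, and every downstream pipeline is
validated by comparing its measurements against the scene it was rendered
from.

Geometry conventions follow :mod:`portalquant.containers`: positions are in
pixels, ``(x, y)`` with origin at the top-left pixel centre; radii in pixels;
planted distances in μm.

The tissue generator emulates a portal tract: osteopontin-positive ductal
nuclei arranged on a ring around the portal-vein centre, peri-ductal
mesenchymal nuclei placed at log-normally distributed distances from the
duct surface (the homeostatic median in vivo is about 8 μm), thin desmin
protrusions routed from a mesenchymal cell to a controlled fraction of duct
nuclei, and optional sub-threshold debris specks.  ``planted_distance_um``
for each mesenchymal nucleus is the exact distance from its centre to the
nearest duct-nucleus boundary — the quantity the signed-EDT pipeline
measures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ConfigError, CrowdedFieldError

_MAX_PLACEMENT_ATTEMPTS = 400


@dataclass
class Disk:
    """Circle in pixel coordinates."""

    cx: float
    cy: float
    radius_px: float

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "radius_px": self.radius_px}

    @classmethod
    def from_dict(cls, d: dict) -> "Disk":
        return cls(d["cx"], d["cy"], d["radius_px"])


@dataclass
class MscNucleus(Disk):
    sca1_positive: bool = True

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["sca1_positive"] = bool(self.sca1_positive)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MscNucleus":
        return cls(d["cx"], d["cy"], d["radius_px"], d["sca1_positive"])


# ---------------------------------------------------------------------------
# tissue


@dataclass
class TissueParams:
    """Generator knobs for a portal-tract scene.

    Defaults emulate the homeostatic portal tract: a ring of ductal nuclei,
    mesenchymal nuclei at a log-normal surface distance with median 8 μm,
    93% of duct nuclei contacted by a desmin protrusion, and a 0.3
    mesenchyme-to-duct census ratio when all mesenchymal cells are SCA1+.
    """

    n_dc: int = 30
    n_msc: int = 9
    sca1_fraction: float = 1.0
    distance_median_um: float = 8.0
    distance_sigma_log: float = 0.4
    contact_fraction: float = 0.93
    field_um: float = 300.0
    pixel_size_um: float = 0.5
    duct_radius_um: float = 2.5
    msc_radius_um: float = 1.5
    ring_radius_um: float | None = None   # None -> sized from n_dc
    ring_gap_um: float = 4.0              # edge-to-edge gap between duct nuclei
    n_debris: int = 0
    debris_radius_um: float = 0.7

    def validate(self) -> None:
        if self.n_dc < 3:
            raise ConfigError("n_dc must be >= 3")
        if not 0 <= self.contact_fraction <= 1:
            raise ConfigError("contact_fraction must be in [0, 1]")
        if not 0 <= self.sca1_fraction <= 1:
            raise ConfigError("sca1_fraction must be in [0, 1]")
        if self.n_msc < 0 or self.n_debris < 0:
            raise ConfigError("object counts must be non-negative")
        if self.contact_fraction > 0 and self.n_msc == 0:
            raise ConfigError("contact_fraction > 0 requires at least one msc")
        if min(self.distance_median_um, self.pixel_size_um, self.field_um) <= 0:
            raise ConfigError("distances, pixel size and field must be positive")


@dataclass
class TissueScene:
    """Analytic ground truth for one portal-tract field of view."""

    pv_center: tuple[float, float]            # (x, y) px
    duct_nuclei: list[Disk]
    msc_nuclei: list[MscNucleus]
    planted_distance_um: list[float]          # per msc: centre -> duct surface
    radial_um: list[float]                    # per msc: centre -> pv_center
    protrusions: list[list[tuple[float, float]]]
    contacted_duct_indices: set[int]
    debris: list[Disk]
    pixel_size_um: float
    field_shape_px: tuple[int, int]           # (H, W)
    params: dict = field(default_factory=dict)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "tissue",
            "pv_center": list(self.pv_center),
            "duct_nuclei": [d.to_dict() for d in self.duct_nuclei],
            "msc_nuclei": [m.to_dict() for m in self.msc_nuclei],
            "planted_distance_um": list(self.planted_distance_um),
            "radial_um": list(self.radial_um),
            "protrusions": [[list(p) for p in line] for line in self.protrusions],
            "contacted_duct_indices": sorted(self.contacted_duct_indices),
            "debris": [d.to_dict() for d in self.debris],
            "pixel_size_um": self.pixel_size_um,
            "field_shape_px": list(self.field_shape_px),
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueScene":
        return cls(
            pv_center=tuple(d["pv_center"]),
            duct_nuclei=[Disk.from_dict(x) for x in d["duct_nuclei"]],
            msc_nuclei=[MscNucleus.from_dict(x) for x in d["msc_nuclei"]],
            planted_distance_um=list(d["planted_distance_um"]),
            radial_um=list(d["radial_um"]),
            protrusions=[[tuple(p) for p in line] for line in d["protrusions"]],
            contacted_duct_indices=set(d["contacted_duct_indices"]),
            debris=[Disk.from_dict(x) for x in d["debris"]],
            pixel_size_um=d["pixel_size_um"],
            field_shape_px=tuple(d["field_shape_px"]),
            params=d.get("params", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TissueScene":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # -- derived ------------------------------------------------------------
    def objects_table(self) -> pd.DataFrame:
        """Per-object ground-truth table (id, class, position, area, flags)."""
        ps = self.pixel_size_um
        rows = []
        for i, d in enumerate(self.duct_nuclei):
            rows.append(
                dict(
                    id=f"dc{i}", obj_class="dc", x_um=d.cx * ps, y_um=d.cy * ps,
                    area_um2=math.pi * (d.radius_px * ps) ** 2, sca1=0,
                    contacted=int(i in self.contacted_duct_indices),
                    planted_distance_um=np.nan,
                )
            )
        for i, m in enumerate(self.msc_nuclei):
            rows.append(
                dict(
                    id=f"msc{i}", obj_class="msc", x_um=m.cx * ps, y_um=m.cy * ps,
                    area_um2=math.pi * (m.radius_px * ps) ** 2,
                    sca1=int(m.sca1_positive), contacted=0,
                    planted_distance_um=self.planted_distance_um[i],
                )
            )
        for i, d in enumerate(self.debris):
            rows.append(
                dict(
                    id=f"debris{i}", obj_class="debris", x_um=d.cx * ps, y_um=d.cy * ps,
                    area_um2=math.pi * (d.radius_px * ps) ** 2, sca1=0, contacted=0,
                    planted_distance_um=np.nan,
                )
            )
        return pd.DataFrame(rows)


def _ring_radius_um(p: TissueParams) -> float:
    auto = p.n_dc * (2 * p.duct_radius_um + p.ring_gap_um) / (2 * math.pi)
    base = max(auto, 3 * p.duct_radius_um)
    if p.ring_radius_um is not None:
        if p.ring_radius_um < auto:
            raise ConfigError(
                f"ring_radius_um={p.ring_radius_um} too small for {p.n_dc} duct "
                f"nuclei (need >= {auto:.1f} μm)"
            )
        return p.ring_radius_um
    return base


def _no_overlap(cx, cy, r, others) -> bool:
    for o in others:
        if (cx - o.cx) ** 2 + (cy - o.cy) ** 2 <= (r + o.radius_px) ** 2:
            return False
    return True


def generate_tissue_scene(params: TissueParams, seed: int) -> TissueScene:
    """Generate a seeded portal-tract scene with planted ground truth.

    Raises :class:`CrowdedFieldError` when bounded rejection sampling cannot
    place every object without overlap inside the field.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    ps = params.pixel_size_um
    side_px = int(round(params.field_um / ps))
    shape = (side_px, side_px)
    cx0 = cy0 = (side_px - 1) / 2.0
    ring_um = _ring_radius_um(params)
    ring_px = ring_um / ps
    r_dc = params.duct_radius_um / ps
    r_msc = params.msc_radius_um / ps
    margin = r_dc + 3

    if ring_px + r_dc + margin > side_px / 2:
        raise CrowdedFieldError(
            f"field too crowded: duct ring radius {ring_um:.1f} μm does not fit "
            f"in a {params.field_um:.0f} μm field"
        )

    # duct ring: even angular spacing with small jitter, non-overlap enforced
    spacing = 2 * math.pi / params.n_dc
    duct_angles = None
    for _ in range(50):
        jitter = rng.uniform(-0.1, 0.1, size=params.n_dc) * spacing
        ang = np.arange(params.n_dc) * spacing + jitter
        pos = np.stack([cx0 + ring_px * np.cos(ang), cy0 + ring_px * np.sin(ang)], axis=1)
        diffs = pos - np.roll(pos, 1, axis=0)
        if np.all(np.hypot(diffs[:, 0], diffs[:, 1]) > 2 * r_dc):
            duct_angles = ang
            break
    if duct_angles is None:
        raise CrowdedFieldError("field too crowded: cannot jitter duct ring without overlap")
    duct = [
        Disk(cx0 + ring_px * math.cos(a), cy0 + ring_px * math.sin(a), r_dc)
        for a in duct_angles
    ]
    duct_xy = np.array([[d.cx, d.cy] for d in duct])

    # mesenchymal nuclei: log-normal surface distance, placed outward of the
    # ring in the angular sector of a randomly chosen duct nucleus, accepted
    # only if that nucleus is indeed the nearest (so the plant is exact)
    mu = math.log(params.distance_median_um)
    # feasible distance window: below the msc radius the nucleus would
    # overlap its generator duct nucleus; above t_max it cannot fit in the
    # field.  Draws outside the window are redrawn (truncated log-normal);
    # only the extreme tails are affected.
    t_min = params.msc_radius_um * 1.05
    t_max = (side_px / 2.0 - margin) * ps - ring_um - params.duct_radius_um - 1.0
    if t_max <= t_min or t_max <= params.distance_median_um * 0.5:
        raise CrowdedFieldError(
            f"field too crowded: feasible distance window ({t_min:.1f}, {t_max:.1f}) μm "
            f"cannot hold the requested median {params.distance_median_um} μm"
        )
    msc: list[MscNucleus] = []
    planted: list[float] = []
    radial: list[float] = []
    placed_all: list[Disk] = list(duct)
    for _ in range(params.n_msc):
        # draw the planted distance once and retry only the angular
        # placement, so rejection sampling does not bias the planted
        # distribution
        t = float(rng.lognormal(mu, params.distance_sigma_log))
        redraws = 0
        while not t_min < t <= t_max:
            t = float(rng.lognormal(mu, params.distance_sigma_log))
            redraws += 1
            if redraws > 1000:
                raise CrowdedFieldError("field too crowded: distance window unreachable")
        ok = False
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            j = int(rng.integers(params.n_dc))
            # place anywhere around the chosen duct nucleus (mesenchyme
            # wraps the duct); the nearest-nucleus check below rejects any
            # position whose true surface distance is not the plant
            direction = rng.uniform(0.0, 2.0 * math.pi)
            off = (t + params.duct_radius_um) / ps
            mx = duct[j].cx + off * math.cos(direction)
            my = duct[j].cy + off * math.sin(direction)
            if not (margin <= mx <= side_px - 1 - margin and margin <= my <= side_px - 1 - margin):
                continue
            dists = np.hypot(duct_xy[:, 0] - mx, duct_xy[:, 1] - my) * ps - params.duct_radius_um
            if dists.min() < t - 1e-6:
                continue  # another duct nucleus would be nearer than the plant
            if not _no_overlap(mx, my, r_msc, placed_all):
                continue
            nucleus = MscNucleus(mx, my, r_msc, True)
            msc.append(nucleus)
            placed_all.append(nucleus)
            planted.append(t)
            radial.append(math.hypot(mx - cx0, my - cy0) * ps)
            ok = True
            break
        if not ok:
            raise CrowdedFieldError(
                "field too crowded: could not place all mesenchymal nuclei"
            )

    # SCA1 flags: exact count, random assignment
    n_pos = int(round(params.sca1_fraction * params.n_msc))
    flags = np.zeros(params.n_msc, dtype=bool)
    if params.n_msc:
        flags[rng.permutation(params.n_msc)[:n_pos]] = True
    for m, f in zip(msc, flags):
        m.sca1_positive = bool(f)

    # debris specks: uniform placement with clearance from every object
    debris: list[Disk] = []
    r_deb = params.debris_radius_um / ps
    clearance = 3.0 / ps
    for _ in range(params.n_debris):
        ok = False
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            dx = rng.uniform(margin, side_px - 1 - margin)
            dy = rng.uniform(margin, side_px - 1 - margin)
            if _no_overlap(dx, dy, r_deb + clearance, placed_all):
                speck = Disk(dx, dy, r_deb)
                debris.append(speck)
                placed_all.append(speck)
                ok = True
                break
        if not ok:
            raise CrowdedFieldError("field too crowded: could not place debris")

    # contacts: exactly round(contact_fraction * n_dc) duct nuclei receive a
    # desmin protrusion, routed from the nearest safe mesenchymal cell along
    # an arc held clear of all other duct nuclei
    n_contact = int(round(params.contact_fraction * params.n_dc))
    contacted = set(int(i) for i in rng.choice(params.n_dc, size=n_contact, replace=False))
    protrusions = _route_protrusions(
        params, duct, duct_angles, msc, contacted, (cx0, cy0), ring_px, ps
    )

    return TissueScene(
        pv_center=(cx0, cy0),
        duct_nuclei=duct,
        msc_nuclei=msc,
        planted_distance_um=planted,
        radial_um=radial,
        protrusions=protrusions,
        contacted_duct_indices=contacted,
        debris=debris,
        pixel_size_um=ps,
        field_shape_px=shape,
        params={"seed": int(seed), **{k: getattr(params, k) for k in vars(params)}},
    )


def _route_protrusions(params, duct, duct_angles, msc, contacted, center, ring_px, ps):
    """Route one polyline per contacted duct nucleus.

    The route runs from the mesenchymal cell body to a clearance arc 4 μm
    off the duct surface *on the cell's own side of the ring*, along the arc
    to the target's angular position, then radially to the target,
    terminating 0.25 μm inside its boundary.  Keeping every polyline >= 4 μm
    clear of non-target duct nuclei (and starting only from cells >= 3.5 μm
    clear of non-contacted nuclei) keeps planted contact flags unambiguous.
    """
    if not contacted:
        return []
    cx0, cy0 = center
    r_dc_px = params.duct_radius_um / ps
    clear_px = 4.0 / ps
    msc_xy = np.array([[m.cx, m.cy] for m in msc])
    non_contacted = [i for i in range(len(duct)) if i not in contacted]
    protrusions = []
    for j in sorted(contacted):
        order = np.argsort(np.hypot(msc_xy[:, 0] - duct[j].cx, msc_xy[:, 1] - duct[j].cy))
        pick = None
        for i in order:
            safe = all(
                math.hypot(msc[i].cx - duct[k].cx, msc[i].cy - duct[k].cy) * ps
                - params.duct_radius_um
                >= 3.5
                for k in non_contacted
            )
            if safe:
                pick = int(i)
                break
        if pick is None:
            pick = int(order[0])
        m = msc[pick]
        theta_m = math.atan2(m.cy - cy0, m.cx - cx0)
        theta_j = duct_angles[j]
        outside = math.hypot(m.cx - cx0, m.cy - cy0) >= ring_px
        route_px = ring_px + (r_dc_px + clear_px) * (1 if outside else -1)
        delta = (theta_j - theta_m + math.pi) % (2 * math.pi) - math.pi
        step = math.radians(6.0)
        n_steps = max(1, int(math.ceil(abs(delta) / step)))
        line = [(m.cx, m.cy)]
        for s in range(n_steps + 1):
            a = theta_m + delta * s / n_steps
            line.append((cx0 + route_px * math.cos(a), cy0 + route_px * math.sin(a)))
        # final approach from the routed side, ending just inside the target
        end_r = r_dc_px - 0.25 / ps
        approach = theta_j if outside else theta_j + math.pi
        line.append(
            (duct[j].cx + end_r * math.cos(approach), duct[j].cy + end_r * math.sin(approach))
        )
        protrusions.append(line)
    return protrusions


# ---------------------------------------------------------------------------
# organoid


@dataclass
class OrganoidParams:
    """Generator knobs for a chimeric-organoid scene.

    Defaults emulate a single mid-sized organoid imaged as a short z-stack
    with one in-focus plane, a Notch-reporter (Hes1-GFP) region covering a
    quarter of the organoid and a few discrete tdTomato-positive mesenchymal
    cell clusters attached to it.
    """

    organoid_axes_um: tuple[float, float] = (55.0, 40.0)   # semi-axes
    gfp_area_fraction: float = 0.25
    n_tomato_clusters: int = 3
    n_z: int = 5
    pixel_size_um: float = 1.0
    field_um: float = 200.0
    cluster_radius_um: float = 4.0
    min_cluster_gap_um: float = 8.0

    def validate(self) -> None:
        if not 0 <= self.gfp_area_fraction <= 1:
            raise ConfigError("gfp_area_fraction must be in [0, 1]")
        if self.n_z < 1:
            raise ConfigError("n_z must be >= 1")
        if self.n_tomato_clusters < 0:
            raise ConfigError("n_tomato_clusters must be non-negative")
        if min(self.organoid_axes_um) <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("axes and pixel size must be positive")


@dataclass
class Ellipse:
    cx: float
    cy: float
    a_px: float     # semi-axis along the rotated x'
    b_px: float
    angle_rad: float

    def area_px2(self) -> float:
        return math.pi * self.a_px * self.b_px

    def quad(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Implicit quadratic form: <=1 inside the ellipse."""
        ct, st = math.cos(self.angle_rad), math.sin(self.angle_rad)
        xr = (x - self.cx) * ct + (y - self.cy) * st
        yr = -(x - self.cx) * st + (y - self.cy) * ct
        return (xr / self.a_px) ** 2 + (yr / self.b_px) ** 2

    def to_dict(self) -> dict:
        return {
            "cx": self.cx, "cy": self.cy, "a_px": self.a_px, "b_px": self.b_px,
            "angle_rad": self.angle_rad,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipse":
        return cls(d["cx"], d["cy"], d["a_px"], d["b_px"], d["angle_rad"])


@dataclass
class OrganoidScene:
    """Analytic ground truth for one chimeric-organoid z-stack."""

    organoid: Ellipse
    gfp_region: Ellipse | None
    tomato_clusters: list[Disk]
    focus_z: int
    n_z: int
    pixel_size_um: float
    field_shape_px: tuple[int, int]
    params: dict = field(default_factory=dict)

    def organoid_area_um2(self) -> float:
        return self.organoid.area_px2() * self.pixel_size_um**2

    def gfp_area_um2(self) -> float:
        if self.gfp_region is None:
            return 0.0
        return self.gfp_region.area_px2() * self.pixel_size_um**2

    def gfp_area_fraction(self) -> float:
        return self.gfp_area_um2() / self.organoid_area_um2()

    def to_dict(self) -> dict:
        return {
            "type": "organoid",
            "organoid": self.organoid.to_dict(),
            "gfp_region": None if self.gfp_region is None else self.gfp_region.to_dict(),
            "tomato_clusters": [d.to_dict() for d in self.tomato_clusters],
            "focus_z": self.focus_z,
            "n_z": self.n_z,
            "pixel_size_um": self.pixel_size_um,
            "field_shape_px": list(self.field_shape_px),
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrganoidScene":
        return cls(
            organoid=Ellipse.from_dict(d["organoid"]),
            gfp_region=None if d["gfp_region"] is None else Ellipse.from_dict(d["gfp_region"]),
            tomato_clusters=[Disk.from_dict(x) for x in d["tomato_clusters"]],
            focus_z=d["focus_z"],
            n_z=d["n_z"],
            pixel_size_um=d["pixel_size_um"],
            field_shape_px=tuple(d["field_shape_px"]),
            params=d.get("params", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "OrganoidScene":
        return cls.from_dict(json.loads(Path(path).read_text()))


def generate_organoid_scene(params: OrganoidParams, seed: int) -> OrganoidScene:
    """Generate a seeded chimeric-organoid scene.

    The GFP sub-region is a concentric ellipse with axes scaled by
    ``sqrt(gfp_area_fraction)``, so its analytic area fraction is exact.
    Tomato clusters are disjoint disks placed well inside the organoid;
    infeasible packing raises :class:`CrowdedFieldError`.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    ps = params.pixel_size_um
    side_px = int(round(params.field_um / ps))
    a_px = params.organoid_axes_um[0] / ps
    b_px = params.organoid_axes_um[1] / ps
    if max(a_px, b_px) * 2 + 10 > side_px:
        raise CrowdedFieldError("organoid does not fit in the field")
    c0 = (side_px - 1) / 2.0
    jitter = min(4.0 / ps, 0.05 * side_px)
    center = (c0 + rng.uniform(-jitter, jitter), c0 + rng.uniform(-jitter, jitter))
    angle = float(rng.uniform(0, math.pi))
    organoid = Ellipse(center[0], center[1], a_px, b_px, angle)

    if params.gfp_area_fraction == 0:
        gfp = None
    else:
        s = math.sqrt(params.gfp_area_fraction)
        gfp = Ellipse(center[0], center[1], a_px * s, b_px * s, angle)

    r_cl = params.cluster_radius_um / ps
    min_sep = (2 * params.cluster_radius_um + params.min_cluster_gap_um) / ps
    clusters: list[Disk] = []
    for _ in range(params.n_tomato_clusters):
        ok = False
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            px = rng.uniform(center[0] - a_px, center[0] + a_px)
            py = rng.uniform(center[1] - b_px, center[1] + b_px)
            if organoid.quad(np.array(px), np.array(py)) > 0.64:  # well inside
                continue
            if any(math.hypot(px - c.cx, py - c.cy) < min_sep for c in clusters):
                continue
            clusters.append(Disk(float(px), float(py), r_cl))
            ok = True
            break
        if not ok:
            raise CrowdedFieldError("cannot pack tomato clusters inside the organoid")

    focus_z = int(rng.integers(params.n_z))
    return OrganoidScene(
        organoid=organoid,
        gfp_region=gfp,
        tomato_clusters=clusters,
        focus_z=focus_z,
        n_z=params.n_z,
        pixel_size_um=ps,
        field_shape_px=(side_px, side_px),
        params={"seed": int(seed), **{k: _jsonable(getattr(params, k)) for k in vars(params)}},
    )


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    return v
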
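"""Voxelized ex vivo vertebral-body phantom and applicator/probe placement.

Geometry emulates an excised vertebral segment of a ~45 kg pig suspended in
air: an elliptical-cross-section vertebral body (2.5 cm latero-lateral x
2.0 cm dorsoventral, 2.5 cm tall craniocaudal) of cancellous bone inside a
2 mm cortical shell, a 1.0 cm spinal canal (spinal cord properties) running
craniocaudally along the dorsal face, and 7.5 mm cartilage disks cranial and
caudal, all inside an 8 x 4 x 4 cm air box.

Coordinate convention (right-handed, SI meters):

* ``x`` latero-lateral — the applicator shaft axis;
* ``+y`` ventral — the directional radiation direction;
* ``z`` craniocaudal.

The vertebral-body center sits at the origin of the ``x``/``z`` axes; the
body/canal assembly is centered dorsoventrally within the air box.  Voxels
are uniform cubes; voxel centers lie at ``origin + (i + 1/2) * spacing``.

The 14-gauge applicator (outer diameter 2.11 mm) enters through the lateral
cortical wall aimed ventrally, its dorsal ("back") surface a configurable
gap (default 2 mm) from the spinal canal boundary.  Virtual fiber-optic
probes T1 (forward, ventral) and T2 (backward, toward the canal) are placed
in the cross-sectional plane through the center of the radiating zone;
distances are measured from the shaft *axis* (configurable convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .materials import MaterialLibrary

__all__ = [
    "PhantomSpec",
    "ApplicatorPose",
    "LabelGrid",
    "ProbeSpec",
    "build_phantom",
    "place_applicator",
    "default_pose",
    "default_probes",
    "T1_NOMINAL_DISTANCE_M",
    "T2_NOMINAL_DISTANCE_M",
    "T2_HISTOLOGY_DISTANCE_M",
]

#: Forward-channel nominal radial distance (mean of experimental placements).
T1_NOMINAL_DISTANCE_M = 9.5e-3
#: Backward channel, simulation convention.
T2_NOMINAL_DISTANCE_M = 2.5e-3
#: Backward channel, histology-derived minimum-possible placement.
T2_HISTOLOGY_DISTANCE_M = 2.4e-3

#: 14-gauge outer radius: 2.11 mm outer diameter per the standard gauge table.
GAUGE14_RADIUS_M = 1.055e-3

AIR = "air"
APPLICATOR = "applicator"
CORTICAL = "cortical bone"
CANCELLOUS = "cancellous bone"
CARTILAGE = "cartilage"
SPINAL_CORD = "spinal cord"


@dataclass(frozen=True)
class PhantomSpec:
    """Dimensions of the vertebral-body phantom (all meters)."""

    body_width: float = 0.025      # latero-lateral (x)
    body_depth: float = 0.020      # dorsoventral (y)
    body_height: float = 0.025     # craniocaudal (z)
    cortical_thickness: float = 0.002
    canal_diameter: float = 0.010
    disk_thickness: float = 0.0075
    domain_size: Tuple[float, float, float] = (0.08, 0.04, 0.04)
    surround: str = AIR
    cross_section: str = "ellipse"  # "ellipse" (default) or "box"

    def __post_init__(self) -> None:
        for name in (
            "body_width", "body_depth", "body_height",
            "canal_diameter", "disk_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cortical_thickness < 0:
            raise ValueError("cortical_thickness must be >= 0")
        if 2 * self.cortical_thickness >= min(self.body_width, self.body_depth):
            raise ValueError("cortical shell thicker than the body")
        if self.cross_section not in ("ellipse", "box"):
            raise ValueError("cross_section must be 'ellipse' or 'box'")
        if self.body_depth + self.canal_diameter > self.domain_size[1]:
            # canal must fit dorsally inside the domain (see canal_center_y)
            raise ValueError("canal does not fit inside the domain")

    @property
    def canal_center_y(self) -> float:
        """Canal axis y: the canal is tangent to the dorsal body surface."""
        return -(self.body_depth / 2 + self.canal_diameter / 2)

    @property
    def origin(self) -> Tuple[float, float, float]:
        """Corner of the air box: x/z centered on the body, the body+canal
        assembly centered dorsoventrally."""
        dx, dy, dz = self.domain_size
        margin = (dy - self.body_depth - self.canal_diameter) / 2
        if margin < 0:
            raise ValueError("domain too shallow for body + canal")
        y0 = -(self.body_depth / 2 + self.canal_diameter + margin)
        return (-dx / 2, y0, -dz / 2)


@dataclass(frozen=True)
class ApplicatorPose:
    """Pose of the directional applicator.

    ``axis_direction`` points distally (from entry toward the tip);
    ``radiation_direction`` is the forward-firing direction, perpendicular to
    the shaft.  ``active_length`` is the axial extent of the radiating zone,
    centered ``active_length/2`` proximal of the tip.
    """

    tip_position: Tuple[float, float, float]
    axis_direction: Tuple[float, float, float] = (-1.0, 0.0, 0.0)
    radiation_direction: Tuple[float, float, float] = (0.0, 1.0, 0.0)
    shaft_radius: float = GAUGE14_RADIUS_M
    active_length: float = 0.010
    back_to_canal_gap: float = 0.002
    shaft_length: float = 0.06  # distal modeled extent; clipped to the domain

    def __post_init__(self) -> None:
        a = np.asarray(self.axis_direction, float)
        r = np.asarray(self.radiation_direction, float)
        if not np.isclose(np.linalg.norm(a), 1.0) or not np.isclose(np.linalg.norm(r), 1.0):
            raise ValueError("axis_direction and radiation_direction must be unit vectors")
        if abs(float(a @ r)) >= 1e-9:
            raise ValueError("radiation_direction must be perpendicular to axis_direction")
        if self.shaft_radius <= 0 or self.active_length <= 0:
            raise ValueError("shaft_radius and active_length must be > 0")

    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.axis_direction, float)

    @property
    def forward(self) -> np.ndarray:
        return np.asarray(self.radiation_direction, float)

    @property
    def tip(self) -> np.ndarray:
        return np.asarray(self.tip_position, float)

    @property
    def active_center(self) -> np.ndarray:
        """Center of the radiating zone, on the shaft axis."""
        return self.tip - (self.active_length / 2) * self.axis


def default_pose(spec: PhantomSpec = PhantomSpec()) -> ApplicatorPose:
    """Standard pose: shaft along x through the lateral wall, aimed ventrally,
    back surface ``back_to_canal_gap`` from the canal, radiating zone centered
    on the body midplane (x = 0)."""
    gap = 0.002
    radius = GAUGE14_RADIUS_M
    active_length = 0.010
    canal_top_y = spec.canal_center_y + spec.canal_diameter / 2  # == -body_depth/2
    axis_y = canal_top_y + gap + radius
    # tip half an active length past the body midplane so active_center.x == 0
    tip = (-active_length / 2, axis_y, 0.0)
    return ApplicatorPose(
        tip_position=tip,
        axis_direction=(-1.0, 0.0, 0.0),
        radiation_direction=(0.0, 1.0, 0.0),
        shaft_radius=radius,
        active_length=active_length,
        back_to_canal_gap=gap,
    )


@dataclass
class LabelGrid:
    """Uniform Cartesian voxel grid with one tissue-class label per voxel.

    ``label_ids`` holds small integer codes; ``class_names`` maps code ->
    label.  ``applicator_mask`` marks the outer shaft-surface voxels carrying
    the isothermal (Dirichlet) boundary condition.
    """

    origin: Tuple[float, float, float]
    spacing: float
    label_ids: np.ndarray                 # int8, shape (nx, ny, nz)
    class_names: List[str]
    applicator_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    pose: Optional[ApplicatorPose] = None

    def __post_init__(self) -> None:
        if self.applicator_mask is None:
            self.applicator_mask = np.zeros(self.label_ids.shape, dtype=bool)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.label_ids.shape)  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def class_id(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"no voxels of class {name!r} declared") from None

    def mask(self, name: str) -> np.ndarray:
        if name not in self.class_names:
            return np.zeros(self.shape, dtype=bool)
        return self.label_ids == self.class_id(name)

    def class_volume(self, name: str) -> float:
        """Total volume (m^3) of voxels labeled ``name``."""
        return float(self.mask(name).sum()) * self.voxel_volume

    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis."""
        o = np.asarray(self.origin)
        return tuple(
            o[d] + (np.arange(self.shape[d]) + 0.5) * self.spacing for d in range(3)
        )  # type: ignore[return-value]

    def centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center coordinate arrays."""
        x, y, z = self.axes()
        return x[:, None, None], y[None, :, None], z[None, None, :]

    def contains(self, point: Sequence[float]) -> bool:
        p = np.asarray(point, float)
        o = np.asarray(self.origin)
        hi = o + np.asarray(self.shape) * self.spacing
        return bool(np.all(p >= o) and np.all(p <= hi))

    def validate_against(self, library: MaterialLibrary) -> None:
        present = np.unique(self.label_ids)
        for code in present:
            name = self.class_names[int(code)]
            if name not in library:
                raise KeyError(f"label {name!r} missing from material library")

    def copy(self) -> "LabelGrid":
        return LabelGrid(
            origin=self.origin,
            spacing=self.spacing,
            label_ids=self.label_ids.copy(),
            class_names=list(self.class_names),
            applicator_mask=self.applicator_mask.copy(),
            pose=self.pose,
        )


@dataclass(frozen=True)
class ProbeSpec:
    """A virtual point temperature sensor."""

    name: str
    position: Tuple[float, float, float]
    nominal_distance: float  # m, radial offset from the shaft axis


def build_phantom(spec: PhantomSpec = PhantomSpec(), spacing: float = 1e-3) -> LabelGrid:
    """Voxelize the vertebral-body phantom.

    ``spacing`` must resolve the cortical shell (``<= cortical_thickness/2``
    whenever a shell is present).  Labeling is deterministic: each voxel gets
    the class of the region containing its center, painted in the order
    surround -> body (cortical/cancellous) -> disks -> canal.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if spec.cortical_thickness > 0 and spacing > spec.cortical_thickness / 2:
        raise ValueError(
            f"spacing {spacing * 1e3:.2f} mm too coarse to resolve the "
            f"{spec.cortical_thickness * 1e3:.1f} mm cortical shell; need "
            f"spacing <= {spec.cortical_thickness / 2 * 1e3:.2f} mm"
        )

    shape = tuple(int(round(s / spacing)) for s in spec.domain_size)
    class_names = [AIR, CORTICAL, CANCELLOUS, CARTILAGE, SPINAL_CORD, APPLICATOR]
    ids = np.zeros(shape, dtype=np.int8)  # surround/air = 0
    grid = LabelGrid(origin=spec.origin, spacing=spacing,
                     label_ids=ids, class_names=class_names)
    X, Y, Z = grid.centers()

    a, b = spec.body_width / 2, spec.body_depth / 2
    t = spec.cortical_thickness
    hz = spec.body_height / 2

    if spec.cross_section == "ellipse":
        in_outer = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
        if t > 0:
            in_inner = (X / (a - t)) ** 2 + (Y / (b - t)) ** 2 <= 1.0
        else:
            in_inner = in_outer
    else:  # box
        in_outer = (np.abs(X) <= a) & (np.abs(Y) <= b)
        in_inner = (np.abs(X) <= a - t) & (np.abs(Y) <= b - t)

    in_body_z = np.abs(Z) <= hz
    in_core_z = np.abs(Z) <= hz - t  # cortical endplates cranial/caudal
    body = in_outer & in_body_z
    core = in_inner & in_core_z
    ids[body] = class_names.index(CORTICAL)
    ids[body & core] = class_names.index(CANCELLOUS)

    # intervertebral disks: same outer cross-section, cranial and caudal
    in_disk_z = (np.abs(Z) > hz) & (np.abs(Z) <= hz + spec.disk_thickness)
    ids[in_outer & in_disk_z] = class_names.index(CARTILAGE)

    # spinal canal: straight craniocaudal cylinder, dorsal to the body
    yc = spec.canal_center_y
    in_canal = np.broadcast_to(
        X**2 + (Y - yc) ** 2 <= (spec.canal_diameter / 2) ** 2, shape
    )
    ids[in_canal] = class_names.index(SPINAL_CORD)

    return grid


def place_applicator(grid: LabelGrid, pose: ApplicatorPose) -> LabelGrid:
    """Label the shaft voxels and mark the Dirichlet surface mask.

    The shaft is a cylinder of ``pose.shaft_radius`` extending
    ``pose.shaft_length`` proximally from the tip (clipped to the domain).
    Rejects poses whose shaft would intersect the spinal canal.  Returns a new
    grid; the input is not modified.
    """
    out = grid.copy()
    X, Y, Z = out.centers()
    P = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1)  # (nx,ny,nz,3)
    rel = P - pose.tip
    # axial coordinate s >= 0 going proximally (toward entry) from the tip
    s = -(rel @ pose.axis)
    radial = rel + s[..., None] * pose.axis[None, None, None, :]
    r2 = np.einsum("...i,...i->...", radial, radial)
    in_shaft = (s >= 0.0) & (s <= pose.shaft_length) & (r2 <= pose.shaft_radius**2)

    if not in_shaft.any():
        raise ValueError("applicator shaft lies outside the voxel domain")
    if (in_shaft & out.mask(SPINAL_CORD)).any():
        raise ValueError("applicator shaft intersects the spinal canal")

    app_id = out.class_names.index(APPLICATOR)
    out.label_ids[in_shaft] = app_id

    # surface voxels: applicator voxels with a 6-neighbor that is not applicator
    is_app = out.label_ids == app_id
    surface = np.zeros_like(is_app)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(is_app, shift, axis=axis)
            # voxels at the domain edge count as surface
            edge = [slice(None)] * 3
            edge[axis] = 0 if shift == 1 else -1
            rolled[tuple(edge)] = False
            surface |= is_app & ~rolled
    out.applicator_mask = surface
    out.pose = pose
    return out


def default_probes(pose: ApplicatorPose) -> List[ProbeSpec]:
    """Virtual thermometry channels in the plane of maximum heating.

    T1 forward at 9.5 mm (mean experimental placement), T2 backward at 2.5 mm
    (simulation convention) with an alternate ``T2_histology`` channel at the
    histology-derived 2.4 mm.  All distances from the shaft axis.
    """
    c = pose.active_center
    f = pose.forward

    def probe(name: str, signed_distance: float) -> ProbeSpec:
        pos = c + signed_distance * f
        return ProbeSpec(name=name, position=tuple(pos),
                         nominal_distance=abs(signed_distance))

    return [
        probe("T1", +T1_NOMINAL_DISTANCE_M),
        probe("T2", -T2_NOMINAL_DISTANCE_M),
        probe("T2_histology", -T2_HISTOLOGY_DISTANCE_M),
    ]
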
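"""Synthetic anthropomorphic chest-phantom scans.

This module generates the ground truth that the rest of the pipeline is
tested against: a digital stand-in for a commercial anthropomorphic chest
phantom (LUNGMAN-class) with outer chest plates, two foam lungs, and three
tubular channels holding interchangeable inserts — air, distilled-water
vials, standardized NIST foams, synthetic bone, textured lung-sample
material, and a 2 cm solid polyethylene cube used for MTF estimation.

The simulator is deliberately a *linear blur + correlated noise* model, not
a CT physics simulation: no beam hardening, scatter, or reconstruction
algorithms.  The net effect of a scanner's dose-modulation and iterative /
deep-learning reconstruction chain is abstracted into three knobs of
:class:`AcquisitionModel` — an anisotropic Gaussian PSF, a noise magnitude
tied to dose by the quantum-noise relation ``SD ∝ CTDIvol^(-1/2)``, and a
small correlation kernel shaping the noise texture.  That is exactly the
level of description the downstream metrics (HU statistics, LAA, MTF, NPS)
respond to, and it keeps every metric's ground truth computable in closed
form or by brute force.

Geometry constants (tube positions, insert stacking, per-configuration
insert sets) are package-defined: the physical phantom's blueprint is not
public.  All coordinates are mm with the phantom centered on the origin;
x = left-right, y = anterior-posterior, z = cranio-caudal.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .volume_io import VoxelVolume

__all__ = [
    "MaterialSpec",
    "InsertSpec",
    "PhantomLayout",
    "AcquisitionModel",
    "LabelVolume",
    "MATERIALS",
    "CONFIGURATIONS",
    "build_layout",
    "large_tube_slot",
    "rasterize",
    "simulate_scan",
    "analytic_cube_volume",
    "cube_rotation",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class MaterialSpec:
    """A phantom material: nominal HU plus intrinsic heterogeneity.

    ``texture_sd`` is the voxel SD of the material itself (0 for uniform
    materials such as air, water, or acrylic); it is realised once per
    rasterization as a seeded, 1-mm-smoothed Gaussian field so that LAA
    ground truth is computable on the noiseless volume.
    """

    name: str
    nominal_hu: float
    texture_sd: float = 0.0

    def __post_init__(self):
        if not (-1024.0 <= self.nominal_hu <= 3000.0):
            raise ValueError(f"nominal_hu {self.nominal_hu} outside [-1024, 3000]")
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be >= 0")


@dataclass(frozen=True)
class InsertSpec:
    """One geometric element of the phantom.

    Cylinders run along z (``axis`` fixed to +z); the MTF cube may carry a
    small tilt (degrees about z then x) so that its faces are slightly
    oblique to the voxel grid — matching how a physical cube sits in its
    holder, and providing the sampling-phase diversity the edge-pooling MTF
    estimator exploits.  ``measured=False`` marks structural parts (tube
    carriers, shells, end caps) that are painted but never labeled as ROIs.
    """

    label: str
    material: MaterialSpec
    shape: str  # "cylinder" | "cube"
    center: tuple[float, float, float]
    radius_or_halfedge: float
    length: float = 0.0  # cylinders only
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    tilt_deg: tuple[float, float] = (0.0, 0.0)  # cube only: about z, about x
    measured: bool = True

    def __post_init__(self):
        if self.shape not in ("cylinder", "cube"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.radius_or_halfedge <= 0:
            raise ValueError("radius_or_halfedge must be positive")
        if self.shape == "cylinder" and self.length <= 0:
            raise ValueError("cylinder length must be positive")

    def rotation(self) -> np.ndarray:
        return cube_rotation(*self.tilt_deg)

    def z_extent(self) -> tuple[float, float]:
        cz = self.center[2]
        if self.shape == "cylinder":
            h = self.length / 2.0
        else:
            # rotated cube: conservative bound
            h = self.radius_or_halfedge * np.sqrt(3.0)
        return (cz - h, cz + h)


def cube_rotation(tilt_z_deg: float, tilt_x_deg: float) -> np.ndarray:
    """Rotation matrix (columns = cube axes in world frame)."""
    az, ax = np.deg2rad(tilt_z_deg), np.deg2rad(tilt_x_deg)
    rz = np.array([[np.cos(az), -np.sin(az), 0.0],
                   [np.sin(az), np.cos(az), 0.0],
                   [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0],
                   [0.0, np.cos(ax), -np.sin(ax)],
                   [0.0, np.sin(ax), np.cos(ax)]])
    return rx @ rz


@dataclass
class PhantomLayout:
    """Declarative geometry of one phantom configuration."""

    configuration: str
    inserts: list[InsertSpec]
    body_extent: tuple[float, float] = (435.0, 229.0)  # left-right, ant-post
    lung_foam_hu: float = -629.2
    lung_foam_texture_sd: float = 29.0
    tube_wall_hu: float = 60.0
    body_hu: float = 35.0

    def __post_init__(self):
        labels = [i.label for i in self.inserts]
        if len(labels) != len(set(labels)):
            raise ValueError("insert labels must be unique")
        hx, hy = self.body_extent[0] / 2.0, self.body_extent[1] / 2.0
        for ins in self.inserts:
            if abs(ins.center[0]) > hx or abs(ins.center[1]) > hy:
                raise ValueError(f"insert {ins.label} center outside body extent")

    @property
    def measured_inserts(self) -> list[InsertSpec]:
        return [i for i in self.inserts if i.measured]

    def to_json(self, path: str | Path) -> None:
        def enc(ins):
            return {
                "label": ins.label,
                "material": {"name": ins.material.name,
                             "nominal_hu": ins.material.nominal_hu,
                             "texture_sd": ins.material.texture_sd},
                "shape": ins.shape,
                "center": list(ins.center),
                "radius_or_halfedge": ins.radius_or_halfedge,
                "length": ins.length,
                "axis": list(ins.axis),
                "tilt_deg": list(ins.tilt_deg),
                "measured": ins.measured,
            }
        doc = {
            "configuration": self.configuration,
            "body_extent": list(self.body_extent),
            "lung_foam_hu": self.lung_foam_hu,
            "lung_foam_texture_sd": self.lung_foam_texture_sd,
            "tube_wall_hu": self.tube_wall_hu,
            "body_hu": self.body_hu,
            "inserts": [enc(i) for i in self.inserts],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomLayout":
        doc = json.loads(Path(path).read_text())
        inserts = [
            InsertSpec(
                label=d["label"],
                material=MaterialSpec(**d["material"]),
                shape=d["shape"],
                center=tuple(d["center"]),
                radius_or_halfedge=d["radius_or_halfedge"],
                length=d["length"],
                axis=tuple(d["axis"]),
                tilt_deg=tuple(d["tilt_deg"]),
                measured=d["measured"],
            )
            for d in doc["inserts"]
        ]
        return cls(
            configuration=doc["configuration"],
            inserts=inserts,
            body_extent=tuple(doc["body_extent"]),
            lung_foam_hu=doc["lung_foam_hu"],
            lung_foam_texture_sd=doc["lung_foam_texture_sd"],
            tube_wall_hu=doc["tube_wall_hu"],
            body_hu=doc["body_hu"],
        )


@dataclass
class AcquisitionModel:
    """Net stand-in for dose modulation + reconstruction.

    Noise magnitude follows the quantum-noise model: the voxel SD in a
    uniform region is ``noise_sd_at_reference * sqrt(reference_ctdi /
    ctdi_vol)``.  ``noise_kernel`` (normalized to unit sum of squares, so it
    preserves white-noise variance) shapes the noise texture; the default
    3x3x3 stencil gives the mild positive correlation typical of
    reconstructed CT noise.
    """

    ctdi_vol: float = 2.22
    reference_ctdi: float = 2.22
    noise_sd_at_reference: float = 15.4
    psf_sigma_inplane: float = 0.52
    psf_sigma_z: float = 0.54
    noise_kernel: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.ctdi_vol <= 0:
            raise ValueError("ctdi_vol must be positive")
        for name in ("reference_ctdi", "noise_sd_at_reference",
                     "psf_sigma_inplane", "psf_sigma_z"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_kernel is None:
            k1 = np.array([0.28, 1.0, 0.28])
            self.noise_kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        self.noise_kernel = np.asarray(self.noise_kernel, dtype=np.float64)
        norm = np.sqrt((self.noise_kernel ** 2).sum())
        if norm == 0:
            raise ValueError("noise_kernel must be non-zero")
        self.noise_kernel = self.noise_kernel / norm

    @property
    def noise_sd(self) -> float:
        if self.reference_ctdi == 0:
            return self.noise_sd_at_reference
        return self.noise_sd_at_reference * np.sqrt(self.reference_ctdi / self.ctdi_vol)


@dataclass
class LabelVolume:
    """Integer label grid paired with a name -> integer map."""

    labels: np.ndarray
    label_map: dict[str, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_map[name]

    def write(self, nifti_path: str | Path, json_path: str | Path) -> None:
        import nibabel as nib

        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), str(nifti_path))
        Path(json_path).write_text(json.dumps(self.label_map, indent=2))


# ---------------------------------------------------------------------------
# Materials and configurations

_AIR_HU = -1000.0

#: Material library.  Air and water use the densitometric ground-truth values
#: (-1000 / 0 HU); foam and lung-material HUs mirror a modern reference
#: reconstruction; structural plastics use typical CT numbers.
MATERIALS: dict[str, MaterialSpec] = {
    m.name: m
    for m in [
        MaterialSpec("air", -1000.0),
        MaterialSpec("water", 0.0),
        MaterialSpec("lung_sample", -655.6, texture_sd=130.0),
        MaterialSpec("phantom_lung_foam", -629.2, texture_sd=29.0),
        MaterialSpec("nist4", -934.0),
        MaterialSpec("nist8", -883.1),
        MaterialSpec("nist12", -821.4),
        MaterialSpec("nist14", -778.1),
        MaterialSpec("nist20", -683.0),
        MaterialSpec("bone20", 148.0),
        MaterialSpec("bone50", 570.0),
        MaterialSpec("acrylic", 120.0),
        MaterialSpec("pmp", -180.0),
        MaterialSpec("low_contrast", 15.0),
        MaterialSpec("hdpe", -70.0),
        MaterialSpec("urethane", 60.0),
        MaterialSpec("tissue", 35.0),
    ]
}

# Tube geometry (mm).  Large tube in the right lung (negative x = patient
# right), two small tubes (anterior/posterior) in the left lung.
_LARGE_TUBE_XY = (-65.0, 0.0)
_SMALL_TUBE_ANT_XY = (65.0, -55.0)
_SMALL_TUBE_POST_XY = (65.0, 55.0)
_LARGE_TUBE_R_IN, _LARGE_TUBE_R_OUT = 23.0, 25.0
_SMALL_TUBE_R_IN, _SMALL_TUBE_R_OUT = 14.0, 16.0
_LUNG_CENTERS = ((-65.0, 0.0), (65.0, 0.0))
_LUNG_SEMIAXES = ((62.0, 88.0), (62.0, 88.0))

_SLOT_LENGTH = 40.0
_SLOT_GAP = 5.0
_LARGE_INSERT_R = 22.0
_LARGE_CORE_R = 20.0
_SMALL_INSERT_R = 13.0
_CUBE_HALF_EDGE = 10.0  # the MTF cube has 2 cm edges
_CUBE_TILT = (3.0, 3.0)

#: Insert slots per configuration: (large tube, small anterior, small posterior).
CONFIGURATIONS: dict[str, dict[str, list[str]]] = {
    "i": {
        "large": ["lung_sample_A", "mtf_cube", "air"],
        "anterior": ["nist4", "nist8", "nist12"],
        "posterior": ["bone20", "bone50", "acrylic"],
    },
    "ii": {
        "large": ["lung_sample_B", "water_vials", "lung_sample_C"],
        "anterior": ["nist14", "nist20", "pmp"],
        "posterior": ["low_contrast", "acrylic", "bone20"],
    },
    "iii": {
        "large": ["lung_sample_D", "lung_sample_E", "lung_sample_F"],
        "anterior": ["nist8", "nist14", "nist20"],
        "posterior": ["pmp", "low_contrast", "bone50"],
    },
    "iv": {
        "large": ["water_vials", "air", "mtf_cube", "lung_sample_A"],
        "anterior": ["nist4", "nist12", "nist20"],
        "posterior": ["bone20", "acrylic", "pmp"],
    },
}


def _slot_centers(n: int) -> list[float]:
    pitch = _SLOT_LENGTH + _SLOT_GAP
    return [(i - (n - 1) / 2.0) * pitch for i in range(n)]


def large_tube_slot(name: str, cz: float) -> list[InsertSpec]:
    """Build the insert(s) occupying one large-tube slot."""
    cx, cy = _LARGE_TUBE_XY
    hdpe = MATERIALS["hdpe"]
    if name == "water_vials":
        carrier = InsertSpec(f"_carrier_{cz:+.0f}", MATERIALS["urethane"], "cylinder",
                             (cx, cy, cz), _LARGE_INSERT_R, _SLOT_LENGTH,
                             measured=False)
        v1 = InsertSpec("water_vial_1", MATERIALS["water"], "cylinder",
                        (cx, cy, cz - 10.5), 10.0, 15.0)
        v2 = InsertSpec("water_vial_2", MATERIALS["water"], "cylinder",
                        (cx, cy, cz + 10.5), 10.0, 15.0)
        return [carrier, v1, v2]
    if name == "mtf_cube":
        # HDPE end cap with the 2 cm HDPE cube glued beneath, surrounded by air
        cap = InsertSpec(f"_cap_{cz:+.0f}", hdpe, "cylinder",
                         (cx, cy, cz + _SLOT_LENGTH / 2 - 2.0), _LARGE_INSERT_R,
                         4.0, measured=False)
        cube = InsertSpec("mtf_cube", hdpe, "cube",
                          (cx, cy, cz + _SLOT_LENGTH / 2 - 4.0 - _CUBE_HALF_EDGE),
                          _CUBE_HALF_EDGE, tilt_deg=_CUBE_TILT)
        return [cap, cube]
    if name == "air":
        shell = InsertSpec(f"_shell_air_{cz:+.0f}", hdpe, "cylinder",
                           (cx, cy, cz), _LARGE_INSERT_R, _SLOT_LENGTH,
                           measured=False)
        core = InsertSpec("air", MATERIALS["air"], "cylinder",
                          (cx, cy, cz), _LARGE_CORE_R, _SLOT_LENGTH - 4.0)
        return [shell, core]
    if name.startswith("lung_sample"):
        shell = InsertSpec(f"_shell_{name}", hdpe, "cylinder",
                           (cx, cy, cz), _LARGE_INSERT_R, _SLOT_LENGTH,
                           measured=False)
        core = InsertSpec(name, MATERIALS["lung_sample"], "cylinder",
                          (cx, cy, cz), _LARGE_CORE_R, _SLOT_LENGTH - 4.0)
        return [shell, core]
    raise ValueError(f"unknown large-tube insert {name!r}")


def build_layout(configuration: str) -> PhantomLayout:
    """Build the declarative layout for one phantom configuration.

    Parameters
    ----------
    configuration : {"i", "ii", "iii", "iv"}
        Insert arrangement.  Configurations i-iii spread the full insert set
        over three scans; configuration iv packs water, air, the MTF cube and
        a lung sample into the large tube for single-series sites.
    """
    if configuration not in CONFIGURATIONS:
        raise ValueError(
            f"unknown configuration {configuration!r}; valid options: "
            + ", ".join(sorted(CONFIGURATIONS))
        )
    plan = CONFIGURATIONS[configuration]
    inserts: list[InsertSpec] = []
    for cz, name in zip(_slot_centers(len(plan["large"])), plan["large"]):
        inserts.extend(large_tube_slot(name, cz))
    for tube_xy, key in ((_SMALL_TUBE_ANT_XY, "anterior"),
                         (_SMALL_TUBE_POST_XY, "posterior")):
        names = plan[key]
        for cz, name in zip(_slot_centers(len(names)), names):
            inserts.append(
                InsertSpec(name, MATERIALS[_material_of(name)], "cylinder",
                           (tube_xy[0], tube_xy[1], cz), _SMALL_INSERT_R,
                           _SLOT_LENGTH)
            )
    return PhantomLayout(configuration=configuration, inserts=inserts)


def _material_of(name: str) -> str:
    if name.startswith("lung_sample"):
        return "lung_sample"
    return name


# ---------------------------------------------------------------------------
# Rasterization

_BASE_LABELS = {"background": 0, "body": 1, "lung_foam": 2, "tube_wall": 3,
                "structural": 4}


def _grid_world(shape, spacing, origin):
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    return xs, ys, zs


def _insert_mask(ins: InsertSpec, xs, ys, zs) -> np.ndarray:
    if ins.shape == "cylinder":
        r2 = (xs[:, None] - ins.center[0]) ** 2 + (ys[None, :] - ins.center[1]) ** 2
        inplane = r2 <= ins.radius_or_halfedge ** 2
        axial = np.abs(zs - ins.center[2]) <= ins.length / 2.0
        return inplane[:, :, None] & axial[None, None, :]
    # cube (possibly tilted): evaluate |R^T (p - c)|_inf <= h
    R = ins.rotation()
    h = ins.radius_or_halfedge
    dx = xs - ins.center[0]
    dy = ys - ins.center[1]
    dz = zs - ins.center[2]
    mask = np.ones((len(xs), len(ys), len(zs)), dtype=bool)
    for i in range(3):
        u = (R[0, i] * dx[:, None, None] + R[1, i] * dy[None, :, None]
             + R[2, i] * dz[None, None, :])
        mask &= np.abs(u) <= h
    return mask


def _texture_field(mask: np.ndarray, spacing, sd: float, rng) -> np.ndarray:
    """Seeded 1-mm-smoothed Gaussian field with exact mean 0 / SD ``sd`` over mask.

    Returns the per-voxel values in the C order of the mask's True voxels,
    ready for ``hu[mask] += values``.
    """
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    pad = tuple(int(np.ceil(3.0 / s)) + 1 for s in spacing)
    box = tuple(hi[i] - lo[i] + 2 * pad[i] for i in range(3))
    white = rng.standard_normal(box)
    sig = tuple(1.0 / s for s in spacing)  # 1 mm smoothing kernel
    smooth = ndimage.gaussian_filter(white, sigma=sig)
    sub = smooth[tuple(slice(pad[i], pad[i] + hi[i] - lo[i]) for i in range(3))]
    local = mask[tuple(slice(lo[i], hi[i]) for i in range(3))]
    vals = sub[local]
    vals = vals - vals.mean()
    s = vals.std()
    if s > 0:
        vals = vals * (sd / s)
    return vals


def default_grid(layout: PhantomLayout,
                 spacing: tuple[float, float, float] = (0.51, 0.51, 0.5),
                 inplane_shape: tuple[int, int] = (512, 512),
                 z_margin: float = 10.0) -> tuple[tuple[int, int, int],
                                                  tuple[float, float, float]]:
    """Grid shape and origin covering all inserts (z auto-fit), 260 mm-class FOV."""
    z_lo = min(i.z_extent()[0] for i in layout.inserts) - z_margin
    z_hi = max(i.z_extent()[1] for i in layout.inserts) + z_margin
    nz = int(np.ceil((z_hi - z_lo) / spacing[2])) + 1
    shape = (inplane_shape[0], inplane_shape[1], nz)
    origin = (
        -(shape[0] - 1) / 2.0 * spacing[0],
        -(shape[1] - 1) / 2.0 * spacing[1],
        z_lo,
    )
    return shape, origin


def rasterize(
    layout: PhantomLayout,
    spacing: tuple[float, float, float] = (0.51, 0.51, 0.5),
    grid_shape: tuple[int, int, int] | None = None,
    origin: tuple[float, float, float] | None = None,
    texture_seed: int = 0,
) -> tuple[VoxelVolume, LabelVolume]:
    """Noiseless HU volume plus integer label volume for one layout.

    Every voxel takes its material's nominal HU (voxel-center point
    sampling); textured materials additionally receive a seeded 1-mm-smoothed
    Gaussian field normalized to exact mean 0 and SD ``texture_sd`` over the
    region, so per-region ground truth (mean, SD, LAA) is computable by brute
    force on the returned volume.  If ``grid_shape`` is omitted the z extent
    is auto-fitted to the layout at a 512x512 in-plane grid (260 mm-class
    field of view, tight to the ribcage, cropping the chest plates
    laterally).
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive componentwise")
    if grid_shape is None:
        grid_shape, auto_origin = default_grid(layout, spacing)
        if origin is None:
            origin = auto_origin
    elif origin is None:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(grid_shape, spacing))
    xs, ys, zs = _grid_world(grid_shape, spacing, origin)

    # containment: every measured insert must fit inside the grid
    for ins in layout.measured_inserts:
        zlo, zhi = ins.z_extent()
        r = ins.radius_or_halfedge * (np.sqrt(2) if ins.shape == "cube" else 1.0)
        if (zlo < zs[0] - spacing[2] / 2 or zhi > zs[-1] + spacing[2] / 2
                or ins.center[0] - r < xs[0] or ins.center[0] + r > xs[-1]
                or ins.center[1] - r < ys[0] or ins.center[1] + r > ys[-1]):
            raise ValueError(
                f"grid too small to contain insert {ins.label!r}: "
                f"grid z [{zs[0]:.1f}, {zs[-1]:.1f}] mm"
            )

    hu = np.full(grid_shape, _AIR_HU, dtype=np.float64)
    labels = np.zeros(grid_shape, dtype=np.int32)

    # body ellipse (chest plates included; may be cropped by a tight FOV)
    hx, hy = layout.body_extent[0] / 2.0, layout.body_extent[1] / 2.0
    body2d = (xs[:, None] / hx) ** 2 + (ys[None, :] / hy) ** 2 <= 1.0
    body = np.broadcast_to(body2d[:, :, None], grid_shape)
    hu[body] = layout.body_hu
    labels[body] = _BASE_LABELS["body"]

    # lungs
    lung2d = np.zeros(grid_shape[:2], dtype=bool)
    for (cx, cy), (ax_, ay_) in zip(_LUNG_CENTERS, _LUNG_SEMIAXES):
        lung2d |= ((xs[:, None] - cx) / ax_) ** 2 + ((ys[None, :] - cy) / ay_) ** 2 <= 1.0
    lung = np.broadcast_to(lung2d[:, :, None], grid_shape) & body
    hu[lung] = layout.lung_foam_hu
    labels[lung] = _BASE_LABELS["lung_foam"]

    # tubes: wall annulus + interior air, full z
    for (cx, cy), (r_in, r_out) in (
        (_LARGE_TUBE_XY, (_LARGE_TUBE_R_IN, _LARGE_TUBE_R_OUT)),
        (_SMALL_TUBE_ANT_XY, (_SMALL_TUBE_R_IN, _SMALL_TUBE_R_OUT)),
        (_SMALL_TUBE_POST_XY, (_SMALL_TUBE_R_IN, _SMALL_TUBE_R_OUT)),
    ):
        r2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
        wall2d = (r2 <= r_out ** 2) & (r2 > r_in ** 2)
        in2d = r2 <= r_in ** 2
        wall = np.broadcast_to(wall2d[:, :, None], grid_shape)
        interior = np.broadcast_to(in2d[:, :, None], grid_shape)
        hu[wall] = layout.tube_wall_hu
        labels[wall] = _BASE_LABELS["tube_wall"]
        hu[interior] = _AIR_HU
        labels[interior] = _BASE_LABELS["background"]

    # inserts: structural first, measured after (paint order = occlusion order)
    label_map = dict(_BASE_LABELS)
    next_label = 10
    rng_base = texture_seed
    ordered = ([i for i in layout.inserts if not i.measured]
               + [i for i in layout.inserts if i.measured])
    for ins in ordered:
        mask = _insert_mask(ins, xs, ys, zs)
        if not mask.any():
            continue
        hu[mask] = ins.material.nominal_hu
        if ins.material.texture_sd > 0:
            seed = (rng_base + zlib.crc32(ins.label.encode())) % (2**31)
            hu[mask] += _texture_field(mask, spacing, ins.material.texture_sd,
                                       np.random.default_rng(seed))
        if ins.measured:
            label_map[ins.label] = next_label
            labels[mask] = next_label
            next_label += 1
        else:
            labels[mask] = _BASE_LABELS["structural"]

    # lung-foam texture (drawn last so inserts are untouched)
    foam = labels == _BASE_LABELS["lung_foam"]
    if layout.lung_foam_texture_sd > 0 and foam.any():
        seed = (rng_base + zlib.crc32(b"lung_foam")) % (2**31)
        hu[foam] += _texture_field(foam, spacing, layout.lung_foam_texture_sd,
                                   np.random.default_rng(seed))

    vol = VoxelVolume(hu, spacing=spacing, origin=origin)
    lab = LabelVolume(labels, label_map, spacing=spacing, origin=origin)
    return vol, lab


# ---------------------------------------------------------------------------
# Scan simulation


def simulate_scan(truth: VoxelVolume, acq: AcquisitionModel) -> VoxelVolume:
    """Blur the noiseless volume with the acquisition PSF and add dose-scaled
    correlated noise.

    The PSF is a separable Gaussian (``psf_sigma_inplane`` for x/y,
    ``psf_sigma_z`` for z, both mm).  Noise is seeded white Gaussian noise
    filtered by ``acq.noise_kernel`` (unit sum of squares, hence variance
    preserving) and scaled so a uniform region has voxel SD equal to
    ``acq.noise_sd``.  Deterministic given ``acq.seed``.
    """
    if not np.all(np.isfinite(truth.voxels)):
        raise ValueError("input volume contains non-finite values")
    sig_vox = (
        acq.psf_sigma_inplane / truth.spacing[0],
        acq.psf_sigma_inplane / truth.spacing[1],
        acq.psf_sigma_z / truth.spacing[2],
    )
    if any(s > 0 for s in sig_vox):
        blurred = ndimage.gaussian_filter(truth.voxels, sigma=sig_vox)
    else:
        blurred = truth.voxels.copy()
    sd = acq.noise_sd
    if sd > 0:
        rng = np.random.default_rng(acq.seed)
        white = rng.standard_normal(truth.shape)
        noise = ndimage.convolve(white, acq.noise_kernel, mode="reflect")
        blurred = blurred + sd * noise
    return VoxelVolume(blurred, spacing=truth.spacing, origin=truth.origin)


# ---------------------------------------------------------------------------
# Analytic blurred cube (exact continuous-domain simulation)


def analytic_cube_volume(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[float, float, float],
    half_edge: float = _CUBE_HALF_EDGE,
    tilt_deg: tuple[float, float] = _CUBE_TILT,
    sigma: float | tuple[float, float, float] = 0.5,
    cube_hu: float = MATERIALS["hdpe"].nominal_hu,
    background_hu: float = _AIR_HU,
    origin: tuple[float, float, float] | None = None,
) -> VoxelVolume:
    """Sample the *exact* Gaussian-blurred rotated cube.

    Because an isotropic Gaussian commutes with rotation, the blurred cube is
    a product of erf pairs in the cube frame; sampling that closed form at
    voxel centers gives a simulated scan with zero discretization error in
    the blur — the correct oracle for MTF recovery tests (the measured
    spread then comes from sigma alone, not from rasterize-then-filter
    artifacts).  An anisotropic ``sigma`` triple is supported only for the
    untilted cube, where the blur stays separable along the cube axes.
    """
    if origin is None:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    xs, ys, zs = _grid_world(shape, spacing, origin)
    sigmas = ((sigma, sigma, sigma) if np.isscalar(sigma) else tuple(sigma))
    if len(set(sigmas)) > 1 and any(t != 0 for t in tilt_deg):
        raise ValueError("anisotropic sigma requires an untilted cube")
    R = cube_rotation(*tilt_deg)
    dx = xs - center[0]
    dy = ys - center[1]
    dz = zs - center[2]
    prof = np.ones(shape)
    for i in range(3):
        u = (R[0, i] * dx[:, None, None] + R[1, i] * dy[None, :, None]
             + R[2, i] * dz[None, None, :])
        if sigmas[i] > 0:
            s2 = sigmas[i] * np.sqrt(2.0)
            prof *= 0.5 * (erf((u + half_edge) / s2) - erf((u - half_edge) / s2))
        else:
            prof *= (np.abs(u) <= half_edge).astype(float)
    return VoxelVolume(background_hu + (cube_hu - background_hu) * prof,
                       spacing=spacing, origin=origin)
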
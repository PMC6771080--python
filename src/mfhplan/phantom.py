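"""Labelled voxel breast phantoms with per-tissue physical properties.

The phantom is a regular isotropic voxel grid whose labels distinguish
exterior air, a 2 mm skin shell, a muscle slab (chest wall), a subcutaneous
fat layer, breast fat, glandular tissue and an embedded spherical tumour.
Each tissue label carries the electrical and thermal properties needed by the
eddy-current and bioheat solvers: density, electrical conductivity, specific
heat, thermal conductivity, metabolic heat generation rate (HGR) and the
linearised perfusion heat-transfer coefficient (HTR) that multiplies
(T_b - T) in the Pennes equation.  The tumour takes the muscle properties.

The synthetic generator emulates a heterogeneously dense breast: a layered
hemisphere (skin shell, subcutaneous fat, a smooth retroareolar glandular
core grown to a 51-75 % glandular fraction) sitting on a fat layer and a
pectoral muscle disc.  Physical coordinates are voxel-centre based, axis
order (x, y, z), with the chest wall at z = 0 and the breast pointing
towards +z.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Label",
    "TissueProperties",
    "VoxelPhantom",
    "PhantomConfig",
    "builtin_tissue_table",
    "generate_phantom",
    "embed_tumour",
    "save_phantom",
    "load_phantom",
]


class PhantomError(RuntimeError):
    """Phantom generation or tumour placement failed."""


class Label:
    """Integer tissue labels of the voxel grid."""

    EXTERIOR = 0
    SKIN = 1
    MUSCLE = 2
    BREAST_GLAND = 3
    FAT = 4
    BREAST_FAT = 5
    TUMOUR = 6

    NAMES = {
        EXTERIOR: "exterior",
        SKIN: "skin",
        MUSCLE: "muscle",
        BREAST_GLAND: "breast_gland",
        FAT: "fat",
        BREAST_FAT: "breast_fat",
        TUMOUR: "tumour",
    }
    BY_NAME = {v: k for k, v in NAMES.items()}


@dataclass(frozen=True)
class TissueProperties:
    """Physical parameters of one tissue class.

    rho : density (kg/m^3); sigma : electrical conductivity (S/m);
    c : specific heat (J/kg/degC); kappa : thermal conductivity (W/m/degC);
    hgr : metabolic heat generation rate (W/kg); htr : perfusion heat-transfer
    coefficient rho_b*c_b*rho*omega (W/m^3/degC).
    """

    rho: float
    sigma: float
    c: float
    kappa: float
    hgr: float
    htr: float

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.c > 0 and self.kappa > 0):
            raise ValueError("rho, c, kappa must be > 0")
        if self.sigma < 0 or self.hgr < 0 or self.htr < 0:
            raise ValueError("sigma, hgr, htr must be >= 0")


def builtin_tissue_table() -> dict[int, TissueProperties]:
    """Breast tissue property table at 171 kHz (IT'IS-derived).

    The tumour row copies muscle; its perfusion is replaced by the nonlinear
    temperature-dependent model inside the bioheat solver.
    """
    muscle = TissueProperties(1090.4, 0.355, 3421.2, 0.4949, 0.9061, 2705.95)
    return {
        Label.SKIN: TissueProperties(1109.0, 0.17, 3390.5, 0.3722, 1.647, 7969.16),
        Label.MUSCLE: muscle,
        Label.BREAST_GLAND: TissueProperties(1040.5, 0.5412, 2960.0, 0.3345, 2.323, 10542.6),
        Label.FAT: TissueProperties(911.0, 0.057, 2348.3, 0.21145, 0.5, 2012.82),
        Label.BREAST_FAT: TissueProperties(911.0, 0.0222, 2348.33, 0.209, 0.7278, 2892.22),
        Label.TUMOUR: muscle,
    }


@dataclass
class VoxelPhantom:
    """Labelled voxel grid with tissue properties and a tumour mask.

    ``labels`` is an (nx, ny, nz) uint8 array of :class:`Label` codes,
    ``spacing`` the isotropic voxel size in metres, ``properties`` a map from
    label code to :class:`TissueProperties`.  Physical coordinates of voxel
    (i, j, k) are ((i+0.5)h, (j+0.5)h, (k+0.5)h).
    """

    labels: np.ndarray
    spacing: float
    properties: dict[int, TissueProperties]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        present = set(np.unique(self.labels)) - {Label.EXTERIOR}
        missing = present - set(self.properties)
        if missing:
            raise ValueError(f"labels without properties: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def tumour_mask(self) -> np.ndarray:
        return self.labels == Label.TUMOUR

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != Label.EXTERIOR

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-centre coordinate arrays (broadcastable, m)."""
        h = self.spacing
        nx, ny, nz = self.shape
        x = (np.arange(nx) + 0.5) * h
        y = (np.arange(ny) + 0.5) * h
        z = (np.arange(nz) + 0.5) * h
        return x[:, None, None], y[None, :, None], z[None, None, :]

    def property_map(self, attr: str, exterior: float = 0.0) -> np.ndarray:
        """Per-voxel map of one tissue property (``attr`` of TissueProperties)."""
        out = np.full(self.shape, exterior, dtype=float)
        for lab, props in self.properties.items():
            out[self.labels == lab] = getattr(props, attr)
        return out

    def tumour_centre(self) -> np.ndarray:
        """Physical centroid of the tumour mask (m)."""
        mask = self.tumour_mask
        if not mask.any():
            raise PhantomError("phantom has no tumour")
        idx = np.argwhere(mask)
        return (idx.mean(axis=0) + 0.5) * self.spacing

    def glandular_fraction(self) -> float:
        """Glandular fraction of interior breast tissue (gland vs gland+breast fat)."""
        n_gland = int(np.count_nonzero(self.labels == Label.BREAST_GLAND))
        n_bfat = int(np.count_nonzero(self.labels == Label.BREAST_FAT))
        if n_gland + n_bfat == 0:
            raise PhantomError("phantom has no interior breast tissue")
        return n_gland / (n_gland + n_bfat)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry controls of the synthetic breast phantom generator.

    Lengths in metres.  ``gland_band`` is the admissible interval for the
    glandular fraction of interior breast tissue (51-75 % corresponds to a
    heterogeneously dense breast).
    """

    grid: int = 96
    spacing: float = 1.5e-3
    breast_radius: float = 50.0e-3
    skin_thickness: float = 2.0e-3
    muscle_thickness: float = 12.0e-3
    fat_thickness: float = 5.0e-3
    #: lateral radius of the pectoral muscle disc behind the breast; the rest
    #: of the chest slab is subcutaneous/torso fat
    muscle_radius: float = 50.0e-3
    #: subcutaneous fat margin between glandular tissue and the skin shell
    gland_margin: float = 8.0e-3
    gland_band: tuple[float, float] = (0.51, 0.75)
    #: semi-axis range of the glandular core blobs
    blob_radius_range: tuple[float, float] = (15.0e-3, 25.0e-3)
    #: lateral / axial spread of blob centres around the retroareolar axis
    gland_lateral_spread: float = 6.0e-3
    gland_axial_spread: float = 14.0e-3
    #: morphological closing+opening radius (m) applied to the gland mask;
    #: removes voxel-scale necks and spurs that would act as artificial
    #: eddy-current crowding sites (0 disables)
    gland_smooth_radius: float = 4.5e-3
    max_blobs: int = 2000

    def __post_init__(self) -> None:
        if self.grid < 32:
            raise ValueError("grid must be >= 32 voxels per side")
        lo, hi = self.gland_band
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid gland_band {self.gland_band!r}")


def generate_phantom(
    config: PhantomConfig = PhantomConfig(),
    seed: int = 0,
    properties: dict[int, TissueProperties] | None = None,
) -> VoxelPhantom:
    """Generate a layered hemispherical breast phantom.

    Pectoral muscle disc and fat slab at the bottom, fat layer, hemispherical
    breast with a closed skin shell; inside, a smooth retroareolar
    fibroglandular core grown from overlapping ellipsoidal blobs (keeping a
    subcutaneous fat margin below the skin) until the glandular fraction of
    interior breast tissue falls inside ``config.gland_band``.  Deterministic
    for a fixed seed.

    Raises
    ------
    PhantomError
        If the glandular band cannot be reached at the given resolution.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    props = builtin_tissue_table() if properties is None else properties
    n = cfg.grid
    h = cfg.spacing
    labels = np.zeros((n, n, n), dtype=np.uint8)

    x = (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    extent = n * h
    cx = cy = extent / 2.0
    z_base = cfg.muscle_thickness + cfg.fat_thickness

    body = Z < z_base  # slab spans the full lateral extent
    r_breast = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - z_base) ** 2)
    hemisphere = (Z >= z_base) & (r_breast <= cfg.breast_radius)
    body |= hemisphere

    # closed skin shell: body voxels whose centre lies within skin_thickness
    # of the body surface (voxel-centre distance minus half a voxel), except
    # on the bottom (chest-wall) face of the grid; at least one voxel thick
    dist = ndimage.distance_transform_edt(body, sampling=h)
    skin = body & (dist <= max(cfg.skin_thickness + h / 2.0, h))
    skin[:, :, 0] = False

    # pectoral muscle only behind the breast; the lateral chest slab is fat
    rho_xy = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    slab = body & (Z < cfg.muscle_thickness)
    labels[slab] = Label.FAT
    labels[slab & (rho_xy <= cfg.muscle_radius)] = Label.MUSCLE
    labels[body & (Z >= cfg.muscle_thickness) & (Z < z_base)] = Label.FAT
    labels[hemisphere] = Label.BREAST_FAT
    labels[skin] = Label.SKIN

    interior = labels == Label.BREAST_FAT
    n_interior = int(np.count_nonzero(interior))
    if n_interior == 0:
        raise PhantomError("no interior breast tissue: grid too coarse for geometry")
    # glandular tissue keeps a subcutaneous fat margin below the skin shell
    allowed = interior & (r_breast <= cfg.breast_radius - cfg.skin_thickness - cfg.gland_margin)

    lo, hi = cfg.gland_band
    gland = np.zeros_like(interior)
    n_allowed = int(np.count_nonzero(allowed))
    if lo >= 1.0:
        # degenerate band: the whole interior is glandular, margin included
        gland[:] = interior
        frac = 1.0
    elif lo > 0 and n_allowed / n_interior < lo:
        raise PhantomError(
            f"glandular band lower edge {lo} exceeds the attainable fraction "
            f"{n_allowed / n_interior:.3f} under the {cfg.gland_margin * 1e3:.0f} mm "
            "subcutaneous margin"
        )
    else:
        # retroareolar fibroglandular core: large, deeply overlapping blobs
        # around the breast axis.  The mask is morphologically smoothed
        # (closing then opening) so the gland-fat boundary carries no
        # voxel-scale necks or spurs, which would act as artificial
        # eddy-current crowding sites that a body-fitted mesh would not have.
        smooth_iters = int(round(cfg.gland_smooth_radius / h))
        if smooth_iters > 0:
            struct = ndimage.iterate_structure(
                ndimage.generate_binary_structure(3, 1), smooth_iters
            )
        else:
            struct = None

        def smoothed(mask: np.ndarray) -> np.ndarray:
            if struct is None:
                return mask
            return ndimage.binary_opening(ndimage.binary_closing(mask, struct), struct) & allowed

        frac = 0.0
        gland_s = gland
        for i in range(cfg.max_blobs):
            if frac >= lo:
                break
            centre = np.array([cx, cy, z_base]) + np.array([
                rng.normal(0.0, cfg.gland_lateral_spread),
                rng.normal(0.0, cfg.gland_lateral_spread),
                abs(rng.normal(0.0, cfg.gland_axial_spread)),
            ])
            semi = rng.uniform(*cfg.blob_radius_range, size=3)
            i0 = np.maximum(((centre - semi) / h - 0.5).astype(int), 0)
            i1 = np.minimum(((centre + semi) / h + 1.5).astype(int), n)
            if np.any(i0 >= i1):
                continue
            sl = tuple(slice(a, b) for a, b in zip(i0, i1))
            blob = (((X[sl] - centre[0]) / semi[0]) ** 2
                    + ((Y[sl] - centre[1]) / semi[1]) ** 2
                    + ((Z[sl] - centre[2]) / semi[2]) ** 2) <= 1.0
            gland[sl] |= blob & allowed[sl]
            if i % 5 == 4 or np.count_nonzero(gland) / n_interior >= lo:
                gland_s = smoothed(gland)
                frac = np.count_nonzero(gland_s) / n_interior
        gland = smoothed(gland)
        frac = np.count_nonzero(gland) / n_interior
    if frac < lo or frac > hi:
        raise PhantomError(
            f"glandular fraction {frac:.3f} outside band [{lo}, {hi}] "
            f"after blob growth at {h * 1e3:.2f} mm resolution"
        )
    labels[gland] = Label.BREAST_GLAND

    meta = {"seed": int(seed), "generator": "layered-hemisphere", "gland_fraction": float(frac)}
    return VoxelPhantom(labels=labels, spacing=h, properties=props, meta=meta)


def embed_tumour(
    phantom: VoxelPhantom,
    centre: np.ndarray | tuple[float, float, float],
    volume: float,
) -> VoxelPhantom:
    """Relabel a sphere of the given volume (m^3) centred at ``centre`` (m) as tumour.

    The sphere radius is (3V/4pi)^(1/3); a voxel belongs to the tumour when
    its centre lies within the radius.  The sphere must fit entirely inside
    breast tissue (breast fat, gland, fat or existing tumour).

    Raises
    ------
    PhantomError
        If the sphere intersects exterior, skin or muscle.
    """
    if volume <= 0:
        raise ValueError("tumour volume must be > 0")
    centre = np.asarray(centre, dtype=float)
    radius = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    X, Y, Z = phantom.voxel_centres()
    inside = ((X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (Z - centre[2]) ** 2) <= radius**2
    if not inside.any():
        raise PhantomError("tumour sphere does not cover any voxel centre")
    allowed = {Label.BREAST_FAT, Label.BREAST_GLAND, Label.FAT, Label.TUMOUR}
    hit = set(np.unique(phantom.labels[inside]))
    if not hit <= allowed:
        bad = ", ".join(Label.NAMES[l] for l in sorted(hit - allowed))
        raise PhantomError(f"tumour sphere intersects {bad}: placement invalid")
    labels = phantom.labels.copy()
    labels[inside] = Label.TUMOUR
    props = dict(phantom.properties)
    props.setdefault(Label.TUMOUR, builtin_tissue_table()[Label.TUMOUR])
    meta = dict(phantom.meta)
    meta["tumour_centre_m"] = [float(v) for v in centre]
    meta["tumour_volume_m3"] = float(volume)
    return VoxelPhantom(labels=labels, spacing=phantom.spacing, properties=props, meta=meta)


def skin_is_closed(phantom: VoxelPhantom) -> bool:
    """Flood-fill check that no interior tissue touches exterior except through skin.

    Grows the exterior region by one 6-connected step; the dilation must only
    reach skin (or stay exterior).  The bottom grid face is the clamped chest
    wall and is excluded.
    """
    ext = phantom.labels == Label.EXTERIOR
    struct = ndimage.generate_binary_structure(3, 1)
    touched = ndimage.binary_dilation(ext, structure=struct) & ~ext
    touched[:, :, 0] = False
    reached = set(np.unique(phantom.labels[touched]))
    return reached <= {Label.SKIN, Label.EXTERIOR}


def save_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write the phantom as NIfTI labels plus a JSON property sidecar.

    ``path`` should end in ``.nii`` or ``.nii.gz``; the sidecar is written
    next to it with suffix ``.json``.
    """
    path = Path(path)
    affine = np.diag([phantom.spacing * 1e3] * 3 + [1.0])  # NIfTI convention: mm
    img = nib.Nifti1Image(phantom.labels.astype(np.uint8), affine)
    nib.save(img, str(path))
    sidecar = {
        "spacing_m": phantom.spacing,
        "labels": {str(k): Label.NAMES[k] for k in Label.NAMES},
        "properties": {str(k): asdict(v) for k, v in phantom.properties.items()},
        "meta": phantom.meta,
    }
    sidecar_path = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar_path = sidecar_path.parent / (sidecar_path.name + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))


def load_phantom(path: str | Path) -> VoxelPhantom:
    """Read a phantom written by :func:`save_phantom`."""
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj, dtype=np.uint8)
    stem = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar_path = stem.parent / (stem.name + ".json")
    sidecar = json.loads(sidecar_path.read_text())
    props = {int(k): TissueProperties(**v) for k, v in sidecar["properties"].items()}
    return VoxelPhantom(
        labels=labels,
        spacing=float(sidecar["spacing_m"]),
        properties=props,
        meta=sidecar.get("meta", {}),
    )
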
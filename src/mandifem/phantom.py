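"""Synthetic mandible micro-CT phantom with ground-truth tissue labels.

The phantom is a simplified parametric full mandible (two hemimandibles
joined at a symphysis): per side a corpus beam, an ascending ramus with
condylar, coronoid and angular processes, one continuously-growing curved
incisor (enamel shell, dentin, pulp, mesenchymal growing end) and a
three-molar row (enamel cap, dentin, pulp), every tooth wrapped in a
periodontal-ligament shell seated in alveolar bone, all embedded in
cortical bone.

Coordinate convention (mm throughout): x is anteroposterior (+x anterior,
toward the incisor tips), y is mediolateral, z is superoinferior
(+z dorsal).  Voxel ``[i, j, k]`` is centred at
``origin + (index + 0.5) * spacing``; mesh nodes produced downstream sit
on the voxel-corner lattice ``origin + index * spacing``.

Grayscale is produced by mapping each tissue label to its mean intensity,
applying a Gaussian partial-volume blur and adding Gaussian scanner noise;
both are controlled by spec parameters and fully determined by the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

# Tissue label codes.
BACKGROUND = 0
CORTICAL = 1
ALVEOLAR = 2
ENAMEL = 3
DENTIN = 4
PULP = 5
MESENCHYME = 6
PDL = 7

TISSUES = (BACKGROUND, CORTICAL, ALVEOLAR, ENAMEL, DENTIN, PULP, MESENCHYME, PDL)

TISSUE_NAMES: Dict[int, str] = {
    BACKGROUND: "background",
    CORTICAL: "cortical_bone",
    ALVEOLAR: "alveolar_bone",
    ENAMEL: "enamel",
    DENTIN: "dentin",
    PULP: "pulp",
    MESENCHYME: "mesenchyme",
    PDL: "periodontal_ligament",
}

#: Tissue codes ordered by increasing X-ray attenuation (grayscale).
#: Enamel is the brightest hard tissue, pulp the darkest soft tissue.
INTENSITY_ORDER = (BACKGROUND, PULP, MESENCHYME, PDL, ALVEOLAR, CORTICAL, DENTIN, ENAMEL)


def default_intensity_means() -> Dict[int, float]:
    """Equally spaced grayscale means in [0, 255], darkest to brightest
    following :data:`INTENSITY_ORDER`."""
    levels = np.linspace(0.0, 255.0, len(INTENSITY_ORDER))
    return {code: float(v) for code, v in zip(INTENSITY_ORDER, levels)}


@dataclass(frozen=True)
class MandibleGeometry:
    """Parametric dimensions of the phantom mandible (mm).

    Ranges are ``(lo, hi)`` intervals along the named axis; ``hemi_offset``
    is the distance of each hemimandible midplane from the sagittal
    midline.  Defaults describe an adult-mouse-like mandible scaled to a
    15 x 8 x 6 mm bounding box.
    """

    # corpus beam per side
    corpus_x: Tuple[float, float] = (3.0, 14.0)
    corpus_z: Tuple[float, float] = (1.2, 3.6)
    hemi_offset: float = 1.8
    hemi_half_width: float = 1.0
    # symphysis joining the two hemimandibles anteriorly
    symphysis_x: Tuple[float, float] = (12.0, 14.5)
    symphysis_half_width: float = 1.2
    symphysis_z: Tuple[float, float] = (1.5, 3.2)
    # ascending ramus plate
    ramus_x: Tuple[float, float] = (0.8, 3.6)
    ramus_z: Tuple[float, float] = (1.2, 5.0)
    ramus_half_width: float = 0.55
    # condylar process (ellipsoid; articulates with the TMJ disc)
    condyle_center: Tuple[float, float] = (1.3, 4.9)  # (x, z)
    condyle_semiaxes: Tuple[float, float, float] = (0.5, 0.7, 0.5)  # (x, y, z)
    # coronoid process (temporalis insertion)
    coronoid_x: Tuple[float, float] = (2.9, 3.5)
    coronoid_z: Tuple[float, float] = (4.3, 5.2)
    coronoid_half_width: float = 0.35
    # angular process (pterygoid / masseter insertions)
    angular_x: Tuple[float, float] = (0.6, 1.8)
    angular_z: Tuple[float, float] = (0.4, 1.3)
    angular_half_width: float = 0.6
    # incisor: circular arc in the sagittal plane of each hemimandible
    incisor_tip: Tuple[float, float] = (14.4, 3.8)  # (x, z), erupted end
    incisor_root: Tuple[float, float] = (6.0, 2.2)  # (x, z), growing end
    incisor_sagitta: float = 1.1  # ventral bulge of the arc below the chord
    incisor_radius: float = 0.45
    enamel_thickness: float = 0.12
    pulp_radius: float = 0.2
    mesenchyme_fraction: float = 0.2  # arc fraction at the growing end
    # molar row: vertical cylinders per side
    molar_x: Tuple[float, ...] = (6.5, 7.8, 9.1)
    molar_radius: float = 0.35
    molar_root_z: float = 2.7
    molar_crown_z: float = 4.35
    # shells
    pdl_thickness: float = 0.2
    alveolar_thickness: float = 0.3


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic scan; the seed fixes the output."""

    bounding_box: Tuple[float, float, float] = (15.0, 8.0, 6.0)
    voxel_size: float = 0.1
    geometry: MandibleGeometry = field(default_factory=MandibleGeometry)
    intensity_means: Dict[int, float] = field(default_factory=default_intensity_means)
    noise_sigma: float = 6.0
    blur_sigma: float = 0.02
    seed: int = 20170509

    def grid_shape(self) -> Tuple[int, int, int]:
        return tuple(int(round(b / self.voxel_size)) for b in self.bounding_box)

    def validate(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(b <= 0 for b in self.bounding_box):
            raise ValueError("bounding_box extents must be positive")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sigma and blur_sigma must be non-negative")
        means = [self.intensity_means[c] for c in TISSUES]
        if len(set(means)) != len(means):
            raise ValueError("intensity_means must be distinct across tissue classes")
        if self.geometry.pdl_thickness < self.voxel_size:
            raise ValueError(
                "pdl_thickness (%g mm) is below one voxel (%g mm); the periodontal "
                "ligament would not be resolved -- increase pdl_thickness or refine "
                "voxel_size" % (self.geometry.pdl_thickness, self.voxel_size)
            )

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class VoxelVolume:
    """Grayscale scalar grid with physical placement metadata."""

    origin: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on every axis")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 3D grid")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self):
        """Per-axis 1D arrays of voxel-centre coordinates."""
        return tuple(
            self.origin[a] + (np.arange(self.values.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )


@dataclass(frozen=True)
class LabelVolume:
    """Per-voxel tissue codes, same geometry as its paired grayscale volume."""

    origin: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    labels: np.ndarray

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on every axis")
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        present = np.unique(self.labels)
        if not np.isin(present, TISSUES).all():
            raise ValueError("labels contain codes outside the declared tissue set")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self):
        return tuple(
            self.origin[a] + (np.arange(self.labels.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )


def _arc_params(tip, root, sagitta):
    """Circle through ``tip`` and ``root`` (x-z plane) bulging ventrally by
    ``sagitta`` below the chord.  Returns (center, radius, theta_root, theta_tip).
    """
    p0 = np.asarray(root, float)
    p1 = np.asarray(tip, float)
    chord = p1 - p0
    L = float(np.hypot(*chord))
    s = float(sagitta)
    if s <= 0 or s >= L:
        raise ValueError("incisor_sagitta must be in (0, chord length)")
    d = (L * L / 4.0 - s * s) / (2.0 * s)  # center-to-chord distance
    R = d + s
    mid = 0.5 * (p0 + p1)
    # normal to the chord with positive z so the arc sags ventrally
    n = np.array([-chord[1], chord[0]]) / L
    if n[1] < 0:
        n = -n
    center = mid + d * n
    th0 = float(np.arctan2(p0[1] - center[1], p0[0] - center[0]))
    th1 = float(np.arctan2(p1[1] - center[1], p1[0] - center[0]))
    return center, R, th0, th1


def incisor_axis_distance(geom: MandibleGeometry, x, ay, z):
    """Distance of points to the incisor arc axis, and normalized arc
    parameter (0 at the growing end, 1 at the tip).

    ``ay`` is the absolute mediolateral offset from the sagittal midline;
    the arc lives in the hemimandible midplane at ``geom.hemi_offset``.
    Points beyond the arc's angular span measure distance to the nearer
    endpoint (rounded tooth ends).
    """
    center, R, th_root, th_tip = _arc_params(
        geom.incisor_tip, geom.incisor_root, geom.incisor_sagitta
    )
    dy = np.abs(ay - geom.hemi_offset)
    dx = x - center[0]
    dz = z - center[1]
    rho = np.hypot(dx, dz)
    theta = np.arctan2(dz, dx)
    lo, hi = min(th_root, th_tip), max(th_root, th_tip)
    inside = (theta >= lo) & (theta <= hi)
    d_arc = np.hypot(rho - R, dy)
    # endpoint caps
    ex0 = center[0] + R * np.cos(th_root)
    ez0 = center[1] + R * np.sin(th_root)
    ex1 = center[0] + R * np.cos(th_tip)
    ez1 = center[1] + R * np.sin(th_tip)
    d_root = np.sqrt((x - ex0) ** 2 + (z - ez0) ** 2 + dy**2)
    d_tip = np.sqrt((x - ex1) ** 2 + (z - ez1) ** 2 + dy**2)
    dist = np.where(inside, d_arc, np.minimum(d_root, d_tip))
    tfrac = np.clip((theta - th_root) / (th_tip - th_root), 0.0, 1.0)
    tfrac = np.where(inside, tfrac, np.where(d_tip < d_root, 1.0, 0.0))
    return dist, tfrac


def _box(u, lo, hi):
    return (u >= lo) & (u <= hi)


def _build_labels(spec: PhantomSpec) -> np.ndarray:
    g = spec.geometry
    nx, ny, nz = spec.grid_shape()
    h = spec.voxel_size
    x = (np.arange(nx) + 0.5)[:, None, None] * h
    y = (np.arange(ny) + 0.5)[None, :, None] * h
    z = (np.arange(nz) + 0.5)[None, None, :] * h
    midline = spec.bounding_box[1] / 2.0
    ay = np.abs(y - midline)  # mediolateral offset from the midline
    dhemi = np.abs(ay - g.hemi_offset)

    corpus = _box(x, *g.corpus_x) & _box(z, *g.corpus_z) & (dhemi <= g.hemi_half_width)
    symphysis = (
        _box(x, *g.symphysis_x)
        & (ay <= g.symphysis_half_width)
        & _box(z, *g.symphysis_z)
    )
    ramus = _box(x, *g.ramus_x) & _box(z, *g.ramus_z) & (dhemi <= g.ramus_half_width)
    cx, cz = g.condyle_center
    sa, sb, sc = g.condyle_semiaxes
    condyle = ((x - cx) / sa) ** 2 + (dhemi / sb) ** 2 + ((z - cz) / sc) ** 2 <= 1.0
    coronoid = (
        _box(x, *g.coronoid_x) & _box(z, *g.coronoid_z) & (dhemi <= g.coronoid_half_width)
    )
    angular = (
        _box(x, *g.angular_x) & _box(z, *g.angular_z) & (dhemi <= g.angular_half_width)
    )
    bone = corpus | symphysis | ramus | condyle | coronoid | angular

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[bone] = CORTICAL

    r_inc, tfrac = incisor_axis_distance(g, x, ay, z)
    r_i = g.incisor_radius
    t_pdl = g.pdl_thickness
    t_alv = g.alveolar_thickness

    corpus_top = g.corpus_z[1]
    molar_r = {}
    for mx in g.molar_x:
        molar_r[mx] = np.hypot(x - mx, dhemi)

    # alveolar shells (only inside bone)
    labels[(r_inc <= r_i + t_pdl + t_alv) & bone] = ALVEOLAR
    for mx in g.molar_x:
        zone = _box(z, g.molar_root_z - t_pdl - t_alv, corpus_top)
        labels[(molar_r[mx] <= g.molar_radius + t_pdl + t_alv) & zone & bone] = ALVEOLAR

    # periodontal ligament shells (only inside bone)
    labels[(r_inc <= r_i + t_pdl) & bone] = PDL
    for mx in g.molar_x:
        zone = _box(z, g.molar_root_z - t_pdl, corpus_top)
        labels[(molar_r[mx] <= g.molar_radius + t_pdl) & zone & bone] = PDL

    # incisor tissues (enamel shell, dentin, pulp; mesenchyme at growing end)
    labels[r_inc <= r_i] = ENAMEL
    interior = r_inc <= r_i - g.enamel_thickness
    labels[interior] = DENTIN
    labels[(r_inc <= g.pulp_radius) & (tfrac > g.mesenchyme_fraction)] = PULP
    labels[interior & (tfrac <= g.mesenchyme_fraction)] = MESENCHYME

    # molar tissues (enamel cap, dentin body, pulp core)
    for mx in g.molar_x:
        r = molar_r[mx]
        crown = _box(z, corpus_top, g.molar_crown_z)
        root = _box(z, g.molar_root_z, corpus_top)
        labels[(r <= g.molar_radius) & crown] = ENAMEL
        labels[(r <= g.molar_radius) & root] = DENTIN
        labels[
            (r <= g.molar_radius - g.enamel_thickness)
            & _box(z, corpus_top, g.molar_crown_z - g.enamel_thickness)
        ] = DENTIN
        labels[
            (r <= g.pulp_radius)
            & _box(z, g.molar_root_z + 0.15, g.molar_crown_z - 0.3)
        ] = PULP

    return labels


def generate_phantom(spec: PhantomSpec) -> Tuple[VoxelVolume, LabelVolume]:
    """Render a synthetic scan: ground-truth labels plus a grayscale
    volume (tissue mean intensity, Gaussian partial-volume blur of
    ``blur_sigma`` mm, additive Gaussian noise of ``noise_sigma``).

    Deterministic: the same spec (including seed) yields bit-identical
    output; a different seed changes only the noise, not the labels.
    """
    spec.validate()
    labels = _build_labels(spec)

    lut = np.zeros(max(TISSUES) + 1, dtype=np.float64)
    for code in TISSUES:
        lut[code] = spec.intensity_means[code]
    gray = lut[labels]

    if spec.blur_sigma > 0:
        gray = gaussian_filter(gray, sigma=spec.blur_sigma / spec.voxel_size)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        gray = gray + rng.normal(0.0, spec.noise_sigma, size=gray.shape)

    origin = (0.0, 0.0, 0.0)
    spacing = (spec.voxel_size,) * 3
    return (
        VoxelVolume(origin, spacing, gray),
        LabelVolume(origin, spacing, labels),
    )
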
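"""Biomechanical model: materials, masticatory scenarios, muscle-force
allocation, attachment/bite regions and temporomandibular-joint (TMJ)
constraints.

Unit system is mm-N-MPa throughout; the literature elastic moduli are
given in GPa and converted at load time.

Scenario loads are total bilateral bite loads.  Gnawing applies a purely
vertical (superoinferior, -z) bite reaction at the incisor tips; chewing
applies an inclined reaction with equal anteroposterior and
superoinferior components at the molar occlusal surfaces.  The reaction
is distributed equally over the loaded surface nodes of both sides.

Closing muscle forces act opposite the bite reaction (+z, and +x for
the anteroposterior stabilizers) at their anatomical attachment regions
with the published allocation fractions: the vertical fractions sum to
0.88 and the anteroposterior fractions to 1.00; global equilibrium
closes through the TMJ constraint reactions rather than renormalizing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from mandifem.meshing import EmptySelectionError, TetMesh
from mandifem.phantom import (
    ALVEOLAR,
    CORTICAL,
    DENTIN,
    ENAMEL,
    MESENCHYME,
    MandibleGeometry,
    PDL,
    PULP,
    TISSUE_NAMES,
)


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic constants: Young's modulus E (MPa) and
    Poisson ratio nu."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


@dataclass(frozen=True)
class TissueTable:
    """Tissue code -> Material, complete over the seven tissues."""

    materials: Dict[int, Material]

    def __post_init__(self):
        required = {CORTICAL, ALVEOLAR, ENAMEL, DENTIN, PULP, MESENCHYME, PDL}
        missing = required - set(self.materials)
        if missing:
            names = ", ".join(TISSUE_NAMES[c] for c in sorted(missing))
            raise ValueError(f"TissueTable missing materials for: {names}")

    def __getitem__(self, code: int) -> Material:
        return self.materials[code]

    def replace(self, code: int, material: Material) -> "TissueTable":
        mats = dict(self.materials)
        mats[code] = material
        return TissueTable(mats)


#: Literature elastic constants (E in GPa as published, Poisson ratio).
MATERIALS_GPA: Dict[int, Tuple[float, float]] = {
    CORTICAL: (19.92, 0.30),
    ALVEOLAR: (0.345, 0.38),
    ENAMEL: (84.1, 0.33),
    DENTIN: (18.6, 0.31),
    PULP: (0.002, 0.45),
    MESENCHYME: (0.1, 0.37),
    PDL: (0.05, 0.45),
}


def default_materials() -> TissueTable:
    """Published tissue constants converted to the mm-N-MPa system
    (GPa x 1000)."""
    return TissueTable(
        {code: Material(E=e_gpa * 1000.0, nu=nu) for code, (e_gpa, nu) in MATERIALS_GPA.items()}
    )


class Biting(str, enum.Enum):
    GNAWING = "gnawing"
    CHEWING = "chewing"


class Food(str, enum.Enum):
    SOFT = "soft"
    HARD = "hard"


@dataclass(frozen=True)
class Scenario:
    """One masticatory loading case: biting mode, food type and the total
    bilateral bite-load components (N)."""

    biting: Biting
    food: Food
    Fz: float  # superoinferior component
    Fx: float  # anteroposterior component

    def __post_init__(self):
        if self.Fz < 0 or self.Fx < 0:
            raise ValueError("load components must be non-negative")
        if self.biting is Biting.GNAWING and self.Fx != 0:
            raise ValueError("gnawing is purely vertical: Fx must be 0")

    @property
    def name(self) -> str:
        return f"{self.biting.value}_{self.food.value}"


#: Published bite loads (N) per (biting, food): (Fz, Fx).
SCENARIO_LOADS: Dict[Tuple[Biting, Food], Tuple[float, float]] = {
    (Biting.GNAWING, Food.SOFT): (0.84, 0.0),
    (Biting.GNAWING, Food.HARD): (2.5, 0.0),
    (Biting.CHEWING, Food.SOFT): (0.42, 0.42),
    (Biting.CHEWING, Food.HARD): (1.26, 1.26),
}


def scenario_loads(biting: Biting | str, food: Food | str) -> Scenario:
    """Look up the published bite-load components for a scenario."""
    biting = Biting(biting)
    food = Food(food)
    fz, fx = SCENARIO_LOADS[(biting, food)]
    return Scenario(biting, food, Fz=fz, Fx=fx)


def all_scenarios() -> List[Scenario]:
    return [scenario_loads(b, f) for b in Biting for f in Food]


@dataclass(frozen=True)
class MuscleSpec:
    """One masticatory muscle: its share of the vertical closing force
    (fz_fraction) and of the anteroposterior stabilization (fx_fraction),
    and the named attachment region on the mandible surface."""

    name: str
    fz_fraction: float
    fx_fraction: float
    attachment: str

    def __post_init__(self):
        if not 0 <= self.fz_fraction <= 1 or not 0 <= self.fx_fraction <= 1:
            raise ValueError(f"muscle {self.name}: fractions must lie in [0, 1]")


def default_muscles() -> List[MuscleSpec]:
    """The six rodent masticatory muscles with the published force shares.

    The vertical shares sum to 0.88 as published (no renormalization);
    the anteroposterior shares sum to 1.00.  The duplicated published
    muscle entry inserting on the ventral angular process is carried as
    the superficial masseter (pars reflexa).  External pterygoid and the
    posterior medial masseter do not contribute during biting.
    """
    return [
        MuscleSpec("internal_pterygoid", 0.23, 0.00, "angular_process_medial"),
        MuscleSpec("masseter_zygomaticomandibularis", 0.24, 0.30, "masseteric_fossa"),
        MuscleSpec("superficial_masseter_reflexa", 0.36, 0.30, "angular_process_ventral"),
        MuscleSpec("temporalis", 0.05, 0.40, "coronoid_to_last_molar"),
        MuscleSpec("external_pterygoid", 0.00, 0.00, "condyle_articular"),
        MuscleSpec("medial_masseter_posterior", 0.00, 0.00, "masseteric_fossa"),
    ]


def allocate_muscle_forces(
    scenario: Scenario, muscles: Sequence[MuscleSpec] | None = None
) -> Dict[str, np.ndarray]:
    """Per-muscle total force vector (N): muscle i carries
    ``(fx_fraction_i * Fx, 0, fz_fraction_i * Fz)``, the closing direction
    (+z) opposite to the bite reaction."""
    if muscles is None:
        muscles = default_muscles()
    return {
        m.name: np.array([m.fx_fraction * scenario.Fx, 0.0, m.fz_fraction * scenario.Fz])
        for m in muscles
    }


REGION_NAMES = (
    "incisor_tips",
    "molar_occlusal",
    "angular_process_medial",
    "masseteric_fossa",
    "angular_process_ventral",
    "coronoid_to_last_molar",
    "condyle_articular",
)

Box = Tuple[Tuple[float, float], Tuple[float, float], Tuple[float, float]]


def region_boxes(
    geom: MandibleGeometry, midline: float
) -> Dict[str, List[Box]]:
    """Axis-aligned boxes (mm) realizing the named anatomical regions on
    the phantom, mirrored across the sagittal midline."""
    g = geom
    pad = 0.15

    def mirrored(xr, ar, zr) -> List[Box]:
        """ar is the |y - midline| interval; emit one box per side."""
        lo, hi = ar
        return [
            (xr, (midline + lo, midline + hi), zr),
            (xr, (midline - hi, midline - lo), zr),
        ]

    hemi = (g.hemi_offset - g.hemi_half_width, g.hemi_offset + g.hemi_half_width)
    tip_x, tip_z = g.incisor_tip
    boxes: Dict[str, List[Box]] = {
        "incisor_tips": mirrored(
            (tip_x - 0.6, tip_x + g.incisor_radius + pad),
            (g.hemi_offset - g.incisor_radius - pad, g.hemi_offset + g.incisor_radius + pad),
            (tip_z - g.incisor_radius - pad, tip_z + g.incisor_radius + pad),
        ),
        "molar_occlusal": mirrored(
            (g.molar_x[0] - g.molar_radius - pad, g.molar_x[-1] + g.molar_radius + pad),
            (g.hemi_offset - g.molar_radius - pad, g.hemi_offset + g.molar_radius + pad),
            (g.molar_crown_z - 0.3, g.molar_crown_z + pad),
        ),
        # medial face of the angular process (internal pterygoid insertion)
        "angular_process_medial": mirrored(
            (g.angular_x[0] - pad, g.angular_x[1] + pad),
            (g.hemi_offset - g.angular_half_width - pad, g.hemi_offset - 0.2),
            (g.angular_z[0] - pad, g.angular_z[1] + 0.4),
        ),
        # lateral mid-ramus surface (zygomaticomandibular masseter)
        "masseteric_fossa": mirrored(
            (g.ramus_x[0], g.ramus_x[1] + pad),
            (g.hemi_offset + 0.2, g.hemi_offset + g.hemi_half_width + pad),
            (1.6, 3.8),
        ),
        # ventral margin of the angular process (superficial masseter)
        "angular_process_ventral": mirrored(
            (g.angular_x[0] - pad, g.angular_x[1] + pad),
            (g.hemi_offset - g.angular_half_width - pad, g.hemi_offset + g.angular_half_width + pad),
            (0.0, g.angular_z[0] + 0.3),
        ),
        # anterior ramus border, coronoid down to the last molar (temporalis)
        "coronoid_to_last_molar": mirrored(
            (g.coronoid_x[0] - pad, g.molar_x[-1] - g.molar_radius),
            (g.hemi_offset - g.coronoid_half_width - pad, g.hemi_offset + g.coronoid_half_width + pad),
            (g.corpus_z[1] + 0.2, g.coronoid_z[1] + pad),
        ),
        # dorsal condylar surface contacting the TMJ disc
        "condyle_articular": mirrored(
            (g.condyle_center[0] - g.condyle_semiaxes[0] - pad,
             g.condyle_center[0] + g.condyle_semiaxes[0] + pad),
            (g.hemi_offset - g.condyle_semiaxes[1] - pad,
             g.hemi_offset + g.condyle_semiaxes[1] + pad),
            (g.condyle_center[1] + 0.5 * g.condyle_semiaxes[2], g.condyle_center[1] + g.condyle_semiaxes[2] + pad),
        ),
    }
    return boxes


def _in_boxes(points: np.ndarray, boxes: Iterable[Box]) -> np.ndarray:
    sel = np.zeros(len(points), bool)
    for (xr, yr, zr) in boxes:
        sel |= (
            (points[:, 0] >= xr[0]) & (points[:, 0] <= xr[1])
            & (points[:, 1] >= yr[0]) & (points[:, 1] <= yr[1])
            & (points[:, 2] >= zr[0]) & (points[:, 2] <= zr[1])
        )
    return sel


def select_region_nodes(
    mesh: TetMesh,
    region: str,
    geom: MandibleGeometry | None = None,
    midline: float | None = None,
    boxes: Sequence[Box] | None = None,
) -> np.ndarray:
    """Surface nodes of the mesh inside a named anatomical region.

    Regions are side-symmetric axis-aligned boxes in phantom coordinates;
    custom ``boxes`` may be supplied directly.  Raises
    :class:`EmptySelectionError` naming the region and mesh bounds when
    nothing matches.
    """
    if boxes is None:
        if region not in REGION_NAMES:
            raise KeyError(f"unknown region {region!r}; expected one of {REGION_NAMES}")
        geom = geom if geom is not None else MandibleGeometry()
        if midline is None:
            midline = float(mesh.nodes[:, 1].min() + mesh.nodes[:, 1].max()) / 2.0
        boxes = region_boxes(geom, midline)[region]
    surf = mesh.surface_node_ids()
    pts = mesh.nodes[surf]
    sel = _in_boxes(pts, boxes)
    if not sel.any():
        lo = mesh.nodes.min(axis=0)
        hi = mesh.nodes.max(axis=0)
        raise EmptySelectionError(
            f"region {region!r} selected no surface nodes; mesh bounds "
            f"x[{lo[0]:.2f},{hi[0]:.2f}] y[{lo[1]:.2f},{hi[1]:.2f}] z[{lo[2]:.2f},{hi[2]:.2f}]"
        )
    return surf[sel]


@dataclass
class NodalLoadSet:
    """Concentrated nodal forces (N)."""

    node_ids: np.ndarray  # (k,)
    forces: np.ndarray  # (k, 3)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, np.int64)
        self.forces = np.asarray(self.forces, float)
        if self.forces.shape != (len(self.node_ids), 3):
            raise ValueError("forces must be (k, 3) matching node_ids")
        if not np.isfinite(self.forces).all():
            raise ValueError("forces must be finite")

    def total(self) -> np.ndarray:
        return self.forces.sum(axis=0)

    @staticmethod
    def combine(parts: Iterable["NodalLoadSet"]) -> "NodalLoadSet":
        ids = np.concatenate([p.node_ids for p in parts])
        forces = np.concatenate([p.forces for p in parts])
        return NodalLoadSet(ids, forces)


def distribute_load(node_ids: np.ndarray, total: np.ndarray) -> NodalLoadSet:
    """Split a total force vector equally over a node set; the nodal sum
    reproduces the total to machine precision."""
    node_ids = np.asarray(node_ids, np.int64)
    if len(node_ids) == 0:
        raise EmptySelectionError("cannot distribute a load over an empty node set")
    total = np.asarray(total, float)
    per = np.tile(total / len(node_ids), (len(node_ids), 1))
    return NodalLoadSet(node_ids, per)


def bite_direction(biting: Biting | str, food: Food | str = Food.HARD) -> np.ndarray:
    """Unit vector of the bite force: gnawing is purely vertical; chewing
    follows the published equal anteroposterior/superoinferior components."""
    biting = Biting(biting)
    if biting is Biting.GNAWING:
        return np.array([0.0, 0.0, 1.0])
    sc = scenario_loads(biting, food)
    v = np.array([sc.Fx, 0.0, sc.Fz])
    return v / np.linalg.norm(v)


@dataclass
class ConstraintSet:
    """Prescribed-displacement constraints: per node, which axes are
    fixed, and optionally the prescribed values (zero by default)."""

    node_ids: np.ndarray  # (k,)
    fixed_axes: np.ndarray  # (k, 3) bool
    values: Optional[np.ndarray] = None  # (k, 3) prescribed displacement

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, np.int64)
        self.fixed_axes = np.asarray(self.fixed_axes, bool)
        if self.fixed_axes.shape != (len(self.node_ids), 3):
            raise ValueError("fixed_axes must be (k, 3) matching node_ids")
        if len(self.node_ids) == 0:
            raise ValueError("constraint set must be non-empty")
        if self.values is not None:
            self.values = np.asarray(self.values, float)
            if self.values.shape != self.fixed_axes.shape:
                raise ValueError("values must be (k, 3) matching fixed_axes")

    def dof_indices(self) -> np.ndarray:
        dofs = (3 * self.node_ids[:, None] + np.arange(3)[None, :])[self.fixed_axes]
        return np.unique(dofs)

    def dof_values(self, n_dofs: int) -> np.ndarray:
        """Prescribed displacement on the full dof vector (zeros elsewhere)."""
        u = np.zeros(n_dofs)
        if self.values is not None:
            rows = np.repeat(self.node_ids, 3).reshape(-1, 3)
            u[(3 * rows + np.arange(3)[None, :])[self.fixed_axes]] = self.values[
                self.fixed_axes
            ]
        return u


class RigidModeError(RuntimeError):
    """Constraints leave a rigid-body mode (singular stiffness)."""


def tmj_constraints(
    mesh: TetMesh,
    geom: MandibleGeometry | None = None,
    midline: float | None = None,
    band: float | None = None,
) -> ConstraintSet:
    """Articulate the condylar surfaces at the TMJ: fix all translations
    of condylar-surface nodes lying within about one element of each
    condyle's mediolateral axis (the line y -> (x_c, z_top)), both sides.

    The constrained patch is a narrow band on the curved condylar dome,
    so rotation about the mediolateral axis meets only weak elastic
    resistance away from the band.  If the selected nodes are collinear
    (a rigid rotation would survive) the band is widened; failing that a
    :class:`RigidModeError` is raised.
    """
    geom = geom if geom is not None else MandibleGeometry()
    if midline is None:
        midline = float(mesh.nodes[:, 1].min() + mesh.nodes[:, 1].max()) / 2.0
    cond = select_region_nodes(mesh, "condyle_articular", geom, midline)
    pts = mesh.nodes[cond]
    if band is None:
        bs = mesh.provenance.get("block_size")
        band = max(bs) if bs else float(np.median(np.diff(np.unique(mesh.nodes[:, 0]))))

    xc = geom.condyle_center[0]
    for attempt in range(4):
        picked = []
        for side in (pts[:, 1] >= midline, pts[:, 1] < midline):
            if not side.any():
                continue
            ztop = pts[side, 2].max()
            d = np.hypot(pts[side, 0] - xc, pts[side, 2] - ztop)
            picked.append(cond[side][d <= band * 1.001])
        sel = np.unique(np.concatenate(picked)) if picked else np.array([], np.int64)
        if len(sel) >= 3:
            p = mesh.nodes[sel] - mesh.nodes[sel].mean(axis=0)
            svals = np.linalg.svd(p, compute_uv=False)
            if svals[1] > 1e-9 * max(svals[0], 1.0):
                return ConstraintSet(sel, np.ones((len(sel), 3), bool))
        band *= 1.5
    raise RigidModeError(
        "TMJ constraint nodes are collinear or too few; rigid rotation about "
        "the condylar axis would remain"
    )
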
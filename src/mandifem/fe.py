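"""Small-strain isotropic linear-elastic finite elements on TET4 meshes.

Constant-strain tetrahedra (CST): element stiffness ``V * B^T D B`` with
the isotropic elasticity matrix D built from (E, nu).  The global system
is reduced by eliminating fixed degrees of freedom and solved with a
sparse direct factorization (conjugate-gradient fallback with an
incomplete-LU preconditioner for very large systems).  Stresses are
element-constant; the von Mises invariant summarizes each stress tensor.

Engineering shear strains (gamma = 2 eps) are used in the Voigt
convention [xx, yy, zz, xy, yz, zx].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from mandifem.meshing import TetMesh
from mandifem.model import ConstraintSet, Material, NodalLoadSet, RigidModeError, TissueTable


class SolverError(RuntimeError):
    """The constrained solve failed or did not reach the residual target."""


def isotropic_elasticity_matrix(material: Material) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order [xx, yy, zz, xy, yz, zx]."""
    E, nu = material.E, material.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


_DN_REF = np.array(
    [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


def _shape_gradients(coords: np.ndarray):
    """Batched shape-function gradients and volumes for (m, 4, 3) coords."""
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    J = coords[:, 1:] - coords[:, :1]  # (m, 3, 3) rows = edge vectors
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise ValueError(
            f"degenerate tetrahedron at element {bad} (signed volume {vol.min():g})"
        )
    invJ = np.linalg.inv(J)
    dN = _DN_REF[None] @ invJ.transpose(0, 2, 1)  # (m, 4, 3)
    return (dN[0], vol[0]) if single else (dN, vol)


def _b_matrices(dN: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, (m, 6, 12), Voigt engineering shear."""
    m = dN.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        bx, by, bz = dN[:, a, 0], dN[:, a, 1], dN[:, a, 2]
        c = 3 * a
        B[:, 0, c] = bx
        B[:, 1, c + 1] = by
        B[:, 2, c + 2] = bz
        B[:, 3, c] = by
        B[:, 3, c + 1] = bx
        B[:, 4, c + 1] = bz
        B[:, 4, c + 2] = by
        B[:, 5, c] = bz
        B[:, 5, c + 2] = bx
    return B


def element_stiffness_tet4(coords: np.ndarray, material: Material) -> np.ndarray:
    """12x12 CST stiffness ``V * B^T D B`` for one tetrahedron.

    Raises on degenerate (zero or negative signed volume) elements.
    """
    coords = np.asarray(coords, float)
    dN, vol = _shape_gradients(coords)
    if vol <= 0:
        raise ValueError(f"degenerate tetrahedron (signed volume {vol:g})")
    B = _b_matrices(dN[None])[0]
    D = isotropic_elasticity_matrix(material)
    return vol * B.T @ D @ B


def assemble_stiffness(mesh: TetMesh, materials: TissueTable) -> sp.csr_matrix:
    """Global sparse stiffness (3n x 3n), vectorized over elements."""
    coords = mesh.element_coords()
    dN, vol = _shape_gradients(coords)
    if (vol <= 0).any():
        bad = int(np.argmin(vol))
        raise ValueError(f"degenerate element {bad} (signed volume {vol[bad]:g})")
    B = _b_matrices(dN)
    codes = np.unique(mesh.tissue)
    D = np.zeros((int(codes.max()) + 1, 6, 6))
    for c in codes:
        D[c] = isotropic_elasticity_matrix(materials[int(c)])
    DB = np.einsum("mij,mjk->mik", D[mesh.tissue], B)
    Ke = vol[:, None, None] * np.einsum("mji,mjk->mik", B, DB)

    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n))
    return K.tocsr()


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises invariant of symmetric stress tensors (..., 3, 3):
    sqrt(1/2[(s11-s22)^2+(s22-s33)^2+(s33-s11)^2] + 3[s12^2+s23^2+s13^2])."""
    s = np.asarray(stress, float)
    s11, s22, s33 = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
    s12, s23, s13 = s[..., 0, 1], s[..., 1, 2], s[..., 0, 2]
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s23**2 + s13**2)
    )


@dataclass
class FEResult:
    """Solution fields: nodal displacements (mm), element-constant stress
    tensors and von Mises values (MPa), and reactions (N) at constrained
    nodes."""

    displacements: np.ndarray  # (n, 3)
    element_stress: np.ndarray  # (m, 3, 3)
    von_mises: np.ndarray  # (m,)
    reactions: Dict[int, np.ndarray]
    residual: float

    def nodal_von_mises(self, mesh: TetMesh) -> np.ndarray:
        """Volume-weighted average of adjacent-element von Mises per node
        (display only; analysis statistics use element values)."""
        vols = mesh.element_volumes()
        num = np.zeros(mesh.n_nodes)
        den = np.zeros(mesh.n_nodes)
        for a in range(4):
            np.add.at(num, mesh.elements[:, a], vols * self.von_mises)
            np.add.at(den, mesh.elements[:, a], vols)
        den[den == 0] = 1.0
        return num / den


def _recover(mesh, materials, u, K, f, constraints) -> FEResult:
    coords = mesh.element_coords()
    dN, vol = _shape_gradients(coords)
    B = _b_matrices(dN)
    ue = u.reshape(-1, 3)[mesh.elements].reshape(-1, 12)
    strain = np.einsum("mij,mj->mi", B, ue)
    codes = np.unique(mesh.tissue)
    D = np.zeros((int(codes.max()) + 1, 6, 6))
    for c in codes:
        D[c] = isotropic_elasticity_matrix(materials[int(c)])
    sv = np.einsum("mij,mj->mi", D[mesh.tissue], strain)  # Voigt stress
    tensors = np.empty((len(sv), 3, 3))
    tensors[:, 0, 0] = sv[:, 0]
    tensors[:, 1, 1] = sv[:, 1]
    tensors[:, 2, 2] = sv[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = sv[:, 3]
    tensors[:, 1, 2] = tensors[:, 2, 1] = sv[:, 4]
    tensors[:, 0, 2] = tensors[:, 2, 0] = sv[:, 5]

    r = K @ u - f
    reactions = {
        int(nid): r[3 * nid : 3 * nid + 3].copy() for nid in constraints.node_ids
    }
    fn = np.linalg.norm(f)
    free = np.ones(len(u), bool)
    free[constraints.dof_indices()] = False
    resid = np.linalg.norm(r[free]) / (fn if fn > 0 else 1.0)
    return FEResult(u.reshape(-1, 3), tensors, von_mises(tensors), reactions, resid)


class StiffnessOperator:
    """Assembled and factorized stiffness for repeated solves on one mesh
    (the four masticatory scenarios share the factorization)."""

    def __init__(
        self,
        mesh: TetMesh,
        materials: TissueTable,
        constraints: ConstraintSet,
        method: str = "auto",
    ):
        self.mesh = mesh
        self.materials = materials
        self.constraints = constraints
        self.K = assemble_stiffness(mesh, materials)
        n = self.K.shape[0]
        fixed = np.zeros(n, bool)
        fixed[constraints.dof_indices()] = True
        self.free = ~fixed
        self.Kff = self.K[self.free][:, self.free].tocsc()
        self.Kfc = self.K[self.free][:, fixed].tocsr()
        if method == "auto":
            method = "direct" if self.Kff.shape[0] <= 400_000 else "cg"
        self.method = method
        self._lu = None
        if method == "direct":
            try:
                self._lu = spla.splu(self.Kff)
            except RuntimeError as exc:
                raise RigidModeError(
                    f"global stiffness is singular (rigid-body mode?): {exc}"
                ) from exc

    def solve(self, loads: Optional[NodalLoadSet], rtol: float = 1e-8) -> FEResult:
        n = self.K.shape[0]
        f = np.zeros(n)
        if loads is not None:
            np.add.at(f.reshape(-1, 3), loads.node_ids, loads.forces)
        uc = self.constraints.dof_values(n)
        ff = f[self.free] - self.Kfc @ uc[~self.free]
        if self._lu is not None:
            uf = self._lu.solve(ff)
        else:
            M = spla.LinearOperator(
                self.Kff.shape, spla.spilu(self.Kff, drop_tol=1e-5).solve
            )
            uf, info = spla.cg(self.Kff, ff, rtol=1e-10, atol=0.0, M=M, maxiter=20000)
            if info != 0:
                raise SolverError(f"conjugate gradient did not converge (info={info})")
        u = uc.copy()
        u[self.free] = uf
        res = _recover(self.mesh, self.materials, u, self.K, f, self.constraints)
        if not np.isfinite(res.residual) or res.residual > rtol:
            raise SolverError(
                f"relative residual {res.residual:.3e} exceeds tolerance {rtol:g} "
                "(singular or ill-conditioned system?)"
            )
        return res


def surface_traction_loads(
    mesh: TetMesh, node_mask: np.ndarray, traction: np.ndarray
) -> NodalLoadSet:
    """Consistent nodal loads for a uniform traction (N/mm^2) on the
    boundary faces whose three nodes all satisfy ``node_mask``: each face
    contributes traction * area / 3 to each of its nodes."""
    faces = mesh.boundary_faces()
    sel = node_mask[faces].all(axis=1)
    faces = faces[sel]
    if len(faces) == 0:
        raise ValueError("no boundary faces inside the node mask")
    p = mesh.nodes[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    traction = np.asarray(traction, float)
    contrib = (areas[:, None] / 3.0) * traction[None, :]
    ids = faces.ravel()
    forces = np.repeat(contrib, 3, axis=0)
    return NodalLoadSet(ids, forces)


def solve(
    mesh: TetMesh,
    materials: TissueTable,
    loads: NodalLoadSet,
    constraints: ConstraintSet,
    method: str = "auto",
    rtol: float = 1e-8,
) -> FEResult:
    """Assemble, reduce, solve and recover stresses for one load case."""
    return StiffnessOperator(mesh, materials, constraints, method=method).solve(
        loads, rtol=rtol
    )
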
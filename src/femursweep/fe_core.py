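"""Linear-elastic 4-node tetrahedral finite elements with rigid ties.

Constant-strain tetrahedra, isotropic material per element, small strains.
Boundary conditions follow the stance-load setup used for whole-femur
analyses: surface node sets are tied rigidly to 6-DOF reference points
(femoral head -> hip reference; each condyle -> its own reference), the
condyle references are fully constrained, and a point load is applied at the
free hip reference. Constraints are enforced by master-slave elimination:

    u_slave = u_ref + theta_ref x (x_slave - x_ref)

which yields a reduced symmetric positive-definite system solved by sparse
LU factorisation. Reactions are recovered from the internal-force residual
at the constrained nodes, so global equilibrium can be verified to solver
precision. Dirichlet (prescribed-displacement) nodes are supported through
the same elimination, which is how the patch test is driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .calibration import MaterialField
from .mesh import TetMesh

__all__ = [
    "Tie",
    "LoadCase",
    "FEModel",
    "ConstrainedSystem",
    "SolveResult",
    "assemble_stiffness",
    "apply_ties_and_solve",
    "principal_strains",
    "probe_strain",
    "convergence_study",
    "stance_load_magnitude",
    "GRAVITY",
    "DEFAULT_BODY_MASS_KG",
    "DEFAULT_LOAD_MULTIPLE",
]

GRAVITY = 9.81  # m/s^2
DEFAULT_BODY_MASS_KG = 68.0
DEFAULT_LOAD_MULTIPLE = 7.5


def stance_load_magnitude(
    body_mass_kg: float = DEFAULT_BODY_MASS_KG,
    multiple: float = DEFAULT_LOAD_MULTIPLE,
    g: float = GRAVITY,
) -> float:
    """Stance load in newtons: ``multiple x body weight`` (default 7.5 x 68 kg)."""
    return multiple * body_mass_kg * g


@dataclass
class Tie:
    """Rigid coupling of a surface node set to a 6-DOF reference point."""

    name: str
    node_ids: np.ndarray
    ref_point: np.ndarray
    fixed: bool = False

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.ref_point = np.asarray(self.ref_point, dtype=float)
        if self.node_ids.size == 0:
            raise ValueError(f"tie {self.name!r} has an empty node set")


@dataclass
class LoadCase:
    """Ties, prescribed displacements and the applied reference load."""

    ties: list
    load_tie: str | None = None
    load_vector: np.ndarray = field(default_factory=lambda: np.zeros(3))
    prescribed: dict = field(default_factory=dict)  # node id -> (3,) displacement

    def __post_init__(self):
        self.load_vector = np.asarray(self.load_vector, dtype=float)
        seen = np.concatenate([t.node_ids for t in self.ties]) if self.ties else np.array([])
        if len(np.unique(seen)) != len(seen):
            raise ValueError("tie node sets must be disjoint")
        names = [t.name for t in self.ties]
        if len(set(names)) != len(names):
            raise ValueError("tie names must be unique")
        if self.load_tie is not None:
            t = self.tie(self.load_tie)
            if t.fixed:
                raise ValueError("cannot apply a load at a fixed reference")

    def tie(self, name: str) -> Tie:
        for t in self.ties:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def load_magnitude(self) -> float:
        return float(np.linalg.norm(self.load_vector))


def _elasticity_matrix(nu: float) -> np.ndarray:
    """Isotropic 6x6 elasticity matrix for E = 1 (engineering shear)."""
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


class FEModel:
    """Pre-assembled element data for one mesh + material field.

    Caches shape-function gradients, per-element B matrices and unit-modulus
    element stiffness matrices, so global stiffness re-assembly for modified
    moduli (lesion cases) costs one scaled scatter.
    """

    def __init__(self, mesh: TetMesh, materials: MaterialField):
        if materials.n_elements != mesh.n_elements:
            raise ValueError("material field does not match the mesh")
        v = mesh.signed_volumes()
        if np.any(v <= 0):
            bad = int(np.argmin(v))
            raise ValueError(
                f"element {bad} has non-positive volume {v[bad]:.3e}; "
                "mesh orientation is inconsistent"
            )
        self.mesh = mesh
        self.materials = materials
        self.volumes = v
        x = mesh.nodes[mesh.tets]
        J = x[:, 1:] - x[:, :1]  # rows are edge vectors from node 0
        Jinv = np.linalg.inv(J)
        g123 = Jinv.transpose(0, 2, 1)  # (M,3,3): row a-1 = grad(lambda_a) = J^{-T}
        g0 = -g123.sum(axis=1, keepdims=True)
        self.grads = np.concatenate([g0, g123], axis=1)  # (M,4,3)
        M = mesh.n_elements
        B = np.zeros((M, 6, 12))
        for a in range(4):
            gx, gy, gz = (self.grads[:, a, i] for i in range(3))
            c = 3 * a
            B[:, 0, c] = gx
            B[:, 1, c + 1] = gy
            B[:, 2, c + 2] = gz
            B[:, 3, c] = gy
            B[:, 3, c + 1] = gx
            B[:, 4, c + 1] = gz
            B[:, 4, c + 2] = gy
            B[:, 5, c] = gz
            B[:, 5, c + 2] = gx
        self.B = B
        D = _elasticity_matrix(materials.nu)
        # unit-modulus element stiffness: V * B^T D B
        self.unit_ke = np.einsum("eji,jk,ekl,e->eil", B, D, B, v, optimize=True)
        dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(M, 12)
        self.element_dofs = dofs
        self._rows = np.repeat(dofs, 12, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 12)).ravel()
        self.n_dofs = 3 * mesh.n_nodes

    def stiffness(self, E: np.ndarray | None = None) -> csr_matrix:
        """Global stiffness (CSR) for moduli ``E`` (defaults to the field's)."""
        E = self.materials.E if E is None else np.asarray(E, dtype=float)
        vals = (self.unit_ke * E[:, None, None]).ravel()
        K = coo_matrix((vals, (self._rows, self._cols)),
                       shape=(self.n_dofs, self.n_dofs))
        return K.tocsr()

    def stiffness_subset(self, element_ids, dE) -> coo_matrix:
        """Stiffness contribution of a subset with moduli increments ``dE``."""
        element_ids = np.asarray(element_ids, dtype=np.int64)
        dE = np.broadcast_to(np.asarray(dE, dtype=float), element_ids.shape)
        vals = (self.unit_ke[element_ids] * dE[:, None, None]).ravel()
        dofs = self.element_dofs[element_ids]
        rows = np.repeat(dofs, 12, axis=1).ravel()
        cols = np.tile(dofs, (1, 12)).ravel()
        return coo_matrix((vals, (rows, cols)), shape=(self.n_dofs, self.n_dofs))

    def strains(self, u: np.ndarray) -> np.ndarray:
        """Per-element small-strain tensors in Voigt order
        (exx, eyy, ezz, gxy, gyz, gxz)."""
        ue = u[self.element_dofs]
        return np.einsum("eij,ej->ei", self.B, ue)


def assemble_stiffness(mesh: TetMesh, materials: MaterialField) -> csr_matrix:
    """Assemble the global stiffness matrix (convenience wrapper)."""
    return FEModel(mesh, materials).stiffness()


@dataclass
class SolveResult:
    """Displacements, reference-point results, reactions and strains."""

    u: np.ndarray  # (3N,) nodal displacements, mm
    strain: np.ndarray  # (M, 6) element strains
    ref_displacements: dict  # name -> (3,) mm
    ref_rotations: dict  # name -> (3,) rad
    reactions: dict  # fixed-reference name -> (3,) N
    reaction_moments: dict  # fixed-reference name -> (3,) N mm
    applied_force: np.ndarray  # (3,) N
    strain_energy: float
    _principal: np.ndarray | None = None

    @property
    def equilibrium_residual(self) -> float:
        total = sum(self.reactions.values()) + self.applied_force
        denom = max(np.linalg.norm(self.applied_force), 1.0)
        return float(np.linalg.norm(total) / denom)

    def hip_displacement_magnitude(self, ref: str = "hip") -> float:
        return float(np.linalg.norm(self.ref_displacements[ref]))

    @property
    def principal(self) -> np.ndarray:
        """(M, 3) principal strains, ascending."""
        if self._principal is None:
            e = self.strain
            T = np.empty((e.shape[0], 3, 3))
            T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = e[:, 0], e[:, 1], e[:, 2]
            T[:, 0, 1] = T[:, 1, 0] = e[:, 3] / 2
            T[:, 1, 2] = T[:, 2, 1] = e[:, 4] / 2
            T[:, 0, 2] = T[:, 2, 0] = e[:, 5] / 2
            self._principal = np.linalg.eigvalsh(T)
        return self._principal


def _tie_transform_blocks(tie: Tie, nodes: np.ndarray):
    """Rows/cols/values of the rigid map for one tie's slave nodes."""
    d = nodes[tie.node_ids] - tie.ref_point  # (k,3)
    k = len(tie.node_ids)
    # u_s = u_r + theta x d; coefficient matrix on (u_r, theta) is [I | -skew(d)]
    rot = np.zeros((k, 3, 3))
    rot[:, 0, 1] = d[:, 2]
    rot[:, 0, 2] = -d[:, 1]
    rot[:, 1, 0] = -d[:, 2]
    rot[:, 1, 2] = d[:, 0]
    rot[:, 2, 0] = d[:, 1]
    rot[:, 2, 1] = -d[:, 0]
    return rot


class ConstrainedSystem:
    """Master-slave elimination for one mesh + load case.

    Reduced unknowns are the 3 DOFs of each unconstrained node followed by
    6 DOFs (translation, rotation) for every non-fixed reference point.
    """

    def __init__(self, mesh: TetMesh, load_case: LoadCase):
        self.mesh = mesh
        self.load_case = load_case
        n = mesh.n_nodes
        constrained = np.zeros(n, dtype=bool)
        for t in load_case.ties:
            constrained[t.node_ids] = True
        presc_ids = np.fromiter(load_case.prescribed.keys(), dtype=np.int64,
                                count=len(load_case.prescribed))
        if presc_ids.size and constrained[presc_ids].any():
            raise ValueError("a node cannot be both tied and prescribed")
        constrained[presc_ids] = True
        free = np.where(~constrained)[0]
        self.free_nodes = free
        n_free = free.size
        self.free_refs = [t for t in load_case.ties if not t.fixed]
        self.ref_offset = {t.name: 3 * n_free + 6 * i
                           for i, t in enumerate(self.free_refs)}
        self.n_red = 3 * n_free + 6 * len(self.free_refs)
        if self.n_red == 0:
            raise ValueError("no unknowns left after constraints")

        rows, cols, vals = [], [], []
        free_dofs = (3 * free[:, None] + np.arange(3)).ravel()
        rows.append(free_dofs)
        cols.append(np.arange(3 * n_free))
        vals.append(np.ones(3 * n_free))
        for t in self.free_refs:
            off = self.ref_offset[t.name]
            k = len(t.node_ids)
            slave_dofs = (3 * t.node_ids[:, None] + np.arange(3)).ravel()
            # translation part
            rows.append(np.repeat(slave_dofs.reshape(k, 3), 1, axis=0).ravel())
            cols.append(np.tile(off + np.arange(3), k))
            vals.append(np.ones(3 * k))
            # rotation part
            rot = _tie_transform_blocks(t, mesh.nodes)
            rows.append(np.repeat(slave_dofs, 3))
            cols.append(np.tile(off + 3 + np.arange(3), 3 * k))
            vals.append(rot.reshape(-1))
        self.T = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * n, self.n_red),
        ).tocsr()
        self.u_presc = np.zeros(3 * n)
        for nid, disp in load_case.prescribed.items():
            self.u_presc[3 * nid: 3 * nid + 3] = np.asarray(disp, dtype=float)
        self.f_red_applied = np.zeros(self.n_red)
        if load_case.load_tie is not None:
            off = self.ref_offset[load_case.load_tie]
            self.f_red_applied[off: off + 3] = load_case.load_vector

    def reduce(self, K: csr_matrix):
        K_red = (self.T.T @ K @ self.T).tocsc()
        f_red = self.f_red_applied.copy()
        if np.any(self.u_presc):
            f_red -= self.T.T @ (K @ self.u_presc)
        return K_red, f_red

    def factorize(self, K: csr_matrix):
        K_red, f_red = self.reduce(K)
        try:
            lu = splu(K_red)
        except RuntimeError as err:
            raise RuntimeError(
                "constrained stiffness is singular; check that the ties "
                "restrain all rigid-body modes"
            ) from err
        return _Factorisation(self, K, lu, f_red)

    def solve(self, model: FEModel, K: csr_matrix | None = None,
              load_vector: np.ndarray | None = None) -> SolveResult:
        K = model.stiffness() if K is None else K
        return self.factorize(K).solve(model, load_vector=load_vector)


class _Factorisation:
    """A factorised constrained system; cheap re-solves for new load vectors."""

    def __init__(self, system: ConstrainedSystem, K_full, lu, f_red):
        self.system = system
        self.K_full = K_full
        self.lu = lu
        self.f_red = f_red

    def solve(self, model: FEModel, load_vector: np.ndarray | None = None) -> SolveResult:
        sys = self.system
        lc = sys.load_case
        f_red = self.f_red
        applied = lc.load_vector
        if load_vector is not None:
            applied = np.asarray(load_vector, dtype=float)
            f_red = self.f_red.copy()
            off = sys.ref_offset[lc.load_tie]
            f_red[off: off + 3] = applied
            # keep any prescribed-displacement contribution
            f_red[off: off + 3] += self.f_red[off: off + 3] - lc.load_vector
        u_red = self.lu.solve(f_red)
        u = sys.T @ u_red + sys.u_presc
        g = self.K_full @ u  # internal forces; applied loads act at refs only
        reactions, moments = {}, {}
        for t in lc.ties:
            if not t.fixed:
                continue
            gs = g[(3 * t.node_ids[:, None] + np.arange(3)).ravel()].reshape(-1, 3)
            reactions[t.name] = gs.sum(axis=0)
            d = sys.mesh.nodes[t.node_ids] - t.ref_point
            moments[t.name] = np.cross(d, gs).sum(axis=0)
        ref_u, ref_rot = {}, {}
        for t in lc.ties:
            if t.fixed:
                ref_u[t.name] = np.zeros(3)
                ref_rot[t.name] = np.zeros(3)
            else:
                off = sys.ref_offset[t.name]
                ref_u[t.name] = u_red[off: off + 3].copy()
                ref_rot[t.name] = u_red[off + 3: off + 6].copy()
        return SolveResult(
            u=u,
            strain=model.strains(u),
            ref_displacements=ref_u,
            ref_rotations=ref_rot,
            reactions=reactions,
            reaction_moments=moments,
            applied_force=applied.copy(),
            strain_energy=float(0.5 * u @ g),
        )


def apply_ties_and_solve(mesh: TetMesh, materials: MaterialField,
                         load_case: LoadCase) -> SolveResult:
    """Assemble, constrain, and solve in one call."""
    model = FEModel(mesh, materials)
    return ConstrainedSystem(mesh, load_case).solve(model)


def principal_strains(result: SolveResult):
    """Per-element (eps_max, eps_min); eigenvalues of the strain tensor."""
    p = result.principal
    return p[:, 2], p[:, 0]


def probe_strain(result: SolveResult, mesh: TetMesh, point, radius: float = 1.5):
    """Mean principal strains over elements whose centroid lies within
    ``radius`` of ``point`` (spherical averaging to suppress single-element
    strain concentrations).

    Returns ``(mean eps_max, mean eps_min)``; raises if the probe sphere
    contains no element centroid (increase the radius on coarse meshes).
    """
    point = np.asarray(point, dtype=float)
    d2 = np.sum((mesh.centroids - point) ** 2, axis=1)
    sel = d2 <= radius**2
    if not sel.any():
        raise ValueError(
            f"no element centroid within {radius} mm of the probe point; "
            "use a larger radius"
        )
    p = result.principal[sel]
    return float(p[:, 2].mean()), float(p[:, 0].mean())


def convergence_study(make_case, element_counts) -> pd.DataFrame:
    """Hip-reference displacement versus mesh density.

    ``make_case(n_target)`` must return ``(mesh, materials, load_case)`` for
    a mesh of roughly ``n_target`` elements; the load case's ``load_tie``
    reference displacement magnitude is reported per refinement.
    """
    if len(element_counts) < 2:
        raise ValueError("need at least two mesh densities")
    rows = []
    for n in element_counts:
        mesh, materials, lc = make_case(n)
        res = apply_ties_and_solve(mesh, materials, lc)
        rows.append(
            {
                "n_elements": mesh.n_elements,
                "hip_displacement": float(
                    np.linalg.norm(res.ref_displacements[lc.load_tie])
                ),
            }
        )
    return pd.DataFrame(rows)
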
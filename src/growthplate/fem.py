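"""Small-strain plane-strain linear elasticity on 4-node quadrilaterals.

Provides stiffness assembly, Dirichlet/traction boundary conditions, a
sparse solve and centroid stress recovery.  The solver exists to supply one
number to the growth kinetics: the axial stress ``sigma_n = n . sigma . n``
in each cartilage element under the sustained load.

Unit system: lengths in um, stresses and moduli in MPa, unit out-of-plane
thickness; forces therefore carry MPa*um (per um of thickness) and
displacements come out in um.  The system is internally consistent, so no
conversion factors appear anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import FEMesh
from .parameters import Tissue, TissueProperties, get_tissue

__all__ = [
    "BoundaryConditions",
    "FESolution",
    "element_stiffness",
    "assemble_stiffness",
    "assemble_and_solve",
    "axial_stress",
    "default_supports",
]

# 2x2 Gauss rule (full integration for the bilinear quad)
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS = [(xi, eta) for eta in _GP for xi in _GP]
# parent-element node coordinates, CCW
_XI_N = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])


def _shape_gradients(xi: float, eta: float) -> np.ndarray:
    """dN/d(xi,eta) for the 4 bilinear shape functions, shape (4, 2)."""
    g = np.empty((4, 2))
    g[:, 0] = _XI_N[:, 0] * (1.0 + _XI_N[:, 1] * eta) / 4.0
    g[:, 1] = _XI_N[:, 1] * (1.0 + _XI_N[:, 0] * xi) / 4.0
    return g


def _constitutive(E: float, nu: float) -> np.ndarray:
    """Plane-strain isotropic constitutive matrix (Voigt: xx, yy, xy)."""
    c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return c * np.array(
        [
            [1.0 - nu, nu, 0.0],
            [nu, 1.0 - nu, 0.0],
            [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
        ]
    )


def _b_matrix(coords: np.ndarray, xi: float, eta: float) -> tuple[np.ndarray, float]:
    """Strain-displacement matrix (3, 8) and Jacobian determinant."""
    dN = _shape_gradients(xi, eta)
    J = coords.T @ dN  # (2, 2)
    detJ = float(np.linalg.det(J))
    if detJ <= 0:
        raise ValueError(f"inverted element: Jacobian determinant {detJ} <= 0")
    dNdx = dN @ np.linalg.inv(J)  # (4, 2)
    B = np.zeros((3, 8))
    B[0, 0::2] = dNdx[:, 0]
    B[1, 1::2] = dNdx[:, 1]
    B[2, 0::2] = dNdx[:, 1]
    B[2, 1::2] = dNdx[:, 0]
    return B, detJ


def element_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """8x8 stiffness of one plane-strain quad (2x2 Gauss quadrature).

    ``coords`` is (4, 2) in um, counter-clockwise.  Raises on an inverted
    element.
    """
    coords = np.asarray(coords, dtype=float)
    D = _constitutive(E, nu)
    K = np.zeros((8, 8))
    for xi, eta in _GAUSS:
        B, detJ = _b_matrix(coords, xi, eta)
        K += B.T @ D @ B * detJ  # unit Gauss weights
    return K


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet supports plus a uniform axial traction on the top edge.

    ``fixed_dofs`` maps node index -> (fix_x, fix_y).  ``top_traction`` is
    the applied normal stress in MPa, tension (upward on the top edge)
    positive.
    """

    fixed_dofs: dict[int, tuple[bool, bool]]
    top_traction: float = 0.0

    def n_constraints(self) -> int:
        return sum(fx + fy for fx, fy in self.fixed_dofs.values())


def default_supports(mesh: FEMesh, traction: float) -> BoundaryConditions:
    """Confined-column supports: the setup that makes sigma_n uniform.

    Bottom edge fixed vertically, both lateral edges on vertical rollers
    (u_x = 0), uniform traction on the top edge.  With lateral confinement
    the stacked-layer solution is exact for bilinear elements and the axial
    stress equals the applied traction in every element regardless of the
    layer moduli.  (With free lateral edges the Poisson-ratio mismatch
    between bone and cartilage perturbs the interface stress field, so the
    applied load would no longer be the stress the kinetics sees.)
    """
    nxp = mesh.nx + 1
    nyp = mesh.ny + 1
    fixed = {i: (False, True) for i in range(nxp)}
    for iy in range(nyp):
        for node in (iy * nxp, iy * nxp + nxp - 1):
            fx, fy = fixed.get(node, (False, False))
            fixed[node] = (True, fy)
    return BoundaryConditions(fixed_dofs=fixed, top_traction=traction)


@dataclass(frozen=True)
class FESolution:
    """Displacements, centroid stresses, axial stress and reactions."""

    displacements: np.ndarray        # (n_nodes, 2) um
    stresses: np.ndarray             # (n_elems, 3) MPa, Voigt (xx, yy, xy)
    sigma_n: np.ndarray              # (n_elems,) MPa along the growth direction
    reactions: np.ndarray            # (n_dofs,) MPa*um at constrained dofs, else 0
    applied_force: float             # total applied top traction resultant, MPa*um
    growth_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))


def _element_materials(
    mesh: FEMesh, materials: dict[Tissue, TissueProperties] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (E, nu) arrays from the element->tissue map."""
    lookup = {t: (materials[t] if materials else get_tissue(t)) for t in Tissue}
    E = np.empty(mesh.nx * mesh.ny)
    nu = np.empty_like(E)
    for i, tissue in enumerate(mesh.element_tissue):
        props = lookup[tissue]
        E[i] = props.youngs_modulus
        nu[i] = props.poisson_ratio
    return E, nu


def assemble_stiffness(
    mesh: FEMesh, materials: dict[Tissue, TissueProperties] | None = None
) -> sp.csr_matrix:
    """Global sparse stiffness matrix (vectorised over elements)."""
    nodes, elems = mesh.nodes, mesh.elements
    E, nu = _element_materials(mesh, materials)
    ne = len(elems)
    coords = nodes[elems]  # (ne, 4, 2)

    c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    D = np.zeros((ne, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = c * (1.0 - nu)
    D[:, 0, 1] = D[:, 1, 0] = c * nu
    D[:, 2, 2] = c * (1.0 - 2.0 * nu) / 2.0

    Ke = np.zeros((ne, 8, 8))
    for xi, eta in _GAUSS:
        dN = _shape_gradients(xi, eta)                       # (4, 2)
        J = np.einsum("eai,aj->eij", coords, dN)             # (ne, 2, 2) = coords^T dN
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("inverted element during assembly")
        invJ = np.linalg.inv(J)
        dNdx = np.einsum("eij,aj->eai", invJ.transpose(0, 2, 1), dN)  # dN @ invJ
        B = np.zeros((ne, 3, 8))
        B[:, 0, 0::2] = dNdx[:, :, 0]
        B[:, 1, 1::2] = dNdx[:, :, 1]
        B[:, 2, 0::2] = dNdx[:, :, 1]
        B[:, 2, 1::2] = dNdx[:, :, 0]
        Ke += np.einsum("eki,ekl,elj,e->eij", B, D, B, detJ, optimize=True)

    dofs = np.empty((ne, 8), dtype=int)
    dofs[:, 0::2] = 2 * elems
    dofs[:, 1::2] = 2 * elems + 1
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    ndof = 2 * len(nodes)
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()


def _traction_loads(mesh: FEMesh, traction: float) -> np.ndarray:
    """Consistent nodal loads for a uniform normal traction on the top edge."""
    ndof = 2 * (mesh.nx + 1) * (mesh.ny + 1)
    f = np.zeros(ndof)
    top0 = mesh.ny * (mesh.nx + 1)
    seg = np.diff(mesh.x_levels)
    for i, L in enumerate(seg):
        for node in (top0 + i, top0 + i + 1):
            f[2 * node + 1] += traction * L / 2.0
    return f


def assemble_and_solve(
    mesh: FEMesh,
    bc: BoundaryConditions,
    materials: dict[Tissue, TissueProperties] | None = None,
) -> FESolution:
    """Assemble, apply boundary conditions, solve, recover stresses.

    Raises ``ValueError`` if the supports leave rigid-body modes (fewer
    than 3 independent constraints, or a singular reduced system).
    """
    if bc.n_constraints() < 3:
        raise ValueError(
            "boundary conditions leave rigid-body modes: at least 3 independent "
            "constraints are required in 2-D"
        )
    K = assemble_stiffness(mesh, materials)
    f = _traction_loads(mesh, bc.top_traction)

    ndof = K.shape[0]
    fixed = np.zeros(ndof, dtype=bool)
    for node, (fx, fy) in bc.fixed_dofs.items():
        fixed[2 * node] |= fx
        fixed[2 * node + 1] |= fy
    free = ~fixed

    Kff = K[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff)
    except RuntimeError as err:
        raise ValueError(f"singular stiffness system (unconstrained modes?): {err}") from err
    u = np.zeros(ndof)
    u[free] = lu.solve(f[free])

    reactions = np.zeros(ndof)
    reactions[fixed] = (K @ u - f)[fixed]

    # centroid stress recovery
    nodes, elems = mesh.nodes, mesh.elements
    E, nu = _element_materials(mesh, materials)
    stresses = np.empty((len(elems), 3))
    ue = u.reshape(-1, 2)[elems].reshape(len(elems), 8)
    for i, el in enumerate(elems):
        B, _ = _b_matrix(nodes[el], 0.0, 0.0)
        stresses[i] = _constitutive(E[i], nu[i]) @ (B @ ue[i])

    n = np.array([0.0, 1.0])
    sol = FESolution(
        displacements=u.reshape(-1, 2),
        stresses=stresses,
        sigma_n=np.empty(len(elems)),
        reactions=reactions,
        applied_force=bc.top_traction * float(mesh.x_levels[-1] - mesh.x_levels[0]),
        growth_direction=n,
    )
    sol.sigma_n[:] = axial_stress(sol, n)
    return sol


def axial_stress(solution: FESolution, n: np.ndarray) -> np.ndarray:
    """Per-element normal stress along ``n``: ``sigma_n = n . sigma . n``."""
    n = np.asarray(n, dtype=float)
    sxx, syy, sxy = solution.stresses.T
    return n[0] ** 2 * sxx + n[1] ** 2 * syy + 2.0 * n[0] * n[1] * sxy
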
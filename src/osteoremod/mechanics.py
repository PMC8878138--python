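"""Axisymmetric linear elasticity of the axially compressed diaphysis.

The bone is loaded in simple compression by the animal's body weight.  The
half model carries the total axial force through a rigid frictionless
platen on its top face (all top nodes share one axial displacement), with
the symmetry plane at the bottom (zero axial displacement) and the axis
radially fixed.  Because the modulus varies with radius only, this load
case admits an exact uniform-axial-strain solution with vanishing radial
and hoop stress, which the bilinear elements reproduce to solver precision;
the ``iso_strain_reference`` closed form is therefore an independent oracle
for the FE path.

Unit system: mm, N, MPa -- so energies come out in N*mm = mJ and
strain-energy densities in mJ/mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, sparse
from scipy.sparse.linalg import spsolve

from .geometry import (
    BoneGeometry,
    DensityProfileParams,
    MaterialParams,
    Mesh,
    density_profile,
)

#: smallest density used when forming element stiffness, to keep the
#: stiffness matrix regular on the near-empty medullary axis
DENSITY_FLOOR = 0.01

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class LoadCase:
    """Axial compressive load from body weight.

    ``axial_force`` (N) = body_mass * gravity * load_scale, with body mass
    in grams.  ``load_scale`` is the scenario multiplier that converts the
    homeostatic load into a running-scenario load.
    """

    body_mass: float = 350.0            # g
    gravity: float = GRAVITY            # m/s^2
    load_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.load_scale < 0:
            raise ValueError("load_scale must be non-negative")

    @property
    def axial_force(self) -> float:
        """Total axial force (N)."""
        return self.body_mass / 1000.0 * self.gravity * self.load_scale

    def scaled(self, load_scale: float) -> "LoadCase":
        return LoadCase(self.body_mass, self.gravity, load_scale)


@dataclass(frozen=True)
class EnergyField:
    """Elastic strain-energy field of one solved configuration.

    ``sed`` is the strain-energy density per element (mJ/mm^3), evaluated at
    the element centroid.  ``total_energy`` (mJ) is the full-bone energy:
    for a half model it is twice the energy of the meshed half.
    ``reference_sed`` is the volume-mean SED of the configuration the field
    is normalized against (by default this same configuration).
    """

    sed: np.ndarray = field(repr=False)
    total_energy: float
    reference_sed: float


def _elasticity_matrix(E_MPa: float, nu: float) -> np.ndarray:
    """4x4 axisymmetric Hooke matrix for strains (e_rr, e_zz, e_tt, g_rz)."""
    c = E_MPa / ((1.0 + nu) * (1.0 - 2.0 * nu))
    D = c * np.array(
        [
            [1.0 - nu, nu, nu, 0.0],
            [nu, 1.0 - nu, nu, 0.0],
            [nu, nu, 1.0 - nu, 0.0],
            [0.0, 0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
        ]
    )
    return D


_GAUSS = 1.0 / np.sqrt(3.0)
_GAUSS_POINTS = [(-_GAUSS, -_GAUSS), (_GAUSS, -_GAUSS), (_GAUSS, _GAUSS), (-_GAUSS, _GAUSS)]


def _shape_functions(xi: float, eta: float):
    N = 0.25 * np.array(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    )
    dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    return N, dN_dxi, dN_deta


def _element_b_matrices(mesh: Mesh, xi: float, eta: float, r_nodes: np.ndarray):
    """B matrix and integration weight at one quadrature point.

    For the structured rectangular elements the Jacobian is diagonal and
    constant: dr = (dr/2) dxi, dz = (dz/2) deta.
    """
    N, dN_dxi, dN_deta = _shape_functions(xi, eta)
    dN_dr = dN_dxi / (mesh.dr / 2.0)
    dN_dz = dN_deta / (mesh.dz / 2.0)
    r_gp = float(N @ r_nodes)
    B = np.zeros((4, 8))
    B[0, 0::2] = dN_dr
    B[1, 1::2] = dN_dz
    B[2, 0::2] = N / r_gp
    B[3, 0::2] = dN_dz
    B[3, 1::2] = dN_dr
    detJ = (mesh.dr / 2.0) * (mesh.dz / 2.0)
    weight = 2.0 * np.pi * r_gp * detJ  # axisymmetric volume weight, w_gauss = 1
    return B, weight, N


def solve_axial_compression(
    mesh: Mesh,
    density_field: np.ndarray,
    material: MaterialParams | None = None,
    load: LoadCase | None = None,
    *,
    half_model: bool = True,
    density_floor: float = DENSITY_FLOOR,
):
    """Solve the platen-compression problem for one density field.

    Returns ``(displacement, energy)`` where ``displacement`` is an
    (n_nodes, 2) array of (u_r, u_z) in mm and ``energy`` an
    :class:`EnergyField`.  Element stiffness uses E = E0 * max(rho, floor)^2.
    """
    if material is None:
        material = MaterialParams()
    if load is None:
        load = LoadCase()
    rho = np.asarray(density_field, dtype=float)
    if rho.shape != (mesh.n_elements,):
        raise ValueError("density_field must have one value per element")
    if np.all(rho <= 0):
        raise ValueError("all-zero density field: stiffness is singular everywhere")
    rho_eff = np.maximum(rho, density_floor)
    E_elem = material.E0_MPa * rho_eff**2
    nu = material.poisson_ratio

    n_dof = 2 * mesh.n_nodes
    # Precompute B matrices once (identical for every element of the
    # structured grid up to the radial position entering r_gp and the hoop
    # row; those depend on the element column only).
    n_r = mesh.n_r
    col_cache = {}
    rows, cols, vals = [], [], []
    conn = mesh.connectivity
    for e in range(mesh.n_elements):
        ir = e % n_r
        if ir not in col_cache:
            r_nodes = mesh.node_r[conn[e]]
            bw = [_element_b_matrices(mesh, xi, eta, r_nodes) for xi, eta in _GAUSS_POINTS]
            col_cache[ir] = bw
        bw = col_cache[ir]
        D = _elasticity_matrix(E_elem[e], nu)
        ke = np.zeros((8, 8))
        for B, w, _ in bw:
            ke += (B.T @ D @ B) * w
        dofs = np.empty(8, dtype=np.int64)
        dofs[0::2] = 2 * conn[e]
        dofs[1::2] = 2 * conn[e] + 1
        rows.append(np.repeat(dofs, 8))
        cols.append(np.tile(dofs, 8))
        vals.append(ke.ravel())
    K = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    ).tocsr()

    # Boundary conditions: axis u_r = 0; bottom (symmetry) u_z = 0; top face
    # u_z tied to a single master DOF loaded with the axial force.
    axis_nodes = np.where(mesh.node_r == 0.0)[0]
    bottom_nodes = np.where(mesh.node_z == 0.0)[0]
    top_nodes = np.where(mesh.node_z == mesh.height)[0]

    fixed = np.zeros(n_dof, dtype=bool)
    fixed[2 * axis_nodes] = True
    fixed[2 * bottom_nodes + 1] = True

    # Transformation u = T q: free DOFs map to themselves except top-face
    # u_z DOFs, which all map to the master platen DOF (last column).
    free = np.where(~fixed)[0]
    top_uz = set((2 * top_nodes + 1).tolist())
    n_master = 1
    col_index = {}
    reduced = []
    for d in free:
        if d in top_uz:
            continue
        col_index[d] = len(reduced)
        reduced.append(d)
    master_col = len(reduced)
    t_rows, t_cols, t_vals = [], [], []
    for d in free:
        c = master_col if d in top_uz else col_index[d]
        t_rows.append(d)
        t_cols.append(c)
        t_vals.append(1.0)
    T = sparse.coo_matrix(
        (t_vals, (t_rows, t_cols)), shape=(n_dof, master_col + n_master)
    ).tocsr()

    Kr = (T.T @ K @ T).tocsc()
    f = np.zeros(master_col + 1)
    f[master_col] = -load.axial_force  # compression: platen moves toward symmetry plane
    q = spsolve(Kr, f)
    u = T @ q
    disp = u.reshape(mesh.n_nodes, 2)

    # Strain-energy density at element centroids.
    sed = np.empty(mesh.n_elements)
    centroid_cache = {}
    for e in range(mesh.n_elements):
        ir = e % n_r
        if ir not in centroid_cache:
            r_nodes = mesh.node_r[conn[e]]
            centroid_cache[ir] = _element_b_matrices(mesh, 0.0, 0.0, r_nodes)
        B, _, _ = centroid_cache[ir]
        dofs = np.empty(8, dtype=np.int64)
        dofs[0::2] = 2 * conn[e]
        dofs[1::2] = 2 * conn[e] + 1
        eps = B @ u[dofs]
        D = _elasticity_matrix(E_elem[e], nu)
        sed[e] = 0.5 * eps @ D @ eps
    factor = 2.0 if half_model else 1.0
    total = factor * float(sed @ mesh.element_volume)
    ref = float(sed @ mesh.element_volume) / float(mesh.element_volume.sum())
    return disp, EnergyField(sed=sed, total_energy=total, reference_sed=ref)


def iso_strain_reference(
    geometry: BoneGeometry,
    profile: DensityProfileParams | None = None,
    material: MaterialParams | None = None,
    load: LoadCase | None = None,
    *,
    density_floor: float = DENSITY_FLOOR,
):
    """Closed-form uniform-axial-strain solution for the arctan profile.

    Assumes a uniform axial strain eps = F / (EA)_eff with
    (EA)_eff = integral of E(r) 2 pi r dr over the section; the SED is then
    ``sed(r) = E(r) * eps^2 / 2`` and the total energy
    ``(EA)_eff * eps^2 / 2 * L`` over the full bone length.

    Returns ``(sed_function, total_energy)`` with the SED function taking
    radii in mm and returning mJ/mm^3.
    """
    if profile is None:
        profile = DensityProfileParams()
    if material is None:
        material = MaterialParams()
    if load is None:
        load = LoadCase()

    def E_of_r(r_mm):
        rho = np.maximum(density_profile(r_mm, profile), density_floor)
        return material.E0_MPa * rho**2

    EA_eff, err = integrate.quad(
        lambda r: E_of_r(r) * 2.0 * np.pi * r, 0.0, geometry.outer_radius, limit=200
    )
    if not np.isfinite(EA_eff) or EA_eff <= 0:
        raise ValueError("non-integrable stiffness profile")
    eps = load.axial_force / EA_eff

    def sed_of_r(r_mm):
        return 0.5 * E_of_r(r_mm) * eps**2

    total = 0.5 * EA_eff * eps**2 * geometry.length
    return sed_of_r, total


def uniform_strain_energy(
    geometry: BoneGeometry,
    element_density: np.ndarray,
    mesh: Mesh,
    material: MaterialParams | None = None,
    load: LoadCase | None = None,
    *,
    density_floor: float = DENSITY_FLOOR,
):
    """Iso-strain oracle evaluated on a per-element density field.

    Discrete counterpart of :func:`iso_strain_reference` for fields that do
    not come from a radial formula (e.g. two-ring fixtures): the effective
    axial rigidity is summed element-wise over one axial layer.
    """
    if material is None:
        material = MaterialParams()
    if load is None:
        load = LoadCase()
    rho = np.maximum(np.asarray(element_density, float), density_floor)
    E_elem = material.E0_MPa * rho**2
    # (EA)_eff from one axial element layer: sum E * 2 pi r dr over columns
    grid = mesh.element_grid(E_elem)
    r_cols = mesh.element_r[: mesh.n_r]
    EA_eff = float((grid[0] * 2.0 * np.pi * r_cols * mesh.dr).sum())
    eps = load.axial_force / EA_eff
    sed = 0.5 * E_elem * eps**2
    total = 0.5 * EA_eff * eps**2 * geometry.length
    return sed, total


def scenario_energy_scaling(scenario_energy: float, homeostatic_energy: float) -> float:
    """Load multiplier that makes the initial configuration develop
    ``scenario_energy``: sqrt(scenario / homeostatic), since W scales with
    the square of the load in linear elasticity."""
    if scenario_energy <= 0 or homeostatic_energy <= 0:
        raise ValueError("energies must be positive")
    return float(np.sqrt(scenario_energy / homeostatic_energy))
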
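"""Idealized diaphysis geometry, initial density distribution and material law.

The tibial diaphysis is idealized as a solid cylinder whose dimensionless
bone density rises from a low trabecular value on the axis to a high
cortical value at the outer surface.  The radial density distribution is an
arctangent sigmoid whose inflection point marks the cortical-trabecular
interface; stiffness follows the quadratic law ``E = E0 * rho**2``.

All lengths at the public interfaces are millimetres.  The arctangent
profile is natively parameterised in metres (its ``steepness`` has units
1/m); conversion is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MM_PER_M = 1000.0


@dataclass(frozen=True)
class BoneGeometry:
    """Cylindrical diaphysis dimensions (mm).

    The default geometry is 10 mm long with a 3 mm outer diameter and an
    initial cortical thickness of 1 mm (interface at r = 0.5 mm).  With
    ``axisymmetric_half_model`` the meshed height is half the length, with a
    symmetry plane at mid-height.
    """

    length: float = 10.0
    outer_radius: float = 1.5
    initial_interface_radius: float = 0.5
    axisymmetric_half_model: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0 < self.initial_interface_radius < self.outer_radius:
            raise ValueError(
                "initial_interface_radius must lie strictly between 0 and outer_radius"
            )

    @property
    def modeled_height(self) -> float:
        """Axial extent of the meshed domain (mm)."""
        return self.length / 2.0 if self.axisymmetric_half_model else self.length

    @property
    def initial_cortical_thickness(self) -> float:
        return self.outer_radius - self.initial_interface_radius


@dataclass(frozen=True)
class DensityProfileParams:
    """Parameters of the idealized radial density sigmoid.

    rho(R) = atan(steepness * (R - center_radius)) / amplitude_divisor + offset

    with R in metres.  ``offset`` is the density at the inflection point
    (the cortical-trabecular interface, R = center_radius).
    """

    steepness: float = 12000.0          # 1/m
    center_radius: float = 0.0005       # m
    amplitude_divisor: float = 3.4
    offset: float = 0.56


@dataclass(frozen=True)
class MaterialParams:
    """Density-to-stiffness law and the bone mass-density scale.

    ``E0`` is the cortical reference Young's modulus (GPa); the modulus of
    partially dense bone is ``E0 * rho**2``.  ``rho_ref`` (mg/mm^3) converts
    the dimensionless density to a mass density (1 g/cm^3 = 1 mg/mm^3).
    """

    E0: float = 20.3                    # GPa
    poisson_ratio: float = 0.3
    rho_ref: float = 1.0                # mg/mm^3

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.rho_ref <= 0:
            raise ValueError("rho_ref must be positive")

    @property
    def E0_MPa(self) -> float:
        return self.E0 * 1000.0


def density_profile(radius_mm, params: DensityProfileParams | None = None):
    """Dimensionless bone density at radius ``radius_mm`` (mm).

    Vectorized over ``radius_mm``.  Strictly increasing in radius; equals
    ``params.offset`` exactly at the interface radius.  Raises for negative
    radii (the profile is only defined on the physical domain).
    """
    if params is None:
        params = DensityProfileParams()
    r = np.asarray(radius_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    r_m = r / MM_PER_M
    out = (
        np.arctan(params.steepness * (r_m - params.center_radius))
        / params.amplitude_divisor
        + params.offset
    )
    return out if out.ndim else float(out)


def young_modulus(density, material: MaterialParams | None = None):
    """Young's modulus (GPa) for a dimensionless density, E = E0 * rho**2."""
    if material is None:
        material = MaterialParams()
    rho = np.asarray(density, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    out = material.E0 * rho**2
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Mesh:
    """Structured axisymmetric quadrilateral mesh of the (r, z) rectangle.

    Nodes are laid out row-major in z then r; elements likewise.  Element
    volumes are exact solid-of-revolution volumes ``2*pi*r_c*dr*dz`` (the
    full revolution); for a half model they cover the modeled half only.
    """

    n_r: int
    n_z: int
    outer_radius: float                 # mm
    height: float                       # mm
    node_r: np.ndarray = field(repr=False)   # (n_nodes,)
    node_z: np.ndarray = field(repr=False)
    connectivity: np.ndarray = field(repr=False)  # (n_elem, 4) counter-clockwise
    element_r: np.ndarray = field(repr=False)     # centroid radius per element
    element_z: np.ndarray = field(repr=False)
    element_volume: np.ndarray = field(repr=False)  # mm^3

    @property
    def n_nodes(self) -> int:
        return (self.n_r + 1) * (self.n_z + 1)

    @property
    def n_elements(self) -> int:
        return self.n_r * self.n_z

    @property
    def dr(self) -> float:
        return self.outer_radius / self.n_r

    @property
    def dz(self) -> float:
        return self.height / self.n_z

    def element_grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a flat per-element array to (n_z, n_r)."""
        return np.asarray(values).reshape(self.n_z, self.n_r)


def build_mesh(geometry: BoneGeometry, target_element_size: float = 0.1) -> Mesh:
    """Structured (r, z) quad mesh with edge lengths within 20% of target.

    The subdivision counts are the rounded quotients of the domain extents
    by ``target_element_size``; node coordinates are deterministic.
    """
    if target_element_size <= 0 or target_element_size > geometry.outer_radius / 2:
        raise ValueError(
            "target_element_size must be in (0, outer_radius/2]"
        )
    R = geometry.outer_radius
    H = geometry.modeled_height
    n_r = max(1, round(R / target_element_size))
    n_z = max(1, round(H / target_element_size))
    for actual in (R / n_r, H / n_z):
        if not 0.8 * target_element_size <= actual <= 1.2 * target_element_size:
            raise ValueError(
                f"cannot honour target element size {target_element_size} mm "
                f"within 20% on this geometry (got {actual:.4g} mm)"
            )
    r = np.linspace(0.0, R, n_r + 1)
    z = np.linspace(0.0, H, n_z + 1)
    zz, rr = np.meshgrid(z, r, indexing="ij")
    node_r = rr.ravel()
    node_z = zz.ravel()

    def nid(iz, ir):
        return iz * (n_r + 1) + ir

    # counter-clockwise in (r, z): (ir,iz), (ir+1,iz), (ir+1,iz+1), (ir,iz+1)
    conn = np.empty((n_r * n_z, 4), dtype=np.int64)
    e = 0
    for iz in range(n_z):
        for ir in range(n_r):
            conn[e] = (
                nid(iz, ir),
                nid(iz, ir + 1),
                nid(iz + 1, ir + 1),
                nid(iz + 1, ir),
            )
            e += 1
    dr = R / n_r
    dz = H / n_z
    elem_r = np.tile((np.arange(n_r) + 0.5) * dr, n_z)
    elem_z = np.repeat((np.arange(n_z) + 0.5) * dz, n_r)
    elem_vol = 2.0 * np.pi * elem_r * dr * dz
    return Mesh(
        n_r=n_r,
        n_z=n_z,
        outer_radius=R,
        height=H,
        node_r=node_r,
        node_z=node_z,
        connectivity=conn,
        element_r=elem_r,
        element_z=elem_z,
        element_volume=elem_vol,
    )


def initial_density_field(
    mesh: Mesh, params: DensityProfileParams | None = None
) -> np.ndarray:
    """Per-element density sampled from the radial profile at centroids."""
    return np.asarray(density_profile(mesh.element_r, params), dtype=float)


def export_profile_csv(path, params: DensityProfileParams | None = None,
                       outer_radius: float = 1.5, n: int = 151) -> None:
    """Write the radial density profile as CSV (radius_mm, density)."""
    import pandas as pd

    radii = np.linspace(0.0, outer_radius, n)
    pd.DataFrame(
        {"radius_mm": radii, "density": density_profile(radii, params)}
    ).to_csv(path, index=False)
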
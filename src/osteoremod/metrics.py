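"""Scalar and profile summaries of simulation output.

The central observable is the cortical-trabecular interface: the radius at
which the axially averaged density profile crosses the mid-density value
(0.56, the inflection value of the idealized profile).  Formation moves
this front inward (thicker cortex), resorption moves it outward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Mesh

MID_DENSITY = 0.56


@dataclass(frozen=True)
class FrontReport:
    """Summary of one finished run."""

    construction_front_radius: float    # mm (mid-density crossing, final state)
    resorption_front_radius: float      # mm (same crossing; named per direction)
    cortical_thickness: float           # mm = outer_radius - interface radius
    mean_density: float
    mean_density_change_pct: float
    all_crossings: tuple = ()           # every upward crossing, innermost first


def radial_average_profile(field, mesh: Mesh):
    """Volume-weighted axial average of a per-element field per radial column.

    Element volumes within one column are equal, so the weighted mean
    reduces to the plain axial mean.  Returns ``(radii, values)`` at the
    element-centroid radii.
    """
    values = np.asarray(field, dtype=float)
    if mesh.n_elements == 0:
        raise ValueError("empty mesh")
    grid = mesh.element_grid(values)
    return mesh.element_r[: mesh.n_r].copy(), grid.mean(axis=0)


def _upward_crossings(radii, values, threshold):
    radii = np.asarray(radii, float)
    values = np.asarray(values, float)
    out = []
    for i in range(len(radii) - 1):
        lo, hi = values[i], values[i + 1]
        if lo < threshold <= hi:
            t = (threshold - lo) / (hi - lo)
            out.append(float(radii[i] + t * (radii[i + 1] - radii[i])))
    return out


def interface_radius(radii, profile, threshold: float = MID_DENSITY) -> float:
    """Smallest radius where the profile crosses ``threshold`` from below.

    Linear interpolation between profile samples.  Raises ``ValueError``
    when the profile never crosses the threshold (fully formed or fully
    resorbed domain).
    """
    crossings = _upward_crossings(radii, profile, threshold)
    if not crossings:
        raise ValueError(
            f"density profile does not cross the threshold {threshold} from below"
        )
    return crossings[0]


def volume_averaged_density(field, mesh: Mesh) -> float:
    """Solid-of-revolution volume average of a per-element field."""
    values = np.asarray(field, dtype=float)
    return float(values @ mesh.element_volume / mesh.element_volume.sum())


def front_report(result, threshold: float = MID_DENSITY) -> FrontReport:
    """Interface position, cortical thickness and mean-density change of a run."""
    if len(result.density_snapshots) < 2:
        raise ValueError("need at least two snapshots to report remodeling fronts")
    mesh = result.mesh
    radii, prof = radial_average_profile(result.final_state.density, mesh)
    crossings = _upward_crossings(radii, prof, threshold)
    if not crossings:
        raise ValueError(
            f"final profile does not cross the threshold {threshold} from below"
        )
    front = crossings[0]
    mean0 = volume_averaged_density(result.initial_density, mesh)
    mean1 = volume_averaged_density(result.final_state.density, mesh)
    return FrontReport(
        construction_front_radius=front,
        resorption_front_radius=front,
        cortical_thickness=result.geometry.outer_radius - front,
        mean_density=mean1,
        mean_density_change_pct=100.0 * (mean1 / mean0 - 1.0),
        all_crossings=tuple(crossings),
    )
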
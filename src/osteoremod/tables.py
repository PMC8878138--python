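"""Readers for the packaged study tables (printed-precision CSV fixtures)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import GroupObservation
from .remodeling import ActivityParams, ModulationParams


def _read(name: str) -> pd.DataFrame:
    with resources.files("osteoremod.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_group_observations() -> tuple:
    """Cortical-thickness observations of the three study groups."""
    df = _read("group_thickness.csv")
    return tuple(
        GroupObservation(
            row["group"],
            float(row["mean_thickness_um"]),
            float(row["sd_um"]),
            float(row["duration_days"]),
        )
        for _, row in df.iterrows()
    )


def load_activity_params() -> ActivityParams:
    """Cell-activity law parameters (slopes, caps, energy thresholds)."""
    vals = dict(zip(_read("activity_params.csv")["parameter"],
                    _read("activity_params.csv")["value"]))
    return ActivityParams(
        k1=float(vals["k1"]), k2=float(vals["k2"]),
        A1=float(vals["A1"]), A2=float(vals["A2"]),
        W0=float(vals["W0"]), W1=float(vals["W1"]),
        W2=float(vals["W2"]), W3=float(vals["W3"]),
    )


def load_modulation_params() -> ModulationParams:
    """Tuned (alpha - rho)^n modulation parameters."""
    df = _read("modulation_params.csv")
    vals = dict(zip(df["parameter"], df["value"]))
    return ModulationParams(
        alpha_ob_W1=float(vals["alpha_ob_W1"]),
        alpha_oc_W1=float(vals["alpha_oc_W1"]),
        alpha_ob_W3=float(vals["alpha_ob_W3"]),
        alpha_oc_W3=float(vals["alpha_oc_W3"]),
        n_W1=float(vals["n_W1"]),
        n_W3=float(vals["n_W3"]),
    )
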
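"""Volume-weighted wood density (VWWD) and volume-to-biomass conversion.

A single wood-density value multiplied by a whole-tree volume only yields the
true dry biomass when that value weights each part of the tree by its share
of the volume. The compartment contribution is

    VWWD_c = WD_c * V_c / V_obs

and the tree-level estimator is the sum over compartments,
VWWD = sum_c WD_c * V_c / V_obs, so that V_obs * VWWD recovers AGB_obs
exactly on a tree whose compartment masses are built from volumes. Using a
basal or database species-average WD instead propagates the vertical WD
gradient into a systematic biomass error, which is what the correction
models in :mod:`woodgrad.biascorr` remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AGBEstimate",
    "WD_SOURCES",
    "compartment_vwwd",
    "tree_vwwd",
    "convert_volume_to_agb",
    "tree_vwwd_table",
    "agb_estimates_table",
]

#: Recognised provenance tags for the WD used in a conversion.
WD_SOURCES = ("WD_GWD", "WD_Stu", "VWWD", "VWWD_model")


@dataclass(frozen=True)
class AGBEstimate:
    """A volume-to-mass conversion tagged with the WD value's provenance."""

    tree_id: str
    wd_source: str
    AGB_est: float  # g

    def __post_init__(self) -> None:
        if self.wd_source not in WD_SOURCES:
            raise ValueError(
                f"wd_source must be one of {WD_SOURCES}, got {self.wd_source!r}"
            )
        if self.AGB_est < 0:
            raise ValueError("AGB_est must be non-negative")


def compartment_vwwd(WD_c: float, V_c: float, V_obs: float) -> float:
    """Compartment contribution WD_c * V_c / V_obs to the tree VWWD."""
    if V_c <= 0:
        raise ValueError(f"compartment volume must be positive, got {V_c}")
    if V_c > V_obs:
        raise ValueError(
            f"compartment volume V_c={V_c} exceeds tree volume V_obs={V_obs}"
        )
    return WD_c * V_c / V_obs


def tree_vwwd(WD_c, V_c) -> float:
    """Volume-weighted tree wood density: sum_c WD_c*V_c / sum_c V_c.

    Accepts parallel arrays (or anything array-like) of compartment WD and
    fresh volume. Always lies between min(WD_c) and max(WD_c).
    """
    wd = np.asarray(WD_c, dtype=float)
    v = np.asarray(V_c, dtype=float)
    if wd.size == 0:
        raise ValueError("tree_vwwd requires at least one compartment")
    if wd.shape != v.shape:
        raise ValueError("WD_c and V_c must have the same length")
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("volumes must be non-negative with positive total")
    return float(np.sum(wd * v) / np.sum(v))


def convert_volume_to_agb(
    V_obs: float, wd: float, source: str, tree_id: str = ""
) -> AGBEstimate:
    """Convert a tree volume (cm^3) to dry biomass (g) with one WD value."""
    if V_obs <= 0:
        raise ValueError(f"V_obs must be positive, got {V_obs}")
    if wd <= 0:
        raise ValueError(f"wood density must be positive, got {wd}")
    return AGBEstimate(tree_id=tree_id, wd_source=source, AGB_est=V_obs * wd)


# ---------------------------------------------------------------------------
# Table-level wrappers
# ---------------------------------------------------------------------------

def tree_vwwd_table(trees: pd.DataFrame, compartments: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``VWWD`` column to the tree table from the compartment table."""
    agg = compartments.groupby("tree_id", observed=True).apply(
        lambda g: np.sum(g["WD_c"] * g["V_c"]) / np.sum(g["V_c"]),
        include_groups=False,
    )
    out = trees.copy()
    out["VWWD"] = out["tree_id"].map(agg)
    return out


def agb_estimates_table(
    trees: pd.DataFrame,
    wd_source: str,
    species: pd.DataFrame | None = None,
    wd_values: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-tree AGB estimates from V_obs and one choice of WD.

    ``wd_source`` selects the WD column: ``"WD_Stu"`` or ``"VWWD"`` from the
    tree table, ``"WD_GWD"`` looked up by exact ``species_id`` match in the
    species table, or ``"VWWD_model"`` with explicitly supplied ``wd_values``
    (e.g. predictions from a correction model).
    """
    id_cols = [c for c in ("tree_id", "species_id", "site") if c in trees.columns]
    out = trees[id_cols + ["V_obs", "AGB_obs"]].copy()
    if wd_source == "WD_GWD":
        if species is None:
            raise ValueError("WD_GWD conversion requires the species table")
        lookup = species.set_index("species_id")["WD_GWD"]
        missing = set(out["species_id"]) - set(lookup.index)
        if missing:
            raise KeyError(f"species without WD_GWD entry: {sorted(missing)}")
        wd = out["species_id"].map(lookup).to_numpy(dtype=float)
    elif wd_source in ("WD_Stu", "VWWD"):
        wd = trees[wd_source].to_numpy(dtype=float)
    elif wd_source == "VWWD_model":
        if wd_values is None:
            raise ValueError("VWWD_model conversion requires wd_values")
        wd = np.asarray(wd_values, dtype=float)
        if wd.shape[0] != len(out):
            raise ValueError("wd_values length does not match tree table")
    else:
        raise ValueError(f"unknown wd_source {wd_source!r}")
    if np.any(wd <= 0):
        raise ValueError("all WD values must be positive")
    out["wd_used"] = wd
    out["wd_source"] = wd_source
    out["AGB_est"] = out["V_obs"].to_numpy(dtype=float) * wd
    return out
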
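"""Laboratory and field calculations: from wedge samples and log measurements
to compartment wood properties, volumes, dry biomass and tree-level totals.

Internal units are fixed: grams, centimetres, cm^3 and g.cm^-3 throughout;
heights and crown radii at tree level are in metres. Conversion to kg or Mg
is left to reporting code.

The chain implemented here mirrors standard destructive-sampling practice:

* each wedge sample yields basic wood density ``WD_i = m_d / v_f``, moisture
  content ``MC_i = (m_d - m_f) / m_f`` (negative, since dry mass < fresh
  mass) and the fresh biomass-to-volume ratio ``BV_i = v_f / m_f``;
* sample properties are averaged (unweighted) per compartment;
* field-weighed parts convert fresh mass to dry mass via ``1 + MC_c`` and to
  fresh volume via ``BV_c``; large parts measured as truncated-cone logs
  convert frustum volume to dry mass via ``WD_c``;
* compartment volumes and dry masses are summed to tree totals ``V_obs``
  and ``AGB_obs``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import COMPARTMENTS, RANK, STEM, STEM_BASE, STUMP, validate_compartment

__all__ = [
    "WoodSample",
    "LogMeasurement",
    "CompartmentSummary",
    "TreeStructure",
    "TreeRecord",
    "sample_properties",
    "truncated_cone_volume",
    "summarize_compartment",
    "tree_totals",
    "process_tables",
    "MissingStumpError",
]


class MissingStumpError(ValueError):
    """Raised when a tree has no stump compartment (WD_Stu is required)."""


@dataclass(frozen=True)
class WoodSample:
    """One wedge-shaped wood sample: fresh mass/volume and oven-dry mass."""

    tree_id: str
    compartment: str
    m_f: float  # fresh mass, g
    v_f: float  # fresh volume, cm^3
    m_d: float  # oven-dry mass, g

    def __post_init__(self) -> None:
        validate_compartment(self.compartment)
        if self.m_f <= 0 or self.v_f <= 0:
            raise ValueError(
                f"sample {self.tree_id}/{self.compartment}: fresh mass and "
                f"volume must be positive (m_f={self.m_f}, v_f={self.v_f})"
            )
        if self.m_d <= 0:
            raise ValueError(
                f"sample {self.tree_id}/{self.compartment}: dry mass must be positive"
            )


@dataclass(frozen=True)
class LogMeasurement:
    """One field measurement of a tree part.

    ``kind`` is one of:

    * ``"weighed"`` -- the part was weighed fresh in the field
      (``fresh_mass`` in g);
    * ``"coned"`` -- the part was measured as a truncated cone
      (end radii ``r1``, ``r2`` and length ``h``, all in cm);
    * ``"volume"`` -- a directly supplied fresh volume in cm^3 (e.g. an
      irregular stump whose cross-section area was measured separately).
    """

    tree_id: str
    compartment: str
    kind: str
    fresh_mass: float | None = None
    r1: float | None = None
    r2: float | None = None
    h: float | None = None
    volume: float | None = None

    def __post_init__(self) -> None:
        validate_compartment(self.compartment)
        if self.kind == "weighed":
            if self.fresh_mass is None or self.fresh_mass <= 0:
                raise ValueError("weighed log requires fresh_mass > 0")
        elif self.kind == "coned":
            if self.r1 is None or self.r2 is None or self.h is None:
                raise ValueError("coned log requires r1, r2 and h")
            if self.r1 < 0 or self.r2 < 0 or (self.r1 == 0 and self.r2 == 0):
                raise ValueError("coned log radii must be >= 0 and not both zero")
            if self.h <= 0:
                raise ValueError("coned log length h must be positive")
        elif self.kind == "volume":
            if self.volume is None or self.volume <= 0:
                raise ValueError("volume log requires volume > 0")
        else:
            raise ValueError(f"unknown log kind {self.kind!r}")


@dataclass
class CompartmentSummary:
    """Compartment-level wood properties, fresh volume and dry biomass."""

    tree_id: str
    compartment: str
    WD_c: float  # g.cm^-3
    MC_c: float  # dimensionless, in (-1, 0]
    BV_c: float  # cm^3.g^-1
    V_c: float = 0.0  # cm^3
    AGB_c: float = 0.0  # g
    n_samples: int = 0
    imputed: bool = False


@dataclass(frozen=True)
class TreeStructure:
    """Tree-level structural measurements taken before felling."""

    tree_id: str
    species_id: str
    site: str
    DBH: float  # cm
    H: float  # total height, m
    Ht: float  # trunk height, m
    Cr: float  # crown radius, m

    def __post_init__(self) -> None:
        if self.DBH <= 0:
            raise ValueError(f"tree {self.tree_id}: DBH must be positive")
        if self.H <= 0 or self.Ht <= 0:
            raise ValueError(f"tree {self.tree_id}: heights must be positive")
        if self.Ht > self.H + 1e-9:
            raise ValueError(
                f"tree {self.tree_id}: trunk height Ht={self.Ht} exceeds total height H={self.H}"
            )


@dataclass
class TreeRecord:
    """Tree-level totals and derived quantities used downstream."""

    tree_id: str
    species_id: str
    site: str
    DBH: float
    H: float
    Ht: float
    Cr: float
    Sm: float  # trunk height / total height
    V_obs: float  # cm^3
    AGB_obs: float  # g
    WD_Stu: float  # stump compartment WD, g.cm^-3
    VWWD: float = float("nan")  # filled by the vwwd stage
    compartments: dict[str, CompartmentSummary] = field(default_factory=dict)


def sample_properties(
    sample: WoodSample, *, strict: bool = False
) -> tuple[float, float, float]:
    """Compute (WD_i, MC_i, BV_i) for one wedge sample.

    WD_i = m_d/v_f (g.cm^-3), MC_i = (m_d - m_f)/m_f (negative) and
    BV_i = v_f/m_f (cm^3.g^-1). A dry mass exceeding the fresh mass is
    physically impossible and raises if ``strict``, otherwise warns.
    """
    if sample.m_d > sample.m_f:
        msg = (
            f"sample {sample.tree_id}/{sample.compartment}: dry mass "
            f"{sample.m_d} g exceeds fresh mass {sample.m_f} g"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    wd = sample.m_d / sample.v_f
    mc = (sample.m_d - sample.m_f) / sample.m_f
    bv = sample.v_f / sample.m_f
    return wd, mc, bv


def truncated_cone_volume(r1: float, r2: float, h: float) -> float:
    """Volume of a truncated cone (frustum) with end radii r1, r2 and length h.

    V = pi * h / 3 * (r1^2 + r1*r2 + r2^2). Symmetric in (r1, r2); reduces
    to a cylinder for r1 == r2 and to a cone for r2 == 0.
    """
    if h <= 0:
        raise ValueError(f"log length h must be positive, got {h}")
    if r1 < 0 or r2 < 0:
        raise ValueError("radii must be non-negative")
    return math.pi * h / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)


def _log_volume_and_mass(
    log: LogMeasurement, WD_c: float, MC_c: float, BV_c: float
) -> tuple[float, float]:
    """Fresh volume (cm^3) and dry mass (g) of one log given compartment means."""
    if log.kind == "weighed":
        dry = log.fresh_mass * (1.0 + MC_c)
        vol = log.fresh_mass * BV_c
    else:
        vol = (
            log.volume
            if log.kind == "volume"
            else truncated_cone_volume(log.r1, log.r2, log.h)
        )
        dry = vol * WD_c
    return vol, dry


def summarize_compartment(
    samples: list[WoodSample],
    logs: list[LogMeasurement] | None = None,
    *,
    strict: bool = False,
) -> CompartmentSummary:
    """Average sample properties and convert this compartment's logs.

    WD_c, MC_c and BV_c are unweighted arithmetic means over the wedge
    samples. Each weighed log contributes dry mass ``fresh_mass*(1+MC_c)``
    and fresh volume ``fresh_mass*BV_c``; each coned (or direct-volume) log
    contributes its frustum (or supplied) volume and dry mass
    ``volume * WD_c``. V_c and AGB_c sum over logs.
    """
    if not samples:
        raise ValueError("summarize_compartment requires at least one sample")
    tree_ids = {s.tree_id for s in samples}
    comps = {s.compartment for s in samples}
    if logs:
        tree_ids |= {l.tree_id for l in logs}
        comps |= {l.compartment for l in logs}
    if len(tree_ids) > 1:
        raise ValueError(f"mixed tree_ids in one compartment: {sorted(tree_ids)}")
    if len(comps) > 1:
        raise ValueError(f"mixed compartments: {sorted(comps)}")

    props = np.array([sample_properties(s, strict=strict) for s in samples])
    WD_c, MC_c, BV_c = props.mean(axis=0)
    if not (-1.0 < MC_c <= 0.0):
        warnings.warn(
            f"compartment {samples[0].tree_id}/{samples[0].compartment}: "
            f"MC_c={MC_c:.3f} outside (-1, 0]",
            stacklevel=2,
        )

    V_c = 0.0
    AGB_c = 0.0
    for log in logs or []:
        vol, dry = _log_volume_and_mass(log, WD_c, MC_c, BV_c)
        V_c += vol
        AGB_c += dry

    return CompartmentSummary(
        tree_id=samples[0].tree_id,
        compartment=samples[0].compartment,
        WD_c=float(WD_c),
        MC_c=float(MC_c),
        BV_c=float(BV_c),
        V_c=V_c,
        AGB_c=AGB_c,
        n_samples=len(samples),
    )


def tree_totals(
    compartments: list[CompartmentSummary], structure: TreeStructure
) -> TreeRecord:
    """Sum compartment volumes/biomass into a TreeRecord.

    Requires a stump compartment (its WD_c becomes WD_Stu, the basal wood
    density used by the correction models).
    """
    if not compartments:
        raise ValueError("tree_totals requires at least one compartment")
    by_name = {c.compartment: c for c in compartments}
    if len(by_name) != len(compartments):
        raise ValueError("duplicate compartments for one tree")
    if STUMP not in by_name:
        raise MissingStumpError(
            f"tree {structure.tree_id}: stump compartment absent; WD_Stu undefined"
        )
    V_obs = sum(c.V_c for c in compartments)
    AGB_obs = sum(c.AGB_c for c in compartments)
    return TreeRecord(
        tree_id=structure.tree_id,
        species_id=structure.species_id,
        site=structure.site,
        DBH=structure.DBH,
        H=structure.H,
        Ht=structure.Ht,
        Cr=structure.Cr,
        Sm=structure.Ht / structure.H,
        V_obs=V_obs,
        AGB_obs=AGB_obs,
        WD_Stu=by_name[STUMP].WD_c,
        compartments=by_name,
    )


# ---------------------------------------------------------------------------
# Table-level processing (the `process` pipeline stage)
# ---------------------------------------------------------------------------

def process_tables(
    samples: pd.DataFrame,
    logs: pd.DataFrame,
    trees: pd.DataFrame,
    *,
    impute_stem_base: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the sample -> compartment -> tree chain over delimited tables.

    Parameters
    ----------
    samples
        Columns ``tree_id, compartment, m_f, v_f, m_d``.
    logs
        Columns ``tree_id, compartment, kind, fresh_mass, r1, r2, h, volume``
        (irrelevant fields empty/NaN).
    trees
        Columns ``tree_id, species_id, site, DBH, H, Ht, Cr``.
    impute_stem_base
        When a tree has stem-base (Ste_b) logs but no Ste_b wedge samples,
        impute its WD/MC/BV as the mean of the stump and stem values (the
        stem base is physically intermediate) and flag the row.

    Returns
    -------
    (compartments_df, trees_df)
        Per-compartment summaries (with an ``imputed`` flag) and the tree
        table enriched with ``Sm, V_obs, AGB_obs, WD_Stu, VWWD``.
    """
    comp_rows: list[CompartmentSummary] = []
    tree_rows: list[dict] = []

    samples_by_tree = {k: g for k, g in samples.groupby("tree_id")}
    logs_by_tree = {k: g for k, g in logs.groupby("tree_id")}

    for t in trees.itertuples(index=False):
        structure = TreeStructure(
            tree_id=str(t.tree_id),
            species_id=str(t.species_id),
            site=str(t.site),
            DBH=float(t.DBH),
            H=float(t.H),
            Ht=float(t.Ht),
            Cr=float(t.Cr),
        )
        s_tree = samples_by_tree.get(str(t.tree_id))
        l_tree = logs_by_tree.get(str(t.tree_id))
        if s_tree is None or l_tree is None:
            warnings.warn(f"tree {t.tree_id}: no samples or logs; skipped", stacklevel=2)
            continue

        comps: list[CompartmentSummary] = []
        sampled = set(s_tree["compartment"])
        for comp, l_grp in l_tree.groupby("compartment"):
            log_objs = [
                LogMeasurement(
                    tree_id=str(r.tree_id),
                    compartment=str(r.compartment),
                    kind=str(r.kind),
                    fresh_mass=None if pd.isna(r.fresh_mass) else float(r.fresh_mass),
                    r1=None if pd.isna(r.r1) else float(r.r1),
                    r2=None if pd.isna(r.r2) else float(r.r2),
                    h=None if pd.isna(r.h) else float(r.h),
                    volume=None if pd.isna(r.volume) else float(r.volume),
                )
                for r in l_grp.itertuples(index=False)
            ]
            if comp in sampled:
                s_grp = s_tree[s_tree["compartment"] == comp]
                sample_objs = [
                    WoodSample(str(r.tree_id), str(r.compartment), float(r.m_f),
                               float(r.v_f), float(r.m_d))
                    for r in s_grp.itertuples(index=False)
                ]
                comps.append(summarize_compartment(sample_objs, log_objs))
            elif comp == STEM_BASE and impute_stem_base:
                comps.append(_impute_stem_base(str(t.tree_id), s_tree, log_objs))
            else:
                warnings.warn(
                    f"tree {t.tree_id}: compartment {comp} has logs but no samples; dropped",
                    stacklevel=2,
                )
        record = tree_totals(comps, structure)
        comp_rows.extend(comps)
        tree_rows.append(
            {
                "tree_id": record.tree_id,
                "species_id": record.species_id,
                "site": record.site,
                "DBH": record.DBH,
                "H": record.H,
                "Ht": record.Ht,
                "Cr": record.Cr,
                "Sm": record.Sm,
                "V_obs": record.V_obs,
                "AGB_obs": record.AGB_obs,
                "WD_Stu": record.WD_Stu,
            }
        )

    comp_df = pd.DataFrame(
        {
            "tree_id": [c.tree_id for c in comp_rows],
            "compartment": [c.compartment for c in comp_rows],
            "WD_c": [c.WD_c for c in comp_rows],
            "MC_c": [c.MC_c for c in comp_rows],
            "BV_c": [c.BV_c for c in comp_rows],
            "V_c": [c.V_c for c in comp_rows],
            "AGB_c": [c.AGB_c for c in comp_rows],
            "n_samples": [c.n_samples for c in comp_rows],
            "imputed": [c.imputed for c in comp_rows],
        }
    )
    comp_df["compartment"] = pd.Categorical(
        comp_df["compartment"], categories=COMPARTMENTS, ordered=True
    )
    trees_df = pd.DataFrame(tree_rows)

    # tree-level VWWD from the compartment table (volume-weighted WD mean)
    from .vwwd import tree_vwwd_table

    trees_df = tree_vwwd_table(trees_df, comp_df)
    return comp_df, trees_df


def _impute_stem_base(
    tree_id: str, s_tree: pd.DataFrame, log_objs: list[LogMeasurement]
) -> CompartmentSummary:
    """Stand-in Ste_b properties: mean of the tree's Stu and Ste sample means."""
    props = {}
    for comp in (STUMP, STEM):
        grp = s_tree[s_tree["compartment"] == comp]
        if grp.empty:
            raise MissingStumpError(
                f"tree {tree_id}: cannot impute Ste_b without both Stu and Ste samples"
            )
        vals = np.array(
            [
                sample_properties(
                    WoodSample(tree_id, comp, float(r.m_f), float(r.v_f), float(r.m_d))
                )
                for r in grp.itertuples(index=False)
            ]
        )
        props[comp] = vals.mean(axis=0)
    WD_c, MC_c, BV_c = (props[STUMP] + props[STEM]) / 2.0
    V_c = 0.0
    AGB_c = 0.0
    for log in log_objs:
        vol, dry = _log_volume_and_mass(log, WD_c, MC_c, BV_c)
        V_c += vol
        AGB_c += dry
    return CompartmentSummary(
        tree_id=tree_id,
        compartment=STEM_BASE,
        WD_c=float(WD_c),
        MC_c=float(MC_c),
        BV_c=float(BV_c),
        V_c=V_c,
        AGB_c=AGB_c,
        n_samples=0,
        imputed=True,
    )
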
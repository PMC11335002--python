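"""Post-processing of raw bending results into per-joint functional
summaries.

Raw experiment tables carry one ROM record per joint x direction x
parameter variant. Processing follows the field's conventions:

* the most permissive intersection-threshold variants (0.75%) are dropped
  before aggregation (joints typically disarticulate in axial rotation
  before reaching that threshold);
* lateroflexion and axial rotation are averaged across left and right and
  multiplied by two (full amplitude); on asymmetrically damaged joints the
  intact side alone is doubled;
* sagittal ROM is the sum of dorsoflexion and ventroflexion;
* values are then averaged across the surviving parameter variants.

Ternary proportions express each joint's lateral/sagittal/axial ROM as a
fraction of its total, with joints classed sagittal-dominant when the
sagittal share of the sagittal+lateral pair exceeds 50%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .column import ColumnModel

logger = logging.getLogger(__name__)

DROP_THRESHOLD = 0.0075  # removed a posteriori before aggregation


@dataclass
class TernaryPoint:
    p_lateral: float
    p_sagittal: float
    p_axial: float
    klass: str  # sagittal-dominant | lateral-dominant
    dominant: str  # direction with the largest share

    def __post_init__(self) -> None:
        total = self.p_lateral + self.p_sagittal + self.p_axial
        if abs(total - 1.0) > 1e-12:
            raise ValueError("ternary proportions must sum to 1")


def process_rom(
    raw: pd.DataFrame,
    damage: dict[int, str] | None = None,
    drop_threshold: float | None = DROP_THRESHOLD,
) -> pd.DataFrame:
    """Collapse a raw result table to per-joint lateral/sagittal/axial ROM.

    ``damage`` maps joint index to {"none", "left", "right", "both"}; both-
    sides-damaged joints are excluded with a notice. Returns one row per
    joint with columns lateral/sagittal/axial (degrees), n_variants and the
    drop flag.
    """
    damage = damage or {}
    df = raw.copy()
    df = df[~df["limiting_constraint"].astype(str).str.startswith("error")]
    if drop_threshold is not None:
        df = df[~np.isclose(df["threshold"], drop_threshold)]
    rows = []
    for joint, sub in df.groupby("joint"):
        side = damage.get(int(joint), "none")
        if side == "both":
            logger.warning("joint %s damaged on both sides; excluded", joint)
            continue
        by_dir = sub.groupby("direction")["rom_deg"].mean()
        required = {"dorsoflexion", "ventroflexion"}
        if not required.issubset(by_dir.index):
            logger.warning("joint %s lacks sagittal directions; excluded", joint)
            continue

        def symmetric(left_key: str, right_key: str) -> float:
            if side == "left":  # left damaged: intact right side doubled
                return 2.0 * by_dir[right_key]
            if side == "right":
                return 2.0 * by_dir[left_key]
            return by_dir[left_key] + by_dir[right_key]  # = mean x 2

        rows.append(
            dict(
                joint=int(joint),
                lateral=symmetric("left_lateroflexion", "right_lateroflexion"),
                axial=symmetric("left_axial", "right_axial"),
                sagittal=by_dir["dorsoflexion"] + by_dir["ventroflexion"],
                n_variants=int(
                    sub.groupby(["spacing_mult", "threshold", "strain_allow"]).ngroups
                ),
                dropped_threshold=drop_threshold,
            )
        )
    return pd.DataFrame(rows).set_index("joint") if rows else pd.DataFrame(
        columns=["lateral", "axial", "sagittal", "n_variants", "dropped_threshold"]
    )


def ternary_proportions(lateral: float, sagittal: float, axial: float) -> TernaryPoint:
    """Proportion of each bending direction in total ROM, with the
    sagittal-lateral 50% classification."""
    total = lateral + sagittal + axial
    if total <= 0:
        raise ValueError("total ROM is zero; ternary point undefined")
    p_lat, p_sag, p_ax = lateral / total, sagittal / total, axial / total
    sl = sagittal + lateral
    # a tie at exactly 50% is classed lateral-dominant (the sagittal class
    # requires a share strictly greater than one half)
    klass = "sagittal-dominant" if sl > 0 and sagittal / sl > 0.5 else "lateral-dominant"
    dominant = ("lateral", "sagittal", "axial")[int(np.argmax([p_lat, p_sag, p_ax]))]
    return TernaryPoint(p_lat, p_sag, p_ax, klass, dominant)


def ternary_table(processed: pd.DataFrame) -> pd.DataFrame:
    """Per-joint ternary proportions of a processed ROM table."""
    rows = []
    for joint, r in processed.iterrows():
        try:
            t = ternary_proportions(r["lateral"], r["sagittal"], r["axial"])
        except ValueError:
            logger.warning("joint %s has zero total ROM; excluded from ternary", joint)
            continue
        rows.append(
            dict(
                joint=joint,
                p_lateral=t.p_lateral,
                p_sagittal=t.p_sagittal,
                p_axial=t.p_axial,
                klass=t.klass,
                dominant=t.dominant,
            )
        )
    return pd.DataFrame(rows).set_index("joint")


def assign_regions(
    n_joints: int, group: str, diaphragmatic_joint: int | None = None
) -> pd.Series:
    """Anterior/posterior region labels per joint (1-based index).

    Mammals split at the diaphragmatic joint (inclusive on the anterior
    side); other groups split at the mid-dorsal position (floor(n/2)).
    """
    if group == "mammal":
        if diaphragmatic_joint is None:
            raise ValueError("mammal columns need a diaphragmatic joint position")
        boundary = int(diaphragmatic_joint)
    else:
        boundary = n_joints // 2
    labels = ["anterior" if j <= boundary else "posterior" for j in range(1, n_joints + 1)]
    return pd.Series(labels, index=pd.RangeIndex(1, n_joints + 1, name="joint"))


def column_regions(column: ColumnModel) -> pd.Series:
    return assign_regions(column.n_joints, column.group, column.diaphragmatic_joint)


def craniocaudal_profile(
    values: pd.Series | np.ndarray, degree: int = 3
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares polynomial fit of a per-joint quantity along the column.

    Returns ``(fitted values at the joint positions, coefficients,
    residual RMS)``; the degree is reduced with a warning when there are
    fewer than degree+1 joints.
    """
    y = np.asarray(values, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float)
    if len(y) == 0:
        raise ValueError("no joints to fit")
    deg = min(degree, len(y) - 1)
    if deg < degree:
        warnings.warn(f"polynomial degree reduced from {degree} to {deg} ({len(y)} joints)")
    coeffs = np.polyfit(x, y, deg)
    fitted = np.polyval(coeffs, x)
    rms = float(np.sqrt(np.mean((fitted - y) ** 2)))
    return fitted, coeffs, rms


def summarize_constraints(raw: pd.DataFrame) -> pd.DataFrame:
    """Contingency counts of the limiting constraint per species and
    bending direction (over all joints and parameter variants)."""
    df = raw[~raw["limiting_constraint"].astype(str).str.startswith("error")]
    out = (
        df.groupby(["species", "direction", "limiting_constraint"])
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def summary_table(
    column: ColumnModel,
    raw: pd.DataFrame,
    stiffness: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-joint summary: processed ROM, ternary point, region label
    and (optionally) relative stiffness, ready for statistics or export."""
    processed = process_rom(raw, damage=column.damage())
    tern = ternary_table(processed)
    regions = column_regions(column)
    out = processed.join(tern, how="left")
    out["region"] = regions.reindex(out.index)
    out["species"] = column.species
    out["group"] = column.group
    if stiffness is not None:
        out = out.join(stiffness, how="left")
    return out
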
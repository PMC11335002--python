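"""Relative intervertebral stiffness.

Stiffness is approximated as the ratio of a bending-moment proxy to angular
displacement (the processed ROM), size-corrected so only relative
comparisons are meaningful. The moment proxy is the bending lever arm
(COR to arch apex for sagittal bending, COR to the lateral centrum edge
for lateral bending) scaled by the centrum endplate area; dividing by the
mean centrum length cubed renders it dimensionless, making the estimate
invariant under isotropic scaling of the joint (the exponent is exposed
for sensitivity analyses).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .column import ColumnModel

logger = logging.getLogger(__name__)


def bending_moment_proxy(lever: float, centrum_area: float) -> float:
    """Moment proxy (mm^3): lever arm (mm) x centrum area (mm^2)."""
    if not (lever > 0 and centrum_area > 0):
        raise ValueError("lever and centrum area must be positive")
    return lever * centrum_area


def relative_stiffness(
    moment_proxy: float,
    rom_deg: float,
    mean_centrum_length: float,
    size_exponent: float = 3.0,
) -> float:
    """Dimensionless relative stiffness: size-corrected moment / ROM.

    Zero ROM yields an infinite-stiffness sentinel (``inf``) which
    downstream summaries exclude.
    """
    if not mean_centrum_length > 0:
        raise ValueError("mean centrum length must be positive")
    if rom_deg < 0:
        raise ValueError("ROM must be non-negative")
    corrected = moment_proxy / mean_centrum_length**size_exponent
    if rom_deg == 0:
        logger.warning("zero ROM: infinite-stiffness sentinel")
        return float("inf")
    return corrected / rom_deg


def stiffness_table(
    column: ColumnModel, processed_rom: pd.DataFrame, size_exponent: float = 3.0
) -> pd.DataFrame:
    """Per-joint lateral/sagittal relative stiffness with ratio and total.

    Joins the column's lever arms and centrum metrics to a processed ROM
    table (index = joint). Joints with an infinite component are flagged
    and excluded from ratio/total.
    """
    rows = []
    for joint in column.joints:
        k = joint.joint_index
        if k not in processed_rom.index:
            logger.warning("joint %d missing from processed ROM; skipped", k)
            continue
        rom_lat = float(processed_rom.loc[k, "lateral"])
        rom_sag = float(processed_rom.loc[k, "sagittal"])
        s_lat = relative_stiffness(
            bending_moment_proxy(joint.lever_lateral, joint.centrum_area),
            rom_lat,
            joint.mean_centrum_length,
            size_exponent,
        )
        s_sag = relative_stiffness(
            bending_moment_proxy(joint.lever_sagittal, joint.centrum_area),
            rom_sag,
            joint.mean_centrum_length,
            size_exponent,
        )
        finite = np.isfinite(s_lat) and np.isfinite(s_sag)
        rows.append(
            dict(
                joint=k,
                stiffness_lateral=s_lat,
                stiffness_sagittal=s_sag,
                stiffness_ratio=(s_lat / s_sag) if finite else np.nan,
                stiffness_total=(s_lat + s_sag) if finite else np.nan,
            )
        )
    return pd.DataFrame(rows).set_index("joint")


def stiffness_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Ratio (lateral/sagittal) and total (lateral+sagittal) per joint from
    a table with stiffness_lateral/stiffness_sagittal columns; rows with a
    missing or infinite component are skipped with a notice."""
    out = records.copy()
    bad = ~(
        np.isfinite(out["stiffness_lateral"]) & np.isfinite(out["stiffness_sagittal"])
    )
    if bad.any():
        logger.warning("%d joints with missing/infinite stiffness skipped", int(bad.sum()))
    out = out[~bad]
    out["stiffness_ratio"] = out["stiffness_lateral"] / out["stiffness_sagittal"]
    out["stiffness_total"] = out["stiffness_lateral"] + out["stiffness_sagittal"]
    return out
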
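"""Digital bending experiments.

For each intervertebral joint the posterior vertebra is rotated about the
joint COR in six directions (dorsoflexion, ventroflexion, left/right
lateroflexion, left/right axial rotation) in fixed angular increments
(default 0.5 degrees) until a constraint on motion is violated:

* **bone** — the overlap fraction of the two vertebrae exceeds the
  intersection threshold (a small overlap is permitted so facets can slide
  past one another). A pose with exact surface contact but negligible
  overlap volume counts as overlapping, so a zero threshold means "first
  contact".
* **disc** — the relative length change of an endplate locator pair
  exceeds the strain allowance (default 50% of neutral length, in both
  tension and compression).
* **capsule** — likewise for the zygapophyseal locator pairs.

ROM in a direction is the largest swept angle at which no constraint is
violated, capped at ``max_angle`` (90 degrees). Loss of all zygapophyseal
facet overlap (projected along the neutral facet normal) is recorded as
disarticulation but does not stop the sweep.

A full experiment crosses three joint spacings (optimal x 0.9/1.0/1.1),
three intersection thresholds (0.25/0.5/0.75% of the mean vertebral
measure) and three strain allowances (45/50/55%) into 27 parameter
variants per joint and direction.
"""

from __future__ import annotations

import itertools
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import _kernel, mesh as _mesh
from .column import ColumnModel, JointModel, assemble_column

logger = logging.getLogger(__name__)

#: direction name -> (frame axis, sign) for right-handed rotation of the
#: posterior vertebra; +X caudal, +Y dorsal, +Z anatomical left.
DIRECTIONS: dict[str, tuple[str, float]] = {
    "dorsoflexion": ("z", +1.0),
    "ventroflexion": ("z", -1.0),
    "left_lateroflexion": ("y", -1.0),
    "right_lateroflexion": ("y", +1.0),
    "left_axial": ("x", +1.0),
    "right_axial": ("x", -1.0),
}

CONSTRAINT_PRIORITY = ("bone", "disc", "capsule")


@dataclass(frozen=True)
class BendingConfig:
    """Parameters of one bending sweep."""

    step: float = 0.5  # degrees
    max_angle: float = 90.0  # degrees
    intersection_threshold: float = 0.005  # fraction of mean vertebral measure
    strain_allowance: float = 0.5  # |relative length change| permitted
    normalization: str = "mean_volume"
    pitch: float | None = None  # overlap grid pitch (mm); None = automatic
    disc_tension_only: bool = False
    pair_mask: dict | None = None  # direction -> iterable of pair-name prefixes
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError("step must be positive")
        n = self.max_angle / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("max_angle must be a multiple of step")

    @property
    def n_steps(self) -> int:
        return int(round(self.max_angle / self.step))


@dataclass(frozen=True)
class VariantGrid:
    """Factorial uncertainty grid of the experiment."""

    spacing_multipliers: tuple = (0.9, 1.0, 1.1)
    intersection_thresholds: tuple = (0.0025, 0.005, 0.0075)
    strain_scales: tuple = (0.9, 1.0, 1.1)
    base_strain: float = 0.5

    @property
    def strain_allowances(self) -> tuple:
        return tuple(self.base_strain * s for s in self.strain_scales)

    def variants(self):
        """All (spacing, threshold, allowance) combinations."""
        return list(
            itertools.product(
                self.spacing_multipliers,
                self.intersection_thresholds,
                self.strain_allowances,
            )
        )


@dataclass
class ConstraintReport:
    """Constraint state of one pose."""

    bone_overlap: float
    worst_disc_strain: float
    worst_capsule_strain: float
    violated: set
    disarticulated: bool


@dataclass
class SweepResult:
    rom: float
    limiting_constraint: str
    disarticulation_angle: float | None
    neutral_violation: bool = False


def _worst(values: np.ndarray) -> float:
    """Signed value of largest magnitude (0 for empty input)."""
    if values.size == 0:
        return 0.0
    return float(values[np.argmax(np.abs(values))])


class JointEngine:
    """Precomputed geometry for sweeping one joint.

    Builds occupancy grids of both vertebrae once (the anterior in world
    coordinates, the posterior in its neutral pose) and evaluates poses by
    transforming interior sample points, with an exact point-in-mesh
    narrow phase in grid boundary cells and an exact vertex-contact test
    for overlap onset.
    """

    def __init__(self, joint: JointModel, config: BendingConfig):
        self.joint = joint
        self.config = config
        self.cor = joint.frame.cor
        pitch = config.pitch
        if pitch is None:
            pitch = min(
                joint.anterior.mesh.default_pitch(), joint.posterior.mesh.default_pitch()
            )
        self.pitch = pitch
        self.tri_a = joint.anterior.mesh.triangles
        self.tri_p = joint.posterior.mesh.triangles
        self.grid_a = joint.anterior.mesh.occupancy(pitch)
        self.grid_p = joint.posterior.mesh.occupancy(pitch)
        self.pts_a = self.grid_a.cell_centers()
        self.pts_p = self.grid_p.cell_centers()
        self.verts_a = joint.anterior.mesh.vertices
        self.verts_p = joint.posterior.mesh.vertices
        if config.normalization == "mean_volume":
            # normalise by the mean enclosed volume of the two CENTRA (the
            # largest closed part of each vertebra, computed exactly): this
            # size reference is untouched by structure modifications, so
            # paired with/without experiments share their thresholds
            self.mean_measure = 0.5 * (
                max(abs(p.volume) for p in joint.anterior.mesh.parts)
                + max(abs(p.volume) for p in joint.posterior.mesh.parts)
            )
        elif config.normalization == "mean_area":
            self.mean_measure = 0.5 * (joint.anterior.mesh.area + joint.posterior.mesh.area)
        else:
            raise ValueError(f"unknown normalization {config.normalization!r}")

        self.pair_names = [p.name for p in joint.locator_pairs]
        self.pair_tissue = np.array([p.tissue for p in joint.locator_pairs])
        self.pair_a = np.array([p.anterior_point for p in joint.locator_pairs]).reshape(-1, 3)
        self.pair_p = np.array([p.posterior_point for p in joint.locator_pairs]).reshape(-1, 3)
        self.pair_len0 = np.linalg.norm(self.pair_p - self.pair_a, axis=1)
        if np.any(self.pair_len0 <= 0):
            raise ValueError("locator pair with zero neutral length")

        # facet projection bases (neutral prezygapophyseal normal)
        self._facets = []
        for f in joint.facet_pairs:
            n = f.normal / np.linalg.norm(f.normal)
            ref = np.array([1.0, 0.0, 0.0])
            if abs(n @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            u = np.cross(n, ref)
            u /= np.linalg.norm(u)
            v = np.cross(n, u)
            post2d = Polygon(np.column_stack([f.postzyg_poly @ u, f.postzyg_poly @ v]))
            self._facets.append((n, u, v, post2d, f.prezyg_poly))
        self._warned_no_facets = False

    # -- pose helpers ---------------------------------------------------

    def _rotation(self, direction: str, angle_deg: float) -> np.ndarray:
        axis_name, sign = DIRECTIONS[direction]
        axis = self.joint.frame.axis(axis_name) * sign
        return _kernel.rotation_matrix(axis, angle_deg)

    def _pose_points(self, points: np.ndarray, R: np.ndarray) -> np.ndarray:
        return (points - self.cor) @ R.T + self.cor

    def _unpose_points(self, points: np.ndarray, R: np.ndarray) -> np.ndarray:
        return (points - self.cor) @ R + self.cor

    # -- constraint families --------------------------------------------

    def overlap(self, R: np.ndarray) -> tuple[float, bool]:
        """(overlap fraction, exact-contact flag) at a pose."""
        posed_p = self._pose_points(self.pts_p, R)
        v_p_in_a = _kernel.contained_volume(
            posed_p, self.grid_p.cell_volume, self.grid_a, self.tri_a
        )
        inv_a = self._unpose_points(self.pts_a, R)
        v_a_in_p = _kernel.contained_volume(
            inv_a, self.grid_a.cell_volume, self.grid_p, self.tri_p
        )
        inter = 0.5 * (v_p_in_a + v_a_in_p)

        contact = inter > 0
        if not contact:
            vp = self._pose_points(self.verts_p, R)
            lo, hi = self.grid_a.origin, self.grid_a.origin + np.array(
                self.grid_a.occupied.shape
            ) * self.pitch
            cand = vp[np.all((vp >= lo - self.pitch) & (vp <= hi + self.pitch), axis=1)]
            if len(cand) and _kernel.points_in_parts(cand, self.tri_a).any():
                contact = True
            else:
                va = self._unpose_points(self.verts_a, R)
                lo, hi = self.grid_p.origin, self.grid_p.origin + np.array(
                    self.grid_p.occupied.shape
                ) * self.pitch
                cand = va[
                    np.all((va >= lo - self.pitch) & (va <= hi + self.pitch), axis=1)
                ]
                if len(cand) and _kernel.points_in_parts(cand, self.tri_p).any():
                    contact = True
        return inter / self.mean_measure, contact

    def strains(self, R: np.ndarray, direction: str | None = None):
        """Signed relative length change of every locator pair."""
        posed = self._pose_points(self.pair_p, R)
        strain = np.linalg.norm(posed - self.pair_a, axis=1) / self.pair_len0 - 1.0
        mask = np.ones(len(strain), dtype=bool)
        if direction is not None and self.config.pair_mask:
            prefixes = tuple(self.config.pair_mask.get(direction, ()))
            if prefixes:
                mask = np.array(
                    [n.startswith(prefixes) for n in self.pair_names], dtype=bool
                )
        return strain, mask

    def disarticulated(self, R: np.ndarray) -> bool:
        """True when every facet pair has zero projected overlap area."""
        if not self._facets:
            if not self._warned_no_facets:
                logger.info(
                    "%s has no zygapophyseal facets; disarticulation not tracked",
                    self.joint.name,
                )
                self._warned_no_facets = True
            return False
        for n, u, v, post2d, pre_poly in self._facets:
            pre = self._pose_points(pre_poly, R)
            poly = Polygon(np.column_stack([pre @ u, pre @ v]))
            if post2d.intersection(poly).area > 1e-12:
                return False
        return True

    # -- full report -----------------------------------------------------

    def report(
        self,
        direction: str,
        angle_deg: float,
        threshold: float | None = None,
        allowance: float | None = None,
    ) -> ConstraintReport:
        cfg = self.config
        threshold = cfg.intersection_threshold if threshold is None else threshold
        allowance = cfg.strain_allowance if allowance is None else allowance
        R = self._rotation(direction, angle_deg)
        frac, contact = self.overlap(R)
        if contact and frac == 0.0:
            frac = 1e-12  # contact with sub-resolution overlap volume
        strain, mask = self.strains(R, direction)
        disc = strain[mask & (self.pair_tissue == "disc")]
        caps = strain[mask & (self.pair_tissue == "capsule")]
        violated = set()
        if frac > threshold:
            violated.add("bone")
        if cfg.disc_tension_only:
            if disc.size and disc.max(initial=-np.inf) > allowance:
                violated.add("disc")
        elif disc.size and np.abs(disc).max() > allowance:
            violated.add("disc")
        if caps.size and np.abs(caps).max() > allowance:
            violated.add("capsule")
        return ConstraintReport(
            bone_overlap=frac,
            worst_disc_strain=_worst(disc),
            worst_capsule_strain=_worst(caps),
            violated=violated,
            disarticulated=self.disarticulated(R),
        )


def _engine(joint: JointModel, config: BendingConfig) -> JointEngine:
    cache = getattr(joint, "_engine_cache", None)
    key = (config.pitch, config.normalization)
    if cache is None:
        cache = {}
        joint._engine_cache = cache
    if key not in cache:
        cache[key] = JointEngine(joint, config)
    eng = cache[key]
    eng.config = config
    return eng


def evaluate_constraints(
    joint: JointModel, direction: str, angle_deg: float, config: BendingConfig | None = None
) -> ConstraintReport:
    """Constraint state of one joint posed by ``angle_deg`` in a direction."""
    config = config or BendingConfig()
    return _engine(joint, config).report(direction, angle_deg)


def detect_disarticulation(
    joint: JointModel, direction: str, angle_deg: float, config: BendingConfig | None = None
) -> bool:
    """Whether all zygapophyseal facet pairs have lost projected overlap."""
    config = config or BendingConfig()
    eng = _engine(joint, config)
    return eng.disarticulated(eng._rotation(direction, angle_deg))


@dataclass
class _Profile:
    """Per-step constraint curves of one (joint, direction) sweep."""

    angles: np.ndarray
    overlap: np.ndarray
    contact: np.ndarray
    disc_abs: np.ndarray
    disc_tension: np.ndarray
    caps_abs: np.ndarray
    disart: np.ndarray
    neutral: ConstraintReport


def _profile(
    eng: JointEngine,
    direction: str,
    config: BendingConfig,
    max_threshold: float,
    max_allowance: float,
) -> _Profile:
    """Sweep one direction, recording constraint curves until even the most
    permissive parameter variant has violated (or the cap is reached)."""
    neutral = eng.report(direction, 0.0, threshold=max_threshold, allowance=max_allowance)
    rows = []
    for k in range(1, config.n_steps + 1):
        angle = k * config.step
        R = eng._rotation(direction, angle)
        frac, contact = eng.overlap(R)
        strain, mask = eng.strains(R, direction)
        disc = strain[mask & (eng.pair_tissue == "disc")]
        caps = strain[mask & (eng.pair_tissue == "capsule")]
        disart = eng.disarticulated(R)
        rows.append(
            (
                angle,
                frac,
                contact,
                np.abs(disc).max() if disc.size else 0.0,
                disc.max() if disc.size else 0.0,
                np.abs(caps).max() if caps.size else 0.0,
                disart,
            )
        )
        disc_stat = rows[-1][4] if config.disc_tension_only else rows[-1][3]
        if frac > max_threshold or disc_stat > max_allowance or rows[-1][5] > max_allowance:
            break
    arr = np.array(rows, dtype=float) if rows else np.zeros((0, 7))
    return _Profile(
        angles=arr[:, 0],
        overlap=arr[:, 1],
        contact=arr[:, 2].astype(bool),
        disc_abs=arr[:, 3],
        disc_tension=arr[:, 4],
        caps_abs=arr[:, 5],
        disart=arr[:, 6].astype(bool),
        neutral=neutral,
    )


def _resolve(
    prof: _Profile, config: BendingConfig, threshold: float, allowance: float
) -> SweepResult:
    """ROM and limiting constraint for one (threshold, allowance) variant."""
    # neutral violation
    neutral_violated = []
    if prof.neutral.bone_overlap > threshold:
        neutral_violated.append("bone")
    disc0 = (
        prof.neutral.worst_disc_strain
        if config.disc_tension_only
        else abs(prof.neutral.worst_disc_strain)
    )
    if disc0 > allowance:
        neutral_violated.append("disc")
    if abs(prof.neutral.worst_capsule_strain) > allowance:
        neutral_violated.append("capsule")
    disart_angle = None
    if prof.disart.any():
        disart_angle = float(prof.angles[np.argmax(prof.disart)])
    if neutral_violated:
        return SweepResult(0.0, neutral_violated[0], disart_angle, neutral_violation=True)

    bone = prof.overlap > threshold
    if threshold == 0.0:
        bone |= prof.contact
    disc = (prof.disc_tension if config.disc_tension_only else prof.disc_abs) > allowance
    caps = prof.caps_abs > allowance
    any_viol = bone | disc | caps
    if not any_viol.any():
        if len(prof.angles) and prof.angles[-1] >= config.max_angle - 1e-9:
            return SweepResult(config.max_angle, "cap", disart_angle)
        # profile stopped early under a stricter stop rule than this variant
        # (should not happen: the stop rule uses the loosest variant)
        return SweepResult(
            float(prof.angles[-1]) if len(prof.angles) else 0.0, "cap", disart_angle
        )
    k = int(np.argmax(any_viol))
    for fam, hit in (("bone", bone[k]), ("disc", disc[k]), ("capsule", caps[k])):
        if hit:
            limiting = fam
            break
    rom = float(prof.angles[k] - config.step)
    return SweepResult(max(rom, 0.0), limiting, disart_angle)


def sweep_direction(
    joint: JointModel, direction: str, config: BendingConfig | None = None
) -> SweepResult:
    """ROM of one joint in one direction under a single parameter setting."""
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; one of {sorted(DIRECTIONS)}")
    config = config or BendingConfig()
    eng = _engine(joint, config)
    prof = _profile(
        eng, direction, config, config.intersection_threshold, config.strain_allowance
    )
    res = _resolve(prof, config, config.intersection_threshold, config.strain_allowance)
    if res.neutral_violation:
        warnings.warn(
            f"{joint.name}: constraint violated at neutral pose in {direction}; ROM 0"
        )
    return res


def run_experiment(
    column: ColumnModel,
    grid: VariantGrid | None = None,
    config: BendingConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full factorial bending experiment on a column.

    Returns one record per joint x direction x variant, and optionally
    writes one delimited text file per joint. Deterministic given inputs.
    """
    grid = grid or VariantGrid()
    config = config or BendingConfig()
    if config.pitch is None:
        # one shared pitch so occupancy grids are voxelised once per vertebra
        # and re-used (translated) across spacing variants
        config = replace(
            config, pitch=min(v.mesh.default_pitch() for v in column.vertebrae)
        )
    for v in column.vertebrae:
        v.mesh.occupancy(config.pitch)
    records = []
    for mult in grid.spacing_multipliers:
        posed = assemble_column(
            column.vertebrae,
            optimal_spacing=column.optimal_spacing,
            spacing_multiplier=mult,
            species=column.species,
            group=column.group,
            centrum_type=column.centrum_type,
            diaphragmatic_joint=column.diaphragmatic_joint,
            intercentra=column.intercentra,
            check_interpenetration=False,
        )
        for joint in posed.joints:
            t0 = time.perf_counter()
            try:
                eng = JointEngine(joint, config)
            except Exception as exc:  # noqa: BLE001
                logger.warning("joint %s failed assembly: %s", joint.joint_index, exc)
                for direction in DIRECTIONS:
                    for thr in grid.intersection_thresholds:
                        for allow in grid.strain_allowances:
                            records.append(
                                dict(
                                    species=column.species,
                                    joint=joint.joint_index,
                                    direction=direction,
                                    spacing_mult=mult,
                                    threshold=thr,
                                    strain_allow=allow,
                                    rom_deg=np.nan,
                                    limiting_constraint=f"error:{exc}",
                                    disarticulated_at=np.nan,
                                )
                            )
                continue
            for direction in DIRECTIONS:
                prof = _profile(
                    eng,
                    direction,
                    config,
                    max(grid.intersection_thresholds),
                    max(grid.strain_allowances),
                )
                for thr in grid.intersection_thresholds:
                    for allow in grid.strain_allowances:
                        res = _resolve(prof, config, thr, allow)
                        records.append(
                            dict(
                                species=column.species,
                                joint=joint.joint_index,
                                direction=direction,
                                spacing_mult=mult,
                                threshold=thr,
                                strain_allow=allow,
                                rom_deg=res.rom,
                                limiting_constraint=res.limiting_constraint,
                                disarticulated_at=(
                                    np.nan
                                    if res.disarticulation_angle is None
                                    else res.disarticulation_angle
                                ),
                            )
                        )
            logger.info(
                "joint %d spacing %.1f: %.2fs",
                joint.joint_index,
                mult,
                time.perf_counter() - t0,
            )
    table = pd.DataFrame.from_records(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for jidx, sub in table.groupby("joint"):
            sub.to_csv(
                out_dir / f"{column.species}_joint{jidx:02d}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
    return table
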
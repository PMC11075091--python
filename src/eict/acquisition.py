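"""Sampling trajectories: dithering, cycloidal fly scans, scan duration.

Edge illumination undersamples each projection laterally (one beamlet per
mask period), so a full dataset needs N_dith = ⌈p/w⌉ sub-period sample
shifts per view. Three schemes provide them:

* **dithered** — step-and-shoot: N_dith lateral steps at every angle, plus a
  per-angle pseudo-random jitter (an integer number of dither steps, stored
  for exact reversal during assembly) that decorrelates residual mask
  non-uniformities and suppresses ring artefacts.
* **cycloidal type 1** — fly scan at N×N_dith angles, one frame per angle,
  the sample advancing by exactly one dither step per angular increment.
  Same total frame count and sampling density as dithering, on a sheared
  grid.
* **cycloidal type 2** — fly scan with a larger lateral advance per frame,
  deliberately under-sampling the sinogram for speed; the continuous
  roto-translation acts as an anti-aliasing low-pass.

Lateral offsets are expressed at the sample plane in metres. To keep the
interleaved sinogram grid exactly uniform, the dither step is defined as
p·m_s/N_dith (the nominal aperture width w·m_s differs from this by <2% for
the bands modelled here, since p/w is not an exact integer).

Fly scans translate back and forth over a span of 10 projected mask periods
so the horizontal field of view is not consumed by the translation.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import MaskBand, SystemGeometry

__all__ = [
    "Trajectory",
    "dither_steps",
    "dither_step_size",
    "dithered_trajectory",
    "cycloidal_type1_trajectory",
    "cycloidal_type2_trajectory",
    "scan_duration",
]


def dither_steps(band: MaskBand) -> int:
    """Number of lateral steps per angle needed for full sampling, ⌈p/w⌉."""
    if band.aperture >= band.period:
        raise ValueError("aperture must be smaller than the period")
    return math.ceil(band.period / band.aperture - 1e-9)


def dither_step_size(band: MaskBand, geom: SystemGeometry) -> float:
    """Lateral sample shift per dither step at the sample plane (m).

    Defined as p·m_s/N_dith so that N_dith steps tile the projected mask
    period exactly and interleaved samples land on a uniform grid.
    """
    return band.period * geom.m_s / dither_steps(band)


@dataclass
class Trajectory:
    """Ordered acquisition schedule: (angle, lateral offset, exposure) triples."""

    angles_deg: np.ndarray
    offsets: np.ndarray  # m, sample plane
    exposures: np.ndarray  # s
    scheme: str  # "dithered" | "cyc1" | "cyc2"
    band_name: str = ""
    n_dith: int = 1
    step: float = 0.0  # dither step, m
    jitter_steps: np.ndarray | None = None  # per-angle integer jitter (dithered)
    jitter_seed: int | None = None
    overhead_per_step: float = 0.0  # s, step-and-shoot motion overhead
    span: float = 0.0  # back-and-forth span, m (fly scans)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.exposures = np.asarray(self.exposures, dtype=float)
        if not (self.angles_deg.shape == self.offsets.shape == self.exposures.shape):
            raise ValueError("angle/offset/exposure arrays must be congruent")
        if self.angles_deg.size and (
            self.angles_deg.min() < 0 or self.angles_deg.max() >= 360.0
        ):
            raise ValueError("angles must lie in [0, 360)")

    def __len__(self) -> int:
        return self.angles_deg.size

    @property
    def unique_angles(self) -> np.ndarray:
        return np.unique(self.angles_deg)

    def to_csv(self, path: str | Path) -> None:
        """Write entries as CSV plus a JSON sidecar with scheme metadata."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "angle_deg", "offset_um", "exposure_s"])
            for i, (a, o, e) in enumerate(
                zip(self.angles_deg, self.offsets, self.exposures)
            ):
                w.writerow([i, f"{a:.9g}", f"{o * 1e6:.9g}", f"{e:.9g}"])
        sidecar = {
            "scheme": self.scheme,
            "band": self.band_name,
            "n_dith": self.n_dith,
            "step_um": self.step * 1e6,
            "jitter_seed": self.jitter_seed,
            "jitter_steps": None
            if self.jitter_steps is None
            else [int(j) for j in self.jitter_steps],
            "overhead_per_step_s": self.overhead_per_step,
            "span_um": self.span * 1e6,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta = json.loads(path.with_suffix(".json").read_text())
        jit = meta.get("jitter_steps")
        return cls(
            angles_deg=rows[:, 1],
            offsets=rows[:, 2] * 1e-6,
            exposures=rows[:, 3],
            scheme=meta["scheme"],
            band_name=meta.get("band", ""),
            n_dith=meta.get("n_dith", 1),
            step=meta.get("step_um", 0.0) * 1e-6,
            jitter_steps=None if jit is None else np.asarray(jit, dtype=int),
            jitter_seed=meta.get("jitter_seed"),
            overhead_per_step=meta.get("overhead_per_step_s", 0.0),
            span=meta.get("span_um", 0.0) * 1e-6,
        )


def _equispaced_angles(n: int) -> np.ndarray:
    if n < 1:
        raise ValueError("need at least one angle")
    return np.arange(n) * (360.0 / n)


def dithered_trajectory(
    n_angles: int,
    band: MaskBand,
    geom: SystemGeometry,
    exposure: float = 1.0,
    jitter_seed: int | None = None,
    overhead_per_step: float = 0.0,
) -> Trajectory:
    """Step-and-shoot schedule: N_dith offsets per angle plus optional jitter.

    With ``jitter_seed`` set, each angle receives an additional pseudo-random
    lateral offset drawn uniformly from the integer multiples of the dither
    step spanning one projected period; the draw table is stored on the
    trajectory so assembly can reverse it exactly.
    """
    nd = dither_steps(band)
    step = dither_step_size(band, geom)
    base_angles = _equispaced_angles(n_angles)
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        jitter = rng.integers(0, nd, size=n_angles)
    else:
        jitter = np.zeros(n_angles, dtype=int)
    angles = np.repeat(base_angles, nd)
    j = np.tile(np.arange(nd), n_angles)
    offsets = (j + np.repeat(jitter, nd)) * step
    return Trajectory(
        angles_deg=angles,
        offsets=offsets,
        exposures=np.full(angles.size, float(exposure)),
        scheme="dithered",
        band_name=band.name,
        n_dith=nd,
        step=step,
        jitter_steps=jitter,
        jitter_seed=jitter_seed,
        overhead_per_step=overhead_per_step,
    )


def _triangle_positions(n: int, increment: float, span: float) -> np.ndarray:
    """Back-and-forth positions: advance by ``increment`` per entry, folded
    into [0, span] by reflection at the ends."""
    raw = np.arange(n) * increment
    m = np.mod(raw, 2.0 * span)
    return np.where(m <= span, m, 2.0 * span - m)


def cycloidal_type1_trajectory(
    n_angles_base: int,
    band: MaskBand,
    geom: SystemGeometry,
    exposure: float = 1.0,
    span_periods: int = 10,
) -> Trajectory:
    """Fully sampled fly scan: N_base × N_dith angles, one dither step each.

    The lateral position advances by exactly one dither step per angular
    increment, folded back and forth over ``span_periods`` projected mask
    periods. Collectively the frames sample the same (angle, offset) density
    as a dithered scan, on a sheared grid.
    """
    nd = dither_steps(band)
    step = dither_step_size(band, geom)
    n = n_angles_base * nd
    span = span_periods * band.period * geom.m_s
    return Trajectory(
        angles_deg=_equispaced_angles(n),
        offsets=_triangle_positions(n, step, span),
        exposures=np.full(n, float(exposure)),
        scheme="cyc1",
        band_name=band.name,
        n_dith=nd,
        step=step,
        span=span,
    )


def cycloidal_type2_trajectory(
    n_angles: int,
    shift_per_frame: float,
    band: MaskBand,
    geom: SystemGeometry,
    exposure: float = 1.0,
    span_periods: int = 10,
) -> Trajectory:
    """Under-sampled fly scan: one frame per angle, larger lateral advance.

    ``shift_per_frame`` is the lateral sample shift per angular increment at
    the sample plane (m); it must be at least one dither step (at exactly one
    step this degenerates to a type-1 schedule).
    """
    step = dither_step_size(band, geom)
    if shift_per_frame < step * (1.0 - 1e-9):
        raise ValueError(
            "type-2 shift per frame must be >= the dither step; "
            "smaller shifts are a (denser) type-1 scan"
        )
    span = span_periods * band.period * geom.m_s
    return Trajectory(
        angles_deg=_equispaced_angles(n_angles),
        offsets=_triangle_positions(n_angles, shift_per_frame, span),
        exposures=np.full(n_angles, float(exposure)),
        scheme="cyc2",
        band_name=band.name,
        n_dith=dither_steps(band),
        step=step,
        span=span,
        meta={"shift_per_frame_um": shift_per_frame * 1e6},
    )


def scan_duration(traj: Trajectory) -> float:
    """Total scan time in seconds.

    Fly scans (cyc1/cyc2) spend only the exposure time: the rotation and
    translation run continuously, so there is no per-frame overhead.
    Step-and-shoot dithered scans add a motion/settling overhead per step; the
    overhead is a free parameter of the schedule, as it is dominated by
    instrument-specific motor characteristics.
    """
    total = float(np.sum(traj.exposures))
    if traj.scheme == "dithered":
        total += traj.overhead_per_step * len(traj)
    return total
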
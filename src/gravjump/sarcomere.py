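"""Sarcomere operating length and force capacity from fascicle lengths.

The subject's serial sarcomere count is estimated as the standing fascicle
length divided by the in vivo reference sarcomere length (3.09 um at an
ankle angle of 110 deg).  Fascicle length at any jump time point divided by
that count gives the sarcomere operating length, which is mapped to relative
force through a piecewise-linear human length-tension curve.

The default breakpoints are fixed by human filament geometry: thick filament
1.60 um, thin filament 1.32 um, bare zone 0.17 um, giving a maximal-force
plateau at 2.64-2.81 um and a descending limb reaching zero at 4.24 um; the
ascending limb has its steep/shallow junction at 1.67 um (force 0.677) and
its foot at 1.27 um.  All breakpoints are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import DEFAULT_LT_BREAKPOINTS


def estimate_sarcomere_number(lf_stand_mm: float, sl_ref_um: float = 3.09) -> float:
    """Serial sarcomere count = standing fascicle length / reference length.

    Kept real-valued: it is a scaling constant, and rounding would break the
    scale identity ``sl = sl_ref * lf / lf_stand``.
    """
    if lf_stand_mm <= 0 or sl_ref_um <= 0:
        raise ValueError("lengths must be positive")
    if lf_stand_mm < 1.0:
        raise ValueError(
            f"lf_stand={lf_stand_mm} looks like it is not in mm (unit guard)"
        )
    return lf_stand_mm * 1000.0 / sl_ref_um


def sarcomere_length(lf_mm: float, n_sarc: float) -> float:
    """Operating sarcomere length in um for a fascicle length in mm."""
    if lf_mm <= 0 or n_sarc <= 0:
        raise ValueError("fascicle length and sarcomere number must be positive")
    return lf_mm * 1000.0 / n_sarc


@dataclass(frozen=True)
class LTModel:
    """Piecewise-linear sarcomere length-tension curve.

    ``breakpoints`` are ordered (length um, relative force in [0, 1]) pairs;
    force is 0 at and beyond the extreme lengths and exactly 1 on the
    plateau.
    """

    breakpoints: tuple = DEFAULT_LT_BREAKPOINTS

    def __post_init__(self):
        bps = tuple((float(l), float(f)) for l, f in self.breakpoints)
        object.__setattr__(self, "breakpoints", bps)
        lengths = [l for l, _ in bps]
        forces = [f for _, f in bps]
        if len(bps) < 3:
            raise ValueError("need at least three breakpoints")
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValueError("breakpoint lengths must be strictly increasing")
        if any(not 0.0 <= f <= 1.0 for f in forces):
            raise ValueError("forces must lie in [0, 1]")
        if forces[0] != 0.0 or forces[-1] != 0.0:
            raise ValueError("force must be zero at the extreme lengths")
        if 1.0 not in forces:
            raise ValueError("curve never reaches maximal force")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([l for l, _ in self.breakpoints])

    @property
    def forces(self) -> np.ndarray:
        return np.array([f for _, f in self.breakpoints])

    @property
    def plateau(self) -> tuple[float, float]:
        """(start, end) of the maximal-force plateau in um."""
        at_max = np.flatnonzero(self.forces == 1.0)
        return float(self.lengths[at_max[0]]), float(self.lengths[at_max[-1]])

    def relative_force(self, sl_um):
        """Relative force in [0, 1] at sarcomere length(s) ``sl_um``."""
        sl = np.asarray(sl_um, dtype=float)
        if np.any(sl <= 0):
            raise ValueError("sarcomere length must be positive")
        out = np.interp(sl, self.lengths, self.forces, left=0.0, right=0.0)
        return float(out) if np.isscalar(sl_um) else out


def relative_force(sl_um, model: LTModel | None = None):
    """Module-level convenience over :meth:`LTModel.relative_force`."""
    return (model or LTModel()).relative_force(sl_um)


def percent_change(a: float, b: float) -> float:
    """Signed percent change 100*(b - a)/a."""
    if a == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (b - a) / a


def percent_change_magnitude(a: float, b: float) -> int:
    """|percent change| rounded to the nearest integer (reporting convention)."""
    return int(round(abs(percent_change(a, b))))


def round_to_nearest_10(percent: float) -> int:
    """'About N%' reporting granularity for force-capacity statements."""
    return int(round(percent / 10.0) * 10)


def normalize_to_do(lf_by_phase: Mapping[str, float]) -> dict:
    """Divide each phase's fascicle length by the drop-off value."""
    if "DO" not in lf_by_phase:
        raise ValueError("no DO entry to normalize against")
    do = lf_by_phase["DO"]
    if not do > 0:
        raise ValueError("DO fascicle length must be positive")
    return {k: v / do for k, v in lf_by_phase.items()}


@dataclass
class SarcomereEstimate:
    """Per-trial sarcomere bookkeeping across the jump phases."""

    n_sarc: float
    lf_mm: dict
    sl_um: dict
    lf_norm_do: dict
    force_fraction: dict

    @classmethod
    def from_fascicle_lengths(
        cls,
        lf_by_phase: Mapping[str, float],
        lf_stand_mm: float,
        sl_ref_um: float = 3.09,
        model: LTModel | None = None,
    ) -> "SarcomereEstimate":
        model = model or LTModel()
        n = estimate_sarcomere_number(lf_stand_mm, sl_ref_um)
        sl = {k: sarcomere_length(v, n) for k, v in lf_by_phase.items()}
        return cls(
            n_sarc=n,
            lf_mm=dict(lf_by_phase),
            sl_um=sl,
            lf_norm_do=normalize_to_do(lf_by_phase),
            force_fraction={k: model.relative_force(v) for k, v in sl.items()},
        )
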
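"""Quantitative design of the selection experiment: MIC determination on a
discrete concentration grid, the geometric drug schedule, and the generation
count set by daily serial dilution."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoMicError",
    "MicResult",
    "Schedule",
    "compute_mic",
    "make_schedule",
    "max_generations",
]


class NoMicError(ValueError):
    """No tested concentration restricted growth in all replicates."""


@dataclass(frozen=True)
class MicResult:
    mic: float
    tested_concentrations: tuple[float, ...]
    replicate_od: tuple[tuple[float, ...], ...]  # replicates x concentrations


@dataclass(frozen=True)
class Schedule:
    """Daily drug concentrations; strictly geometric after day 1."""

    days: tuple[int, ...]
    concentrations: tuple[float, ...]  # ug/mL
    mic: float

    @property
    def relative_concentrations(self) -> tuple[float, ...]:
        """Concentrations as multiples of the MIC (r.c.)."""
        return tuple(c / self.mic for c in self.concentrations)


def compute_mic(
    replicate_od,
    concentrations,
    od_threshold: float = 0.075,
) -> MicResult:
    """MIC = lowest tested concentration yielding OD <= threshold in *all*
    replicates (no interpolation between grid points).

    ``replicate_od`` is a replicates-by-concentrations matrix aligned with the
    ascending ``concentrations`` list.
    """
    od = np.asarray(replicate_od, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if od.ndim != 2 or od.shape[0] < 1:
        raise ValueError("replicate_od must be a replicates x concentrations matrix")
    if od.shape[1] != conc.size:
        raise ValueError("OD matrix width must match number of concentrations")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly ascending")
    inhibited = np.all(od <= od_threshold, axis=0)
    idx = np.flatnonzero(inhibited)
    if idx.size == 0:
        raise NoMicError(
            f"no tested concentration (max {conc[-1]}) restricted growth to "
            f"OD <= {od_threshold} in all replicates"
        )
    return MicResult(
        mic=float(conc[idx[0]]),
        tested_concentrations=tuple(conc.tolist()),
        replicate_od=tuple(map(tuple, od.tolist())),
    )


def make_schedule(
    mic: float,
    days: int = 10,
    start_fraction: float = 0.5,
    total_fold: float = 10.0,
) -> Schedule:
    """Geometric schedule starting at ``start_fraction * mic`` and reaching
    ``total_fold`` times the initial concentration on the final day.

    The daily multiplier is ``total_fold ** (1 / (days - 1))`` (``days - 1``
    multiplicative steps anchor day 1 and day ``days``). A single-day schedule
    is just the starting concentration.
    """
    if mic <= 0:
        raise ValueError("mic must be positive")
    if days < 1:
        raise ValueError("days must be >= 1")
    c1 = start_fraction * mic
    if days == 1:
        return Schedule(days=(1,), concentrations=(c1,), mic=mic)
    multiplier = total_fold ** (1.0 / (days - 1))
    conc = tuple(c1 * multiplier ** (d - 1) for d in range(1, days + 1))
    return Schedule(days=tuple(range(1, days + 1)), concentrations=conc, mic=mic)


def max_generations(dilution_factor: float = 820.0, days: int = 10) -> tuple[float, int]:
    """Maximum generations under daily serial dilution with regrowth to the
    same saturation density: ``days * log2(dilution_factor)``.

    Returns ``(value rounded to 1 decimal, nearest integer)``.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    g = days * math.log2(dilution_factor)
    return round(g, 1), round(g)
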
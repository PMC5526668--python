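"""Trajectory analysis: normalization, rescue and fluorescence-phenotype
classification, transient-amplification detection, final YFP/CFP ratios, and
the ratio-trajectory rule for ordering amplification vs. other mutations.

All inequalities are deliberately literal:

* rescue: final OD strictly ``>`` the OD threshold;
* zeroing: normalized fluorescence set to exactly 0 on days with OD strictly
  ``<`` the OD threshold;
* elevation: fold increase over the ancestor strictly ``>`` the fold threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import PlateSeries

__all__ = [
    "AnalysisConfig",
    "AncestralReference",
    "NormalizedTrajectory",
    "PhenotypeCall",
    "normalize",
    "ancestral_reference",
    "classify_rescue",
    "classify_phenotype",
    "detect_transient_elevation",
    "amplified_for_cost",
    "final_ratio",
    "classify_well",
    "classify_plate",
    "infer_amplification_timing",
    "classify_spot_amplification",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for trajectory classification.

    ``od_threshold`` is both the rescue criterion and the normalization
    cutoff; ``fold_threshold`` is the fold-increase criterion for calling a
    fluorescence channel elevated; the stringent (transient) criteria require
    ``stringent_min_days`` days with fold increase above threshold at OD
    above ``stringent_od_min``.
    """

    od_threshold: float = 0.075
    fold_threshold: float = 2.77
    stringent_min_days: int = 2
    stringent_od_min: float = 0.3
    final_day: int | None = None  # default: last day of the series

    def __post_init__(self) -> None:
        if self.od_threshold <= 0 or self.fold_threshold <= 0 or self.stringent_od_min <= 0:
            raise ValueError("thresholds must be positive")
        if self.stringent_min_days < 1:
            raise ValueError("stringent_min_days must be >= 1")


@dataclass(frozen=True)
class AncestralReference:
    """Mean OD-normalized fluorescence of ancestor wells grown without drug."""

    mean_norm_yfp: float
    mean_norm_cfp: float
    n_wells: int

    def __post_init__(self) -> None:
        if self.mean_norm_yfp <= 0 or self.mean_norm_cfp <= 0:
            raise ValueError("reference means must be positive")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")


@dataclass
class NormalizedTrajectory:
    od600: np.ndarray
    norm_yfp: np.ndarray  # RFU per OD; exactly 0 on days with od600 < OD_t
    norm_cfp: np.ndarray


@dataclass
class PhenotypeCall:
    """Per-well classification. ``yfp_elevated``/``cfp_elevated`` are final-day
    calls and only meaningful for rescued wells; the transient flags use the
    stringent multi-day criteria; ``final_ratio`` is raw YFP/CFP (NaN when the
    final CFP reading is zero)."""

    plate_id: str
    well: str
    rescued: bool
    yfp_elevated: bool
    cfp_elevated: bool
    transient_yfp: bool
    transient_cfp: bool
    amplified_for_cost: bool
    final_ratio: float

    @property
    def phenotype(self) -> str:
        if not self.rescued:
            return "extinct"
        if self.cfp_elevated:
            return "YFP+CFP" if self.yfp_elevated else "CFP"
        return "YFP" if self.yfp_elevated else "none"


def _final_index(series_len: int, cfg: AnalysisConfig) -> int:
    day = cfg.final_day if cfg.final_day is not None else series_len
    if not 1 <= day <= series_len:
        raise ValueError(f"final_day {day} outside 1..{series_len}")
    return day - 1


def normalize(series: PlateSeries, cfg: AnalysisConfig = AnalysisConfig()) -> NormalizedTrajectory:
    """OD-normalize both channels, zeroing days where OD fell below threshold.

    ``norm = raw / od600`` on days with ``od600 >= od_threshold``; exactly 0
    otherwise ("below" is a strict ``<``, so a day at exactly the threshold is
    normalized, not zeroed).
    """
    keep = series.od600 >= cfg.od_threshold
    norm_yfp = np.zeros_like(series.yfp)
    norm_cfp = np.zeros_like(series.cfp)
    np.divide(series.yfp, series.od600, out=norm_yfp, where=keep)
    np.divide(series.cfp, series.od600, out=norm_cfp, where=keep)
    norm_yfp[~keep] = 0.0
    norm_cfp[~keep] = 0.0
    return NormalizedTrajectory(od600=series.od600.copy(), norm_yfp=norm_yfp, norm_cfp=norm_cfp)


def ancestral_reference(
    ancestor_wells: Iterable[tuple[float, float, float]],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> AncestralReference:
    """Average OD-normalized fluorescence over ancestor wells.

    ``ancestor_wells`` yields single-timepoint ``(od600, yfp, cfp)`` readings;
    wells below the OD threshold are excluded (they carry no signal).
    """
    ys, cs = [], []
    for od, yfp, cfp in ancestor_wells:
        if od >= cfg.od_threshold:
            ys.append(yfp / od)
            cs.append(cfp / od)
    if not ys:
        raise ValueError("no ancestor well reached the OD threshold; reference undefined")
    return AncestralReference(
        mean_norm_yfp=float(np.mean(ys)), mean_norm_cfp=float(np.mean(cs)), n_wells=len(ys)
    )


def classify_rescue(series: PlateSeries, cfg: AnalysisConfig = AnalysisConfig()) -> bool:
    """Rescued iff final-day OD strictly exceeds the OD threshold.

    Only the final day counts: a population that transiently dipped below the
    threshold mid-experiment but recovered is rescued.
    """
    i = _final_index(series.n_days, cfg)
    return bool(series.od600[i] > cfg.od_threshold)


def classify_phenotype(
    traj: NormalizedTrajectory,
    ref: AncestralReference,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> tuple[bool, bool]:
    """Final-day fold-increase calls for (YFP, CFP), each strictly ``>``
    the fold threshold, evaluated independently per channel."""
    i = _final_index(len(traj.od600), cfg)
    yfp_fold = traj.norm_yfp[i] / ref.mean_norm_yfp
    cfp_fold = traj.norm_cfp[i] / ref.mean_norm_cfp
    return bool(yfp_fold > cfg.fold_threshold), bool(cfp_fold > cfg.fold_threshold)


def detect_transient_elevation(
    traj: NormalizedTrajectory,
    ref: AncestralReference,
    cfg: AnalysisConfig = AnalysisConfig(),
    channel: Literal["yfp", "cfp"] = "cfp",
) -> bool:
    """Stringent elevation call: at least ``stringent_min_days`` days with
    fold increase above threshold while OD was above ``stringent_od_min``.

    Designed to exclude extinct wells that are false positives for elevation
    due to low-OD noise just before extinction.
    """
    norm = traj.norm_yfp if channel == "yfp" else traj.norm_cfp
    ref_mean = ref.mean_norm_yfp if channel == "yfp" else ref.mean_norm_cfp
    qualifying = (norm / ref_mean > cfg.fold_threshold) & (traj.od600 > cfg.stringent_od_min)
    return bool(np.count_nonzero(qualifying) >= cfg.stringent_min_days)


def amplified_for_cost(call: PhenotypeCall) -> bool:
    """Counted as an amplification for cost analysis: any well with
    (transiently) increased CFP — extinct wells via the stringent criteria,
    rescued wells via either the final-day call or the stringent criteria."""
    if call.rescued:
        return call.cfp_elevated or call.transient_cfp
    return call.transient_cfp


def final_ratio(series: PlateSeries, cfg: AnalysisConfig = AnalysisConfig()) -> float:
    """Final-day YFP/CFP in raw plate-reader units (NaN when CFP is 0)."""
    i = _final_index(series.n_days, cfg)
    cfp = series.cfp[i]
    if cfp == 0:
        return math.nan
    return float(series.yfp[i] / cfp)


def classify_well(
    series: PlateSeries,
    ref: AncestralReference,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> PhenotypeCall:
    """Run the full per-well classification chain."""
    traj = normalize(series, cfg)
    rescued = classify_rescue(series, cfg)
    yfp_el, cfp_el = classify_phenotype(traj, ref, cfg) if rescued else (False, False)
    t_yfp = detect_transient_elevation(traj, ref, cfg, "yfp")
    t_cfp = detect_transient_elevation(traj, ref, cfg, "cfp")
    call = PhenotypeCall(
        plate_id=series.plate_id,
        well=series.well,
        rescued=rescued,
        yfp_elevated=yfp_el,
        cfp_elevated=cfp_el,
        transient_yfp=t_yfp,
        transient_cfp=t_cfp,
        amplified_for_cost=False,
        final_ratio=final_ratio(series, cfg),
    )
    call.amplified_for_cost = amplified_for_cost(call)
    return call


def classify_plate(
    plate: Sequence[PlateSeries],
    ref: AncestralReference,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Classify every well; returns one row per well (SD15-style table)."""
    calls = [classify_well(s, ref, cfg) for s in plate]
    return pd.DataFrame(
        {
            "plate_id": [c.plate_id for c in calls],
            "well": [c.well for c in calls],
            "rescued": [c.rescued for c in calls],
            "phenotype": [c.phenotype for c in calls],
            "yfp_elevated": [c.yfp_elevated for c in calls],
            "cfp_elevated": [c.cfp_elevated for c in calls],
            "transient_yfp": [c.transient_yfp for c in calls],
            "transient_cfp": [c.transient_cfp for c in calls],
            "amplified_for_cost": [c.amplified_for_cost for c in calls],
            "final_ratio": [c.final_ratio for c in calls],
        }
    )


def infer_amplification_timing(
    ratios: Sequence[float],
    plate_median: float,
    *,
    rel_sd_tolerance: float = 0.25,
    step_factor: float = 2.0,
) -> str:
    """Order amplification relative to a co-occurring mutation from the
    per-day YFP/CFP ratio trajectory (valid days only, i.e. days with OD at or
    above the normalization threshold).

    Returns one of ``amplification_second`` (ratio high and flat throughout:
    the amplification expanded only after the other mutation),
    ``amplification_first`` (a sustained upward step at an intermediate
    timepoint), or ``indeterminate``.
    """
    r = np.asarray([x for x in ratios if np.isfinite(x)], dtype=float)
    if len(r) < 4:
        return "indeterminate"
    mean = float(np.mean(r))
    rel_sd = float(np.std(r, ddof=1) / mean) if mean > 0 else math.inf
    if rel_sd <= rel_sd_tolerance and mean > plate_median:
        return "amplification_second"
    # sustained mid-experiment step: best split with >= 2 days on each side
    best = 0.0
    for k in range(2, len(r) - 1):
        early, late = np.mean(r[:k]), np.mean(r[k:])
        if early > 0 and late / early > best:
            best = late / early
    if best > step_factor:
        return "amplification_first"
    return "indeterminate"


def classify_spot_amplification(
    spot_means: Sequence[float],
    ancestor_means: Sequence[float],
    *,
    rule: Literal["fold", "sd"] = "fold",
    factor: float = 6.0,
) -> list[bool]:
    """Flag colony spots as amplified from spot fluorescence intensity.

    Default rule: intensity strictly greater than ``factor`` times the mean
    ancestor-spot intensity. Alternative rule (``rule='sd'``): intensity
    greater than mean + ``factor`` standard deviations of the ancestor spots.
    """
    anc = np.asarray(ancestor_means, dtype=float)
    if anc.size == 0:
        raise ValueError("empty ancestor spot set")
    if rule == "fold":
        threshold = factor * float(anc.mean())
    elif rule == "sd":
        if anc.size < 2:
            raise ValueError("sd rule needs >= 2 ancestor spots")
        threshold = float(anc.mean()) + factor * float(anc.std(ddof=1))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return [bool(s > threshold) for s in spot_means]
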
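"""Synthetic-data generation.

Two generators live here:

* a stochastic serial-transfer evolutionary-rescue simulator emitting plate
  datasets (OD600/YFP/CFP per well per day) with known per-well ground truth,
  used to exercise the trajectory pipeline end to end; and
* a toy-genome/annotation generator with planted repeats, promoters,
  terminators and essential genes whose set memberships are known by
  construction, used to exercise the neighborhood classifier.

The growth/drug model is deliberately simple: the drug is bacteriostatic; a
genotype grows on a given day iff its expression of the selected gene (in
multiples of ancestral leaky expression) exceeds the day's drug concentration
(in multiples of the ancestral MIC), otherwise it declines at a fixed factor.
Amplified lineages pay a per-extra-copy growth cost scaled by the amplicon
length factor of the scenario; copy number evolves as a biased walk. Defaults
are synthetic and calibrated only to reproduce qualitative regimes (rescue
fraction ordering, cost-dependent extinction, ratio signatures), never exact
experimental counts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import Schedule, make_schedule
from .io import AnnotationBundle, Gene, PlateSeries, Promoter, Terminator

__all__ = [
    "SimParams",
    "ScenarioPreset",
    "PRESETS",
    "get_preset",
    "simulate_well",
    "simulate_plate",
    "simulate_ancestor_plate",
    "default_schedule",
    "make_toy_annotation",
    "ToyAnnotationTruth",
]


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for the rescue simulator (all synthetic)."""

    days: int = 10
    capacity: float = 1e6  # cells at saturation
    dilution: float = 820.0  # daily dilution factor
    growth_fold: float = 1e5  # per-day fold for a tolerant, cost-free genotype
    decline_fold: float = 0.15  # per-day survival factor when not tolerant
    od_saturated: float = 1.0  # OD600 of a saturated culture (reader units)
    od_floor: float = 0.01  # medium blank
    yfp_gain: float = 100.0  # RFU per OD for ancestral leaky expression
    cfp_gain: float = 100.0  # RFU per OD per cassette copy
    rate_point: float = 5e-8  # per cell per day
    rate_is: float = 5e-8
    rate_cooption: float = 1e-7
    dup_rate_basal: float = 6e-7
    dup_rate_homology: float = 6e-6
    mutant_clone_size: float = 120.0  # end-of-day size of a clone founded mid-growth
    amp_up: float = 0.35  # daily fraction of amplified cells stepping k -> k+1
    amp_down: float = 0.10
    c_amp: float = 0.02  # growth cost per extra copy per unit amplicon length
    boost_point: float = 6.0  # expression boost (multiples of leaky) per type
    boost_is: float = 6.0
    boost_cooption: float = 9.0
    secondary_rate_factor: float = 60.0  # boost mutations on amplified lineages
    noise_sd: float = 0.04  # lognormal sigma per channel

    def __post_init__(self) -> None:
        for name in (
            "rate_point", "rate_is", "rate_cooption", "dup_rate_basal",
            "dup_rate_homology", "amp_up", "amp_down",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ScenarioPreset:
    """Neighborhood scenario: flanking homology raises the duplication rate;
    the amplicon length factor scales amplification cost; promoter co-option
    is only available at some loci."""

    name: str
    flanking_homology: bool
    amplicon_len_factor: float
    cooption_available: bool
    baseline_expression: float = 1.0


PRESETS: dict[str, ScenarioPreset] = {
    p.name: p
    for p in [
        ScenarioPreset("A", False, 6.0, False),
        ScenarioPreset("B", True, 1.0, True),
        ScenarioPreset("C", False, 2.0, False),
        ScenarioPreset("D", False, 2.0, True),
        ScenarioPreset("E", True, 0.3, False),
        ScenarioPreset("BdIS5I", False, 8.0, False),
    ]
}


def get_preset(name: str) -> ScenarioPreset:
    key = name.replace("Δ", "d")  # accept the delta spelling
    if key not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[key]


def default_schedule(days: int = 10) -> Schedule:
    return make_schedule(mic=1.0, days=days, start_fraction=0.5, total_fold=10.0)


# genotype key: (label, k, boost); expression = k * (baseline + boost)


def _expression(preset: ScenarioPreset, k: int, boost: float) -> float:
    return k * (preset.baseline_expression + boost)


def _cost(params: SimParams, preset: ScenarioPreset, k: int, boost: float) -> float:
    cost = params.c_amp * (k - 1) * preset.amplicon_len_factor
    if boost > 0:
        cost += 0.02  # small cost of non-amplification up-mutations
    return min(cost, 0.95)


def simulate_well(
    params: SimParams,
    preset: ScenarioPreset,
    schedule: Schedule,
    seed: int | np.random.Generator,
) -> tuple[PlateSeries, dict]:
    """Simulate one well for ``params.days`` days under ``schedule``.

    Daily cycle: Poisson dilution sampling per genotype -> growth or decline
    under the day's relative drug concentration (capacity-capped, cost-
    penalized) -> mutation events (duplication elevated under flanking
    homology; boost mutations; biased copy-number walk for amplified
    lineages) -> noisy OD/YFP/CFP readout.

    Returns the plate series plus a ground-truth dict with the dominant
    genotype path and final composition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(schedule.concentrations) != params.days:
        raise ValueError("schedule length must equal params.days")
    rel = schedule.relative_concentrations

    pop: dict[tuple[str, int, float], float] = {("ancestral", 1, 0.0): params.capacity}
    dup_rate = (
        params.dup_rate_homology if preset.flanking_homology else params.dup_rate_basal
    )

    od, yfp, cfp = [], [], []
    dominant_path = []
    for day in range(params.days):
        # --- dilution bottleneck ---
        diluted: dict[tuple[str, int, float], float] = {}
        for g, cells in pop.items():
            founders = rng.poisson(cells / params.dilution)
            if founders > 0:
                diluted[g] = float(founders)
        pop = diluted

        # --- growth / decline under the day's drug concentration ---
        c_rel = rel[day]
        grown: dict[tuple[str, int, float], float] = {}
        for (label, k, boost), cells in pop.items():
            e = _expression(preset, k, boost)
            if e > c_rel:
                # cost scales the growth exponent: a heavily burdened genotype
                # may grow too slowly to outpace the daily dilution
                factor = params.growth_fold ** (1.0 - _cost(params, preset, k, boost))
            else:
                factor = params.decline_fold
            grown[(label, k, boost)] = cells * factor
        total = sum(grown.values())
        if total > params.capacity:
            scale = params.capacity / total
            grown = {g: c * scale for g, c in grown.items()}
        pop = grown

        # --- mutation and copy-number dynamics ---
        # mutation events scale with the day's divisions (~ final cell count);
        # a clone founded mid-growth ends the day at mutant_clone_size cells
        updates: dict[tuple[str, int, float], float] = {}
        clone = params.mutant_clone_size

        def move(src, dst, amount):
            if amount <= 0:
                return
            amount = min(amount, pop.get(src, 0.0) + updates.get(src, 0.0))
            updates[src] = updates.get(src, 0.0) - amount
            updates[dst] = updates.get(dst, 0.0) + amount

        for (label, k, boost), cells in list(pop.items()):
            if label == "ancestral":
                move(("ancestral", 1, 0.0), ("amplified", 2, 0.0),
                     rng.poisson(cells * dup_rate) * clone)
                move(("ancestral", 1, 0.0), ("point", 1, params.boost_point),
                     rng.poisson(cells * params.rate_point) * clone)
                move(("ancestral", 1, 0.0), ("is_insertion", 1, params.boost_is),
                     rng.poisson(cells * params.rate_is) * clone)
                if preset.cooption_available:
                    move(("ancestral", 1, 0.0), ("cooption", 1, params.boost_cooption),
                         rng.poisson(cells * params.rate_cooption) * clone)
            elif label.startswith("amplified"):
                src = (label, k, boost)
                move(src, (label, k + 1, boost), params.amp_up * cells)
                if k > 2:
                    move(src, (label, k - 1, boost), params.amp_down * cells)
                elif k == 2:
                    down = ("ancestral", 1, 0.0) if boost == 0 else (label.split("+")[1], 1, boost)
                    move(src, down, params.amp_down * cells)
                if boost == 0:
                    rate2 = params.secondary_rate_factor * (
                        params.rate_cooption if preset.cooption_available else params.rate_point
                    )
                    lbl2 = "amplified+cooption" if preset.cooption_available else "amplified+point"
                    b2 = params.boost_cooption if preset.cooption_available else params.boost_point
                    move(src, (lbl2, k, b2), rng.poisson(cells * rate2) * clone)
        for g, delta in updates.items():
            pop[g] = pop.get(g, 0.0) + delta
        pop = {g: c for g, c in pop.items() if c >= 1.0}

        # --- readout ---
        total = sum(pop.values())
        biomass = total / params.capacity
        sum_e = sum(c * _expression(preset, k, b) for (label, k, b), c in pop.items())
        sum_k = sum(c * k for (label, k, b), c in pop.items())
        od_val = params.od_floor + biomass * params.od_saturated * rng.lognormal(
            0.0, params.noise_sd
        )
        yfp_val = params.yfp_gain * (sum_e / params.capacity) * rng.lognormal(
            0.0, params.noise_sd
        )
        cfp_val = params.cfp_gain * (sum_k / params.capacity) * rng.lognormal(
            0.0, params.noise_sd
        )
        od.append(od_val)
        yfp.append(yfp_val)
        cfp.append(cfp_val)
        if pop:
            dom = max(pop, key=pop.get)
            dominant_path.append(dom[0])
        else:
            dominant_path.append("extinct")

    total = sum(pop.values())
    if pop:
        dom_label, dom_k, dom_boost = max(pop, key=pop.get)
        dom_frac = pop[max(pop, key=pop.get)] / total
        mean_k = sum(c * k for (_, k, _b), c in pop.items()) / total
        mean_e = sum(c * _expression(preset, k, b) for (_, k, b), c in pop.items()) / total
    else:
        dom_label, dom_k, dom_boost, dom_frac, mean_k, mean_e = "extinct", 0, 0.0, 1.0, 0.0, 0.0

    truth = {
        "rescued_truth": total / params.capacity * params.od_saturated + params.od_floor > 0.075,
        "dominant_label": dom_label,
        "dominant_k": dom_k,
        "dominant_boost": dom_boost,
        "dominant_fraction": dom_frac,
        "mean_k_final": mean_k,
        "mean_expression_final": mean_e,
        "dominant_path": dominant_path,
    }
    series = PlateSeries(
        plate_id=f"sim-{preset.name}",
        well="A01",
        days=np.arange(1, params.days + 1),
        od600=np.array(od),
        yfp=np.array(yfp),
        cfp=np.array(cfp),
    )
    return series, truth


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGH"
    names = [f"{r}{c:02d}" for r in rows for c in range(1, 13)]
    if n <= len(names):
        return names[:n]
    return names + [f"X{i:03d}" for i in range(n - len(names))]


def simulate_plate(
    params: SimParams,
    preset: ScenarioPreset,
    schedule: Schedule,
    n_wells: int = 95,
    seed: int = 0,
) -> tuple[list[PlateSeries], pd.DataFrame]:
    """Simulate independent wells with per-well child seeds; returns the
    plate series list and a per-well ground-truth table."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_wells)
    wells = _well_names(n_wells)
    plate, rows = [], []
    for i in range(n_wells):
        series, truth = simulate_well(
            params, preset, schedule, np.random.default_rng(children[i])
        )
        series.well = wells[i]
        plate.append(series)
        truth.pop("dominant_path")
        rows.append({"plate_id": series.plate_id, "well": wells[i], **truth})
    return plate, pd.DataFrame(rows)


def simulate_ancestor_plate(
    params: SimParams,
    preset: ScenarioPreset,
    n_wells: int = 95,
    seed: int = 0,
) -> list[tuple[float, float, float]]:
    """Single-timepoint ancestor readings grown 1 day without drug, for
    building the ancestral fluorescence reference."""
    zero = Schedule(days=(1,), concentrations=(0.0,), mic=1.0)
    p1 = replace(params, days=1)
    readings = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_wells):
        series, _ = simulate_well(p1, preset, zero, np.random.default_rng(child))
        readings.append((float(series.od600[0]), float(series.yfp[0]), float(series.cfp[0])))
    return readings


# ---------------------------------------------------------------------------
# toy annotation fixtures
# ---------------------------------------------------------------------------


@dataclass
class ToyAnnotationTruth:
    """Construction-time ground truth for a generated toy genome."""

    tiers: dict[str, str] = field(default_factory=dict)
    rho_set: set[str] = field(default_factory=set)
    deletion_set: set[str] = field(default_factory=set)
    duplicate_set: set[str] = field(default_factory=set)
    planted_repeats: list[tuple[int, int, int, int]] = field(default_factory=list)
    # (start1, start2, length, hamming)


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(rng: random.Random, seq: str, n_mismatch: int) -> str:
    s = list(seq)
    for i in rng.sample(range(len(s)), n_mismatch):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


def make_toy_annotation(
    seed: int = 0,
    *,
    n_locus_b: int = 1,
    n_locus_d: int = 1,
    n_locus_a: int = 1,
    repeat_len: int = 250,
    repeat_hamming: int = 4,
    spacer: int = 1500,
) -> tuple[str, AnnotationBundle, ToyAnnotationTruth]:
    """Generate a random linear genome with planted neighborhoods of three
    archetypes, with tier ground truth known by construction.

    * locus-B-like: upstream essential gene, then a co-oriented primary
      promoter and a co-oriented Rho-dependent terminator, then the focal
      gene — all inside a planted direct-repeat pair (tier ``high``);
    * locus-D-like: the same layout without flanking repeats (``medium``);
    * locus-A-like: promoter, then an essential gene, then an intrinsic
      terminator before the focal gene (``low``: the essential gene blocks
      deletion co-option and the nearest terminator is intrinsic).

    Helper essential genes are placed on the minus strand, so they are never
    co-oriented with any planted promoter/terminator and are tier ``low`` by
    construction; an intrinsic trailer terminator after each neighborhood
    insulates the upstream scans of the following one.
    """
    rng = random.Random(seed)
    truth = ToyAnnotationTruth()
    parts: list[str] = []
    genes: list[Gene] = []
    promoters: list[Promoter] = []
    terminators: list[Terminator] = []
    offset = 0

    def emit(seq: str) -> int:
        nonlocal offset
        parts.append(seq)
        start = offset
        offset += len(seq)
        return start

    def spacer_block(n: int | None = None) -> None:
        emit(_random_dna(rng, n if n is not None else spacer))

    gene_len = 300
    counter = 0

    def plant_neighborhood(kind: str) -> None:
        nonlocal counter
        counter += 1
        gid = f"{kind}{counter}"
        repeat_seq = None
        repeat1 = None
        if kind == "locusB":
            repeat_seq = _random_dna(rng, repeat_len)
            repeat1 = emit(repeat_seq)
            spacer_block(400)
        ess_start = emit(_random_dna(rng, gene_len))
        genes.append(Gene(f"ess_{gid}", ess_start, ess_start + gene_len, "-", essential=True))
        truth.tiers[f"ess_{gid}"] = "low"
        spacer_block(300)
        if kind in ("locusB", "locusD"):
            p_start = emit(_random_dna(rng, 60))
            promoters.append(Promoter(p_start + 30, "+", primary=True))
            spacer_block(300)
            t_start = emit(_random_dna(rng, 40))
            terminators.append(Terminator(t_start + 20, "+", mode="rho"))
            spacer_block(300)
        else:  # locusA: the essential gene sits between the promoter and gene
            p_start = emit(_random_dna(rng, 60))
            promoters.append(Promoter(p_start + 30, "+", primary=True))
            spacer_block(200)
            ess2 = emit(_random_dna(rng, gene_len))
            genes.append(Gene(f"ess2_{gid}", ess2, ess2 + gene_len, "-", essential=True))
            truth.tiers[f"ess2_{gid}"] = "low"
            spacer_block(200)
            t_start = emit(_random_dna(rng, 40))
            terminators.append(Terminator(t_start + 20, "+", mode="intrinsic"))
            spacer_block(200)
        g_start = emit(_random_dna(rng, gene_len))
        genes.append(Gene(gid, g_start, g_start + gene_len, "+", essential=False))
        if kind == "locusB":
            spacer_block(400)
            repeat2 = emit(_mutate(rng, repeat_seq, repeat_hamming))
            truth.planted_repeats.append((repeat1, repeat2, repeat_len, repeat_hamming))
            truth.duplicate_set.update({gid, f"ess_{gid}"})
        # intrinsic trailer terminator insulates the next neighborhood
        spacer_block(150)
        trailer = emit(_random_dna(rng, 40))
        terminators.append(Terminator(trailer + 20, "+", mode="intrinsic"))
        if kind in ("locusB", "locusD"):
            truth.rho_set.add(gid)
            truth.deletion_set.add(gid)
        truth.tiers[gid] = {"locusB": "high", "locusD": "medium", "locusA": "low"}[kind]

    spacer_block()
    for _ in range(n_locus_a):
        plant_neighborhood("locusA")
        spacer_block()
    for _ in range(n_locus_d):
        plant_neighborhood("locusD")
        spacer_block()
    for _ in range(n_locus_b):
        plant_neighborhood("locusB")
        spacer_block()

    sequence = "".join(parts)
    bundle = AnnotationBundle(
        genome_length=len(sequence),
        circular=False,
        genes=genes,
        promoters=promoters,
        terminators=terminators,
        sequence=sequence,
    )
    return sequence, bundle, truth
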
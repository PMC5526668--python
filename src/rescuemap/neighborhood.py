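"""Chromosomal-neighborhood analysis: direct-repeat detection with Hamming
tolerance, strand-aware upstream scans for terminators and promoters, and the
three-set classification of per-gene adaptive potential.

Repeat contract
---------------
A reported repeat is a pair of equal-length, same-strand (forward) segments
``copy1 = [s1, s1+L)`` and ``copy2 = [s2, s2+L)`` with ``s1 < s2`` such that

* ``L >= min_len`` and the Hamming distance between the copies is
  ``<= max_mismatch``;
* the copies start and end with matching bases (trimmed / maximal: the pair
  cannot be extended in either direction without exceeding the mismatch
  budget);
* the gap ``s2 - (s1 + L)`` lies in ``[min_gap, max_gap]`` (copies never
  overlap);
* pairs contained in a longer reported pair on the same offset are
  suppressed.

The search uses exact k-mer seeding with ``k = max(4, min_len // (max_mismatch
+ 1))`` — by pigeonhole, every qualifying pair contains an exact common run of
at least that length, so seeding misses nothing an exhaustive scan would find.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationBundle, Gene, Terminator

__all__ = [
    "RepeatRegion",
    "SetMembership",
    "find_direct_repeats",
    "genes_between_repeats",
    "closest_upstream_terminator",
    "rho_terminated_set",
    "deletion_cooption_set",
    "duplicate_flanked_set",
    "classify_genes",
    "VENN_CELLS",
]


@dataclass(frozen=True)
class RepeatRegion:
    """A direct-repeat pair and the interval between the two copies."""

    copy1: tuple[int, int]
    copy2: tuple[int, int]
    repeat_length: int
    hamming: int
    gap: int

    @property
    def region(self) -> tuple[int, int]:
        """Inter-repeat interval (end of copy1 to start of copy2)."""
        return (self.copy1[1], self.copy2[0])

    def bed_name(self) -> str:
        return f"len={self.repeat_length};ham={self.hamming};gap={self.gap}"


@dataclass
class SetMembership:
    gene_id: str
    in_rho_set: bool
    in_deletion_set: bool
    in_duplicate_set: bool
    tier: str = field(init=False)

    def __post_init__(self) -> None:
        flags = (self.in_rho_set, self.in_deletion_set, self.in_duplicate_set)
        if all(flags):
            self.tier = "high"
        elif self.in_rho_set or self.in_deletion_set:
            self.tier = "medium"
        else:
            self.tier = "low"


# ---------------------------------------------------------------------------
# direct repeats
# ---------------------------------------------------------------------------


def _maximal_windows(mismatch_pos: np.ndarray, m: int, h: int) -> list[tuple[int, int, int]]:
    """Maximal (trimmed) windows on one diagonal.

    ``mismatch_pos`` are the mismatching offsets within the comparable range
    ``[0, m)``; returns ``(start, end, n_mismatch)`` windows containing at
    most ``h`` mismatches that cannot be extended and whose ends match.
    """
    mis = mismatch_pos
    if len(mis) <= h:
        lo, hi = 0, m
        # trim mismatching ends
        j = 0
        while j < len(mis) and mis[j] == lo:
            lo += 1
            j += 1
        j = len(mis) - 1
        while j >= 0 and mis[j] == hi - 1:
            hi -= 1
            j -= 1
        if hi > lo:
            inside = int(np.count_nonzero((mis >= lo) & (mis < hi)))
            return [(lo, hi, inside)]
        return []
    pad = np.concatenate(([-1], mis, [m]))
    out = []
    for i in range(len(pad) - h - 1):
        lo = int(pad[i]) + 1
        hi = int(pad[i + h + 1])
        if hi <= lo:
            continue
        # trim consecutive mismatches at the edges
        j = i + 1
        while j <= i + h and pad[j] == lo:
            lo += 1
            j += 1
        j = i + h
        while j >= i + 1 and pad[j] == hi - 1:
            hi -= 1
            j -= 1
        if hi > lo:
            inside = int(np.count_nonzero((mis >= lo) & (mis < hi)))
            out.append((lo, hi, inside))
    # drop windows contained in another window
    out = sorted(set(out))
    keep = []
    for w in out:
        if not any(
            o != w and o[0] <= w[0] and o[1] >= w[1] for o in out
        ):
            keep.append(w)
    return keep


def find_direct_repeats(
    sequence: str,
    min_len: int = 200,
    max_mismatch: int = 8,
    max_gap: int = 100_000,
    min_gap: int = 200,
    circular: bool = False,
) -> list[RepeatRegion]:
    """Find all maximal forward (direct) repeat pairs meeting the criteria.

    On a circular sequence the search additionally considers pairs whose
    second copy or gap wraps the origin; wrapped coordinates are reported
    modulo the sequence length.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_len + min_gap:
        return []
    k = max(4, min_len // (max_mismatch + 1))

    search_seq = seq + seq[: min(n, max_gap + 2 * min_len + max_mismatch)] if circular else seq
    arr = np.frombuffer(search_seq.encode("ascii"), dtype=np.uint8)
    ns = len(arr)

    # diagonals carrying at least one exact k-mer seed pair
    kmer_pos: dict[bytes, list[int]] = defaultdict(list)
    raw = search_seq.encode("ascii")
    for i in range(ns - k + 1):
        kmer_pos[raw[i : i + k]].append(i)
    diagonals: set[int] = set()
    max_d = max_gap + ns  # gap filter applied later; cap only for safety
    for positions in kmer_pos.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            if positions[a] >= n:  # first copy must start in the primary span
                break
            for b in range(a + 1, len(positions)):
                d = positions[b] - positions[a]
                if min_len <= d <= max_d:
                    diagonals.add(d)

    found: set[tuple[int, int, int, int]] = set()
    for d in sorted(diagonals):
        m = ns - d
        if m < min_len:
            continue
        mis = np.flatnonzero(arr[:m] != arr[d:])
        for lo, hi, ham in _maximal_windows(mis, m, max_mismatch):
            L = hi - lo
            s1, s2 = lo, lo + d
            gap = d - L
            if L < min_len or gap < min_gap or gap > max_gap:
                continue
            if s1 >= n:
                continue
            if circular:
                if s2 - s1 >= n:  # pairing a copy with itself around the circle
                    continue
                key = (s1 % n, s2 % n, L, ham)
            else:
                key = (s1, s2, L, ham)
            found.add(key)

    repeats = [
        RepeatRegion(
            copy1=(s1, s1 + L),
            copy2=(s2, s2 + L),
            repeat_length=L,
            hamming=ham,
            gap=s2 - s1 - L,
        )
        for (s1, s2, L, ham) in found
    ]
    return sorted(repeats, key=lambda r: (r.copy1, r.copy2))


# ---------------------------------------------------------------------------
# strand-aware upstream scans
# ---------------------------------------------------------------------------


def _upstream_distance(gene: Gene, pos: int, genome_length: int, circular: bool) -> float:
    """Distance (in bp, >= 1) from the gene's 5' end to a strictly upstream
    point, scanning against the gene's direction of transcription; ``inf`` if
    the point is not upstream (linear genome) or coincides with the 5' base.
    """
    if gene.strand == "+":
        d = gene.start - pos
    else:
        d = pos - (gene.end - 1)
    if d >= 1:
        return float(d)
    if circular:
        return float(d % genome_length) if d % genome_length >= 1 else float("inf")
    return float("inf")


def closest_upstream_terminator(
    gene: Gene,
    terminators: list[Terminator],
    genome_length: int,
    circular: bool = True,
) -> Terminator | None:
    """Nearest co-oriented terminator strictly upstream of the gene start,
    wrapping the origin on circular genomes; ``None`` if no co-oriented
    terminator is upstream."""
    best: Terminator | None = None
    best_d = float("inf")
    for t in terminators:
        if t.strand != gene.strand:
            continue
        d = _upstream_distance(gene, t.pos, genome_length, circular)
        if d < best_d:
            best, best_d = t, d
    return best


def rho_terminated_set(annotation: AnnotationBundle) -> set[str]:
    """Genes whose closest upstream co-oriented terminator is Rho-dependent
    (read-through candidates)."""
    out = set()
    for g in annotation.genes:
        t = closest_upstream_terminator(
            g, annotation.terminators, annotation.genome_length, annotation.circular
        )
        if t is not None and t.mode == "rho":
            out.add(g.id)
    return out


def _next_upstream_essential_distance(
    gene: Gene, annotation: AnnotationBundle
) -> float:
    """Distance to the proximal edge of the nearest upstream essential gene;
    ``inf`` if there is none (deletions upstream are then unconstrained)."""
    best = float("inf")
    for other in annotation.genes:
        if not other.essential or other.id == gene.id:
            continue
        # the deletion may extend up to the essential gene's nearest base
        edge = other.end - 1 if gene.strand == "+" else other.start
        d = _upstream_distance(gene, edge, annotation.genome_length, annotation.circular)
        best = min(best, d)
    return best


def deletion_cooption_set(annotation: AnnotationBundle) -> set[str]:
    """Genes to which a co-oriented primary promoter could be co-opted by a
    deletion that removes no essential gene.

    A gene qualifies iff, within the upstream interval bounded by the next
    upstream essential gene, there is a co-oriented primary promoter P and a
    co-oriented terminator strictly between P and the gene (without an
    intervening terminator the promoter already reads into the gene and there
    is nothing for a deletion to co-opt)."""
    out = set()
    for g in annotation.genes:
        bound = _next_upstream_essential_distance(g, annotation)
        term_d = sorted(
            d
            for t in annotation.terminators
            if t.strand == g.strand
            and (d := _upstream_distance(g, t.pos, annotation.genome_length, annotation.circular))
            < bound
        )
        if not term_d:
            continue
        nearest_term = term_d[0]
        for p in annotation.promoters:
            if p.strand != g.strand or not p.primary:
                continue
            d_p = _upstream_distance(g, p.pos, annotation.genome_length, annotation.circular)
            # promoter inside the deletable interval, terminator between it and gene
            if d_p < bound and nearest_term < d_p:
                out.add(g.id)
                break
    return out


def genes_between_repeats(
    repeats: list[RepeatRegion],
    genes: list[Gene],
    *,
    min_region_span: int = 0,
    exclude: set[str] | None = None,
) -> set[str]:
    """Genes entirely contained in an inter-repeat interval.

    Boundary-straddling genes are excluded (full-containment rule).
    ``min_region_span`` drops regions between closely spaced repeats;
    ``exclude`` removes individually curated gene ids.
    """
    exclude = exclude or set()
    out = set()
    for r in repeats:
        lo, hi = r.region
        if hi - lo < min_region_span:
            continue
        for g in genes:
            if g.id in exclude:
                continue
            if lo <= g.start and g.end <= hi:
                out.add(g.id)
    return out


VENN_CELLS = (
    "rho_only",
    "deletion_only",
    "duplicate_only",
    "rho_deletion",
    "rho_duplicate",
    "deletion_duplicate",
    "all_three",
    "none",
)


def classify_genes(
    annotation: AnnotationBundle,
    repeats: list[RepeatRegion],
    *,
    min_region_span: int = 0,
    exclude: set[str] | None = None,
) -> tuple[list[SetMembership], dict[str, int]]:
    """Build all three neighborhood property sets and assign tiers.

    Tier map: ``high`` = member of all three sets; ``medium`` = member of at
    least one promoter co-option set (Rho read-through or deletion) but not
    all three; ``low`` = member of neither co-option set. Returns the per-gene
    memberships plus the 7 Venn intersection cells and the outside count
    (cells sum to the number of genes)."""
    rho = rho_terminated_set(annotation)
    dele = deletion_cooption_set(annotation)
    dup = genes_between_repeats(
        repeats, annotation.genes, min_region_span=min_region_span, exclude=exclude
    )
    members = [
        SetMembership(g.id, g.id in rho, g.id in dele, g.id in dup)
        for g in annotation.genes
    ]
    counts = dict.fromkeys(VENN_CELLS, 0)
    for m in members:
        key = {
            (True, False, False): "rho_only",
            (False, True, False): "deletion_only",
            (False, False, True): "duplicate_only",
            (True, True, False): "rho_deletion",
            (True, False, True): "rho_duplicate",
            (False, True, True): "deletion_duplicate",
            (True, True, True): "all_three",
            (False, False, False): "none",
        }[(m.in_rho_set, m.in_deletion_set, m.in_duplicate_set)]
        counts[key] += 1
    return members, counts


def duplicate_flanked_set(
    annotation: AnnotationBundle,
    repeats: list[RepeatRegion],
    **kwargs,
) -> set[str]:
    """Convenience wrapper: gene ids between flanking duplicates."""
    return genes_between_repeats(repeats, annotation.genes, **kwargs)
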
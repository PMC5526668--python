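import random

import pytest

from repeat_oracle import brute_force_direct_repeats
from rescuemap.io import AnnotationBundle, Gene, Promoter, Terminator
from rescuemap.neighborhood import (
    RepeatRegion,
    classify_genes,
    closest_upstream_terminator,
    deletion_cooption_set,
    find_direct_repeats,
    genes_between_repeats,
    rho_terminated_set,
)
from rescuemap.simulate import make_toy_annotation


def rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng, s, h):
    s = list(s)
    for i in rng.sample(range(len(s)), h):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


class TestFindDirectRepeats:
    def test_planted_repeat_found_exactly(self):
        rng = random.Random(0)
        copy = rand_dna(rng, 250)
        seq = rand_dna(rng, 1000) + copy + rand_dna(rng, 1000) + mutate(rng, copy, 3) + rand_dna(rng, 1000)
        found = find_direct_repeats(seq, min_len=200, max_mismatch=8, min_gap=200, max_gap=100_000)
        got = {(r.copy1[0], r.copy2[0], r.repeat_length, r.hamming) for r in found}
        exp = brute_force_direct_repeats(seq, 200, 8, 100_000, 200)
        assert got == exp
        assert any(
            r.copy1[0] <= 1000 <= r.copy1[1] or (r.copy1[0] >= 990 and r.hamming >= 3)
            for r in found
        )
        # the planted pair is recovered (possibly extended a few bases)
        best = max(found, key=lambda r: r.repeat_length)
        assert best.copy1[0] <= 1000 and best.copy1[1] >= 1250
        assert best.hamming >= 3

    def test_random_sequence_has_no_long_repeats(self):
        rng = random.Random(1)
        seq = rand_dna(rng, 5000)
        assert find_direct_repeats(seq) == []
        assert brute_force_direct_repeats(seq, 200, 8, 100_000, 200) == set()

    def test_min_gap_excludes_close_pair(self):
        rng = random.Random(2)
        copy = rand_dna(rng, 200)
        seq = rand_dna(rng, 500) + copy + rand_dna(rng, 150) + copy + rand_dna(rng, 500)
        assert find_direct_repeats(seq, max_mismatch=0, min_gap=200) == []
        # relaxing min_gap recovers it (exact match: no flank extension)
        found = find_direct_repeats(seq, max_mismatch=0, min_gap=100)
        assert len(found) == 1
        assert found[0].gap == 150
        assert found[0].repeat_length == 200

    def test_max_gap_excludes_distant_pair(self):
        rng = random.Random(3)
        copy = rand_dna(rng, 200)
        seq = rand_dna(rng, 100) + copy + rand_dna(rng, 3000) + copy + rand_dna(rng, 100)
        assert find_direct_repeats(seq, max_mismatch=0, max_gap=2000) == []
        assert len(find_direct_repeats(seq, max_mismatch=0, max_gap=5000)) == 1

    def test_too_short_sequence(self):
        assert find_direct_repeats("ACGT" * 50) == []

    def test_circular_wrap_pair(self):
        rng = random.Random(4)
        copy = rand_dna(rng, 220)
        # copy2 wraps: second copy placed at the very end plus start
        seq = copy[100:] + rand_dna(rng, 600) + copy + rand_dna(rng, 600) + copy[:100]
        linear = find_direct_repeats(seq, min_len=200, min_gap=200)
        circular = find_direct_repeats(seq, min_len=200, min_gap=200, circular=True)
        assert linear == []
        assert any(r.repeat_length >= 200 for r in circular)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_randomized(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1500, 4000)
        seq = rand_dna(rng, n)
        min_len = rng.choice([100, 150, 200])
        h = rng.choice([0, 2, 5, 8])
        for _ in range(rng.randint(0, 2)):
            L = min_len + rng.randint(-5, 60)
            ham = max(0, min(h, L))
            gap = rng.choice([180, 200, 500, 1200])
            s1 = rng.randint(0, max(0, n - 2 * L - gap - 1))
            s2 = s1 + L + gap
            if s2 + L <= n:
                seq = seq[:s2] + mutate(rng, seq[s1 : s1 + L], ham) + seq[s2 + L :]
        got = {
            (r.copy1[0], r.copy2[0], r.repeat_length, r.hamming)
            for r in find_direct_repeats(seq, min_len, h, 100_000, 200)
        }
        assert got == brute_force_direct_repeats(seq, min_len, h, 100_000, 200)


def region(c1, c2, length=200, hamming=0):
    return RepeatRegion(
        copy1=(c1, c1 + length),
        copy2=(c2, c2 + length),
        repeat_length=length,
        hamming=hamming,
        gap=c2 - c1 - length,
    )


class TestGenesBetweenRepeats:
    def test_containment_rule(self):
        r = region(0, 1000)  # region = (200, 1000)
        genes = [
            Gene("inside", 300, 500, "+"),
            Gene("straddles_copy", 150, 400, "+"),
            Gene("outside", 1200, 1400, "+"),
        ]
        assert genes_between_repeats([r], genes) == {"inside"}

    def test_min_region_span_and_exclusions(self):
        r = region(0, 500)  # region span 300
        genes = [Gene("g", 250, 400, "+")]
        assert genes_between_repeats([r], genes, min_region_span=400) == set()
        assert genes_between_repeats([r], genes, exclude={"g"}) == set()


def bundle(genes=(), promoters=(), terminators=(), length=10_000, circular=True):
    return AnnotationBundle(
        genome_length=length,
        circular=circular,
        genes=list(genes),
        promoters=list(promoters),
        terminators=list(terminators),
    )


class TestUpstreamScans:
    def test_nearest_cooriented_terminator_plus(self):
        g = Gene("g", 1000, 1300, "+")
        ts = [Terminator(400, "+"), Terminator(800, "+"), Terminator(900, "-")]
        best = closest_upstream_terminator(g, ts, 10_000, circular=False)
        assert best.pos == 800

    def test_minus_strand_scans_higher_coordinates(self):
        g = Gene("g", 1000, 1300, "-")
        ts = [Terminator(400, "-"), Terminator(2000, "-"), Terminator(1500, "+")]
        best = closest_upstream_terminator(g, ts, 10_000, circular=False)
        assert best.pos == 2000

    def test_circular_wrap(self):
        g = Gene("g", 50, 350, "+")
        ts = [Terminator(9900, "+")]
        assert closest_upstream_terminator(g, ts, 10_000, circular=True).pos == 9900
        assert closest_upstream_terminator(g, ts, 10_000, circular=False) is None

    def test_no_coriented_terminator(self):
        g = Gene("g", 1000, 1300, "+")
        assert closest_upstream_terminator(g, [Terminator(500, "-")], 10_000, True) is None


class TestRhoSet:
    def test_rho_upstream_in_set(self):
        b = bundle(
            genes=[Gene("g", 5000, 5300, "+")],
            terminators=[Terminator(4000, "+", "intrinsic"), Terminator(4500, "+", "rho")],
        )
        assert rho_terminated_set(b) == {"g"}

    def test_intrinsic_nearest_not_in_set(self):
        b = bundle(
            genes=[Gene("g", 5000, 5300, "+")],
            terminators=[Terminator(4000, "+", "rho"), Terminator(4500, "+", "intrinsic")],
        )
        assert rho_terminated_set(b) == set()

    def test_no_upstream_terminator_not_in_set(self):
        b = bundle(genes=[Gene("g", 5000, 5300, "+")], circular=False)
        assert rho_terminated_set(b) == set()


class TestDeletionSet:
    def test_promoter_and_terminator_before_essential(self):
        b = bundle(
            genes=[
                Gene("ess", 1000, 1300, "-", essential=True),
                Gene("g", 5000, 5300, "+"),
            ],
            promoters=[Promoter(2000, "+", primary=True)],
            terminators=[Terminator(3000, "+", "intrinsic")],
            circular=False,
        )
        assert deletion_cooption_set(b) == {"g"}

    def test_essential_gene_blocks(self):
        # essential gene between the promoter and the focal gene
        b = bundle(
            genes=[
                Gene("ess", 3500, 3800, "-", essential=True),
                Gene("g", 5000, 5300, "+"),
            ],
            promoters=[Promoter(2000, "+", primary=True)],
            terminators=[Terminator(4000, "+", "intrinsic")],
            circular=False,
        )
        assert deletion_cooption_set(b) == set()

    def test_no_terminator_between_promoter_and_gene(self):
        # the promoter already reads into the gene; nothing to co-opt
        b = bundle(
            genes=[Gene("g", 5000, 5300, "+")],
            promoters=[Promoter(2000, "+", primary=True)],
            circular=False,
        )
        assert deletion_cooption_set(b) == set()

    def test_secondary_promoter_ignored(self):
        b = bundle(
            genes=[Gene("g", 5000, 5300, "+")],
            promoters=[Promoter(2000, "+", primary=False)],
            terminators=[Terminator(3000, "+", "intrinsic")],
            circular=False,
        )
        assert deletion_cooption_set(b) == set()

    def test_terminator_must_be_between_promoter_and_gene(self):
        # terminator upstream of the promoter does not count
        b = bundle(
            genes=[Gene("g", 5000, 5300, "+")],
            promoters=[Promoter(3000, "+", primary=True)],
            terminators=[Terminator(2000, "+", "intrinsic")],
            circular=False,
        )
        assert deletion_cooption_set(b) == set()


class TestClassifyGenes:
    def test_toy_tiers_recovered(self):
        seq, b, truth = make_toy_annotation(seed=5)
        repeats = find_direct_repeats(seq, circular=False)
        members, venn = classify_genes(b, repeats)
        assert {m.gene_id: m.tier for m in members} == truth.tiers
        assert sum(venn.values()) == len(b.genes)

    def test_tier_map(self):
        seq, b, truth = make_toy_annotation(seed=6)
        repeats = find_direct_repeats(seq, circular=False)
        members, _ = classify_genes(b, repeats)
        by_id = {m.gene_id: m for m in members}
        for gid, tier in truth.tiers.items():
            m = by_id[gid]
            if tier == "high":
                assert m.in_rho_set and m.in_deletion_set and m.in_duplicate_set
            elif tier == "low":
                assert not m.in_rho_set and not m.in_deletion_set

    def test_strand_symmetry(self):
        """Reverse-complementing the genome and flipping strands leaves
        every set membership invariant."""
        seq, b, _ = make_toy_annotation(seed=7)
        repeats = find_direct_repeats(seq, circular=False)
        members_fwd, venn_fwd = classify_genes(b, repeats)
        rc = b.reverse_complement()
        rc_repeats = find_direct_repeats(rc.sequence, circular=False)
        members_rc, venn_rc = classify_genes(rc, rc_repeats)
        fwd = {m.gene_id: (m.in_rho_set, m.in_deletion_set, m.in_duplicate_set)
               for m in members_fwd}
        rev = {m.gene_id: (m.in_rho_set, m.in_deletion_set, m.in_duplicate_set)
               for m in members_rc}
        assert fwd == rev
        assert venn_fwd == venn_rc

    def test_zero_planted_features(self):
        seq, b, truth = make_toy_annotation(seed=8, n_locus_b=0, n_locus_d=0, n_locus_a=1)
        repeats = find_direct_repeats(seq, circular=False)
        members, _ = classify_genes(b, repeats)
        assert all(m.tier == "low" for m in members)
        assert repeats == []
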
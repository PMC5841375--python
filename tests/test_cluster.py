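import numpy as np
import pytest

import hybridotu as h
from hybridotu.cluster import DerepUnit


def unit(r1, r2=None, size=1, sample="s1"):
    members = [(sample, f"rd{i}") for i in range(size)]
    return DerepUnit(r1, r2, size, members)


def _mutate(seq, n_mut, rng):
    s = list(seq)
    for p in rng.choice(len(s), n_mut, replace=False):
        s[p] = "ACGT"[("ACGT".index(s[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(s)


class TestDereplicate:
    def test_collapses_identical_reads(self):
        recs = [("ACGT", "TTAA", "s1", f"r{i}") for i in range(3)]
        recs.append(("GGGG", "TTAA", "s1", "r3"))
        units = h.dereplicate(recs)
        assert [u.size for u in units] == [3, 1]
        assert units[0].sequence_r1 == "ACGT"

    def test_key_is_the_pair_not_r1_alone(self):
        recs = [("ACGT", "TTAA", "s1", "a"), ("ACGT", "TTCC", "s1", "b")]
        assert len(h.dereplicate(recs)) == 2

    def test_empty_input(self):
        assert h.dereplicate([]) == []

    def test_deterministic_order_under_shuffle(self):
        rng = np.random.default_rng(0)
        recs = [
            ("".join(rng.choice(list("ACGT"), 30)), None, "s1", f"r{i}")
            for i in range(20)
        ]
        a = h.dereplicate(recs)
        rng.shuffle(recs)
        b = h.dereplicate(recs)
        assert [u.sequence_r1 for u in a] == [u.sequence_r1 for u in b]


class TestPairIdentity:
    def test_identical_pairs(self):
        u = unit("A" * 50, "C" * 40)
        assert h.pair_identity(u, unit("A" * 50, "C" * 40)) == 1.0

    def test_pooled_arithmetic(self):
        rng = np.random.default_rng(1)
        r1 = "".join(rng.choice(list("ACGT"), 250))
        r2 = "".join(rng.choice(list("ACGT"), 200))
        r2_mut = _mutate(r2, 10, rng)
        got = h.pair_identity(unit(r1, r2), unit(r1, r2_mut))
        assert got == pytest.approx((250 + 190) / 450)

    def test_mixed_presence_is_hard_error(self):
        with pytest.raises(ValueError, match="hybrid"):
            h.pair_identity(unit("ACGT", "ACGT"), unit("ACGT"))

    def test_fast_path_matches_dp_on_equal_lengths(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 120))
            b = _mutate(a, int(rng.integers(0, 8)), rng)
            ua, ub = unit(a, None), unit(b, None)
            assert h.pair_identity(ua, ub, fast=True) == pytest.approx(
                h.pair_identity(ua, ub, fast=False)
            )


class TestGreedyCluster:
    def test_single_unit(self):
        cents, assigns, disc = h.greedy_cluster([unit("A" * 30, "C" * 20)])
        assert len(cents) == 1 and assigns == [cents[0].otu_id] and not disc

    def test_unsorted_input_rejected(self):
        us = [unit("A" * 30, "C" * 20, size=1), unit("G" * 30, "C" * 20, size=5)]
        with pytest.raises(ValueError, match="sorted"):
            h.greedy_cluster(us)

    def test_error_free_species_recovery(self, reference_set):
        refs, _ = reference_set
        rng = np.random.default_rng(5)
        recs = []
        for k, (_, seq) in enumerate(refs[:10]):
            for i in range(12):
                recs.append((seq[:250], h.revcomp(seq[-200:]), "s1", f"sp{k}_{i}"))
        units = h.dereplicate(recs)
        cents, assigns, disc = h.greedy_cluster(units)
        assert len(cents) == 10
        assert not disc
        # perfect membership: each unit is its own centroid founder
        assert sum(c.abundance for c in cents) == 120

    def test_just_below_radius_founds_new_centroid(self):
        # 7 mismatches over a 225-column single-end comparison: 218/225 < 0.97
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 225))
        b = _mutate(a, 7, rng)
        assert 218 / 225 < 0.97
        cents, _, _ = h.greedy_cluster(
            [unit(a, size=5), unit(b, size=1)], chimera_check=False
        )
        assert len(cents) == 2

    def test_at_radius_assigns(self):
        # 3 mismatches over 100+100 pooled columns: 197/200 = 0.985 >= 0.97
        rng = np.random.default_rng(4)
        r1 = "".join(rng.choice(list("ACGT"), 100))
        r2 = "".join(rng.choice(list("ACGT"), 100))
        cents, assigns, _ = h.greedy_cluster(
            [unit(r1, r2, size=5), unit(_mutate(r1, 3, rng), r2, size=1)]
        )
        assert len(cents) == 1
        assert cents[0].abundance == 6

    def test_conservation_and_partition(self, reference_set):
        refs, _ = reference_set
        rng = np.random.default_rng(6)
        recs = []
        for k, (_, seq) in enumerate(refs[:6]):
            for i in range(8):
                r1 = _mutate(seq[:150], int(rng.integers(0, 3)), rng)
                recs.append((r1, None, "s1", f"{k}_{i}"))
        units = h.dereplicate(recs)
        cents, assigns, disc = h.greedy_cluster(units)
        assert sum(c.abundance for c in cents) + sum(
            u.size for u, _ in disc
        ) == sum(u.size for u in units)
        # every unit: assigned, founder, or discarded
        assert all(
            (a is not None) or any(u is du for du, _ in disc)
            for a, u in zip(assigns, units)
        )


class TestDetectChimera:
    def _parents(self, L=450, div_frac=0.10, seed=0):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), L))
        b = _mutate(a, round(div_frac * L), rng)
        return a, b, rng

    def test_constructed_splice_flagged_with_crossover(self):
        a, b, rng = self._parents()
        x = 225
        q = a[:x] + b[x:]
        cents = [
            h.OTU("P_A", a, None, h.Origin.SINGLE_END_NEW, 50),
            h.OTU("P_B", b, None, h.Origin.SINGLE_END_NEW, 40),
        ]
        v = h.detect_chimera(unit(q), cents)
        assert v.is_chimera
        assert v.parent_a == "P_A" and v.parent_b == "P_B"
        # the crossover is identifiable only up to the span between adjacent
        # parent-difference sites: splicing at the reported point must
        # reproduce the query exactly
        assert a[: v.crossover] + b[v.crossover :] == q
        assert v.model_identity == 1.0

    def test_paired_unit_splice_flagged_in_genomic_coordinates(self):
        # crossover inside the reverse segment: still a prefix/suffix splice
        # once the reverse read is viewed in genome orientation
        rng = np.random.default_rng(8)
        A = "".join(rng.choice(list("ACGT"), 694))
        B = _mutate(A, 69, rng)
        x = 600  # falls within the last-200 window
        chimera = A[:x] + B[x:]
        q = unit(chimera[:250], h.revcomp(chimera[-200:]))
        cents = [
            h.OTU("P_A", A[:250], h.revcomp(A[-200:]), h.Origin.PAIRED_BACKBONE, 50),
            h.OTU("P_B", B[:250], h.revcomp(B[-200:]), h.Origin.PAIRED_BACKBONE, 40),
        ]
        v = h.detect_chimera(q, cents)
        assert v.is_chimera

    def test_identical_to_parent_not_chimera(self):
        a, b, _ = self._parents(seed=1)
        cents = [
            h.OTU("P_A", a, None, h.Origin.SINGLE_END_NEW, 50),
            h.OTU("P_B", b, None, h.Origin.SINGLE_END_NEW, 40),
        ]
        assert not h.detect_chimera(unit(a), cents).is_chimera

    def test_distant_query_has_no_candidate_parents(self):
        a, b, rng = self._parents(seed=2)
        far = _mutate(a, 100, rng)  # ~78% identity, below min_parent_id
        cents = [
            h.OTU("P_A", a, None, h.Origin.SINGLE_END_NEW, 50),
            h.OTU("P_B", b, None, h.Origin.SINGLE_END_NEW, 40),
        ]
        assert not h.detect_chimera(unit(far), cents).is_chimera


class TestReferenceScreen:
    def test_no_reference_is_identity(self):
        otus = [h.OTU("O1", "A" * 30, None, h.Origin.SINGLE_END_NEW, 3)]
        assert h.reference_chimera_screen(otus, None) == otus
        assert h.reference_chimera_screen(otus, "") == otus

    def test_exact_splice_removed_clean_otu_kept(self):
        rng = np.random.default_rng(10)
        A = "".join(rng.choice(list("ACGT"), 400))
        B = _mutate(A, 40, rng)
        refs = [("gA", A), ("gB", B)]
        splice = A[:125] + B[125:]  # crossover mid-window: both parents visible
        near_a = _mutate(A, 2, rng)  # ~99% to one reference, non-chimeric
        otus = [
            h.OTU("chi", splice[:250], None, h.Origin.SINGLE_END_NEW, 5),
            h.OTU("ok", near_a[:250], None, h.Origin.SINGLE_END_NEW, 5),
        ]
        kept = h.reference_chimera_screen(otus, refs)
        assert [o.otu_id for o in kept] == ["ok"]
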
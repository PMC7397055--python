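import itertools

import numpy as np
import pytest

from shadowcaster.genome_io import Proteome, TaxonomyRecord
from shadowcaster.shadow import (
    RANKS,
    OrthologPair,
    ShadowSpec,
    allocate_counts,
    bucket_rank,
    fit_vertical_model,
    global_identity,
    rbh_orthologs,
    select_shadow,
)

AMPLE = {r: 100 for r in RANKS}


class TestAllocateCounts:
    def test_default_25_gives_canonical_split(self):
        counts = allocate_counts(ShadowSpec(total=25), AMPLE)
        assert counts == {"family": 10, "order": 5, "phylum": 5, "kingdom": 3, "other_kingdom": 2}

    def test_family_deficit_promotes_to_order(self):
        avail = dict(AMPLE, family=4)
        counts = allocate_counts(ShadowSpec(total=25), avail)
        assert counts == {"family": 4, "order": 11, "phylum": 5, "kingdom": 3, "other_kingdom": 2}

    def test_largest_remainder_at_15(self):
        counts = allocate_counts(ShadowSpec(total=15), AMPLE)
        assert counts == {"family": 6, "order": 3, "phylum": 3, "kingdom": 2, "other_kingdom": 1}

    def test_cascade_through_two_ranks(self):
        avail = dict(AMPLE, family=0, order=0)
        counts = allocate_counts(ShadowSpec(total=25), avail)
        assert counts == {"family": 0, "order": 0, "phylum": 20, "kingdom": 3, "other_kingdom": 2}

    def test_terminal_shortfall_reduces_total(self):
        avail = dict(AMPLE, other_kingdom=0)
        counts = allocate_counts(ShadowSpec(total=25), avail)
        assert sum(counts.values()) == 23 and counts["other_kingdom"] == 0

    def test_sum_never_exceeds_total_or_availability(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            avail = {r: int(rng.integers(0, 12)) for r in RANKS}
            if sum(avail.values()) == 0:
                continue
            counts = allocate_counts(ShadowSpec(total=20), avail)
            assert sum(counts.values()) <= min(20, sum(avail.values()))
            assert all(counts[r] <= avail[r] for r in RANKS)

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError, match="achieved 0"):
            allocate_counts(ShadowSpec(total=25), {r: 0 for r in RANKS})

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ShadowSpec(total=25, weights={r: 0.25 for r in RANKS})


QUERY_TAX = TaxonomyRecord("query", "Enterobacteriaceae", "Enterobacterales", "Proteobacteria", "Bacteria")


def _mini_proteome(sid):
    return Proteome(sid, ((f"{sid}|p1", "MKLVAA"),))


def _pool():
    pool = []
    labels = [
        ("fam", "Enterobacteriaceae", "Enterobacterales", "Proteobacteria", "Bacteria"),
        ("ord", "Yersiniaceae", "Enterobacterales", "Proteobacteria", "Bacteria"),
        ("phy", "Pseudomonadaceae", "Pseudomonadales", "Proteobacteria", "Bacteria"),
        ("kin", "Bacillaceae", "Bacillales", "Bacillota", "Bacteria"),
        ("arc", "Methanocaldococcaceae", "Methanococcales", "Methanobacteriota", "Archaea"),
    ]
    for stem, fam, order, phy, king in labels:
        for i in range(8):
            sid = f"{stem}{i}"
            pool.append((TaxonomyRecord(sid, fam, order, phy, king), _mini_proteome(sid)))
    return pool


class TestSelectShadow:
    def test_buckets_follow_most_specific_rank(self):
        for tax, _ in _pool():
            expected = {"f": "family", "o": "order", "p": "phylum", "k": "kingdom", "a": "other_kingdom"}
            assert bucket_rank(QUERY_TAX, tax) == expected[tax.species_id[0]]

    def test_canonical_allocation_respected(self):
        sel = select_shadow(QUERY_TAX, _pool(), ShadowSpec(total=15), seed=1)
        by_rank = {r: sum(s.rank_matched == r for s in sel) for r in RANKS}
        assert by_rank == {"family": 6, "order": 3, "phylum": 3, "kingdom": 2, "other_kingdom": 1}

    def test_same_seed_same_selection(self):
        a = select_shadow(QUERY_TAX, _pool(), ShadowSpec(total=15), seed=42)
        b = select_shadow(QUERY_TAX, _pool(), ShadowSpec(total=15), seed=42)
        assert [s.species_id for s in a] == [s.species_id for s in b]

    def test_zero_archaea_pool_reduces_total(self):
        pool = [(t, p) for t, p in _pool() if t.superkingdom != "Archaea"]
        sel = select_shadow(QUERY_TAX, pool, ShadowSpec(total=15), seed=0)
        assert len(sel) == 14
        assert all(s.rank_matched != "other_kingdom" for s in sel)

    def test_na_family_never_matches(self):
        tax = TaxonomyRecord("x", "NA", "Enterobacterales", "Proteobacteria", "Bacteria")
        assert bucket_rank(QUERY_TAX, tax) == "order"
        # even if the query's own family were NA, NA == NA must not match
        query_na = TaxonomyRecord("query", "NA", "Enterobacterales", "Proteobacteria", "Bacteria")
        assert bucket_rank(query_na, tax) == "order"

    def test_query_in_pool_is_error(self):
        pool = _pool() + [(QUERY_TAX, _mini_proteome("query"))]
        with pytest.raises(ValueError, match="query"):
            select_shadow(QUERY_TAX, pool, ShadowSpec(total=15), seed=0)


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("MKLVAAGG", "MKLVAAGG") == 100.0

    def test_one_mismatch_of_three(self):
        assert global_identity("MKL", "MML") == pytest.approx(66.67, abs=0.01)

    def test_random_unrelated_sequences_are_dissimilar(self):
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        vals = []
        for _ in range(10):
            a = "".join(rng.choice(aa, 50))
            b = "".join(rng.choice(aa, 50))
            vals.append(global_identity(a, b))
        assert np.median(vals) < 30

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            global_identity("", "MKL")


def _brute_force_rbh(query, subject, min_identity=30.0):
    """Exhaustive all-vs-all oracle over BLOSUM62 global identity."""
    ident = {
        (qi, sj): global_identity(qs, ss)
        for (qi, (_, qs)), (sj, (_, ss)) in itertools.product(
            enumerate(query.proteins), enumerate(subject.proteins)
        )
    }
    pairs = []
    def _best(scores_ids):
        top = max(v for v, _ in scores_ids)
        return min(i for v, i in scores_ids if v == top)

    for qi in range(len(query)):
        best_s_id = _best([(ident[(qi, sj)], subject.ids[sj]) for sj in range(len(subject))])
        best_s = subject.ids.index(best_s_id)
        best_q_id = _best([(ident[(qj, best_s)], query.ids[qj]) for qj in range(len(query))])
        best_q = query.ids.index(best_q_id)
        if best_q == qi and ident[(qi, best_s)] >= min_identity:
            pairs.append((query.ids[qi], subject.ids[best_s]))
    return sorted(pairs)


class TestRbhOrthologs:
    Q = Proteome(
        "q",
        (
            ("q1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
            ("q2", "MSERGWLLAACTVLALLGHSAPAPQAQA"),
            ("q3", "MFEQRVNSDVLTVSTVNSQDQVTQKPLRDSVKQALKNYFAQLNGQDVNDLYELVLAE"),
        ),
    )

    def test_self_rbh_pairs_everything_at_100(self):
        copy = Proteome("s", tuple((f"s_{pid}", seq) for pid, seq in self.Q.proteins))
        pairs = rbh_orthologs(self.Q, copy)
        assert len(pairs) == 3
        assert all(p.identity_pct == 100.0 for p in pairs)
        assert {(p.query_protein_id, p.subject_protein_id) for p in pairs} == {
            ("q1", "s_q1"), ("q2", "s_q2"), ("q3", "s_q3")
        }

    def test_matches_exhaustive_oracle_on_toy(self):
        rng = np.random.default_rng(5)
        aa = list("ACDEFGHIKLMNPQRSTVWY")

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(len(s), size=k, replace=False):
                s[i] = aa[rng.integers(20)]
            return "".join(s)

        # s1, s2 are diverged copies of q1, q3; s3 is unrelated noise
        subject = Proteome(
            "s",
            (
                ("s1", mutate(self.Q.proteins[0][1], 6)),
                ("s2", mutate(self.Q.proteins[2][1], 10)),
                ("s3", "".join(rng.choice(aa, 40))),
            ),
        )
        got = sorted(
            (p.query_protein_id, p.subject_protein_id)
            for p in rbh_orthologs(self.Q, subject)
        )
        assert got == _brute_force_rbh(self.Q, subject)
        assert ("q1", "s1") in got and ("q3", "s2") in got

    def test_no_pair_above_cutoff_gives_empty_list(self):
        rng = np.random.default_rng(6)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        subject = Proteome("s", tuple((f"s{i}", "".join(rng.choice(aa, 45))) for i in range(3)))
        assert rbh_orthologs(self.Q, subject, min_identity=60) == []

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        subject = Proteome(
            "s",
            tuple(
                (f"s{i}", "".join(rng.choice(aa, 30)))
                for i in range(2)
            )
            + (("s_q2", self.Q.proteins[1][1]),),
        )
        fwd = {(p.query_protein_id, p.subject_protein_id) for p in rbh_orthologs(self.Q, subject, min_identity=0)}
        rev = {(p.subject_protein_id, p.query_protein_id) for p in rbh_orthologs(subject, self.Q, min_identity=0)}
        assert fwd == rev


class TestFitVerticalModel:
    def test_two_point_arithmetic(self):
        pairs = [OrthologPair("a", "b", 80.0), OrthologPair("c", "d", 90.0)]
        vm = fit_vertical_model(pairs, query_size=10)
        assert vm.mu_identity == pytest.approx(85.0)
        assert vm.sigma_identity == pytest.approx(7.0711, abs=1e-4)
        assert vm.p0 == pytest.approx(0.2)

    def test_single_pair_hits_sigma_floor(self):
        vm = fit_vertical_model([OrthologPair("a", "b", 95.0)], query_size=10)
        assert vm.sigma_identity == 1.0

    def test_zero_pairs_is_uninformative(self):
        vm = fit_vertical_model([], query_size=10)
        assert not vm.informative and vm.p0 == 1e-4

    def test_parameter_recovery_from_simulated_identities(self):
        rng = np.random.default_rng(8)
        ids = np.clip(rng.normal(60, 8, size=1000), 0, 100)
        pairs = [OrthologPair(f"q{i}", f"s{i}", float(v)) for i, v in enumerate(ids)]
        vm = fit_vertical_model(pairs, query_size=2000)
        assert vm.mu_identity == pytest.approx(60, abs=0.5)
        assert vm.sigma_identity == pytest.approx(8, abs=0.5)
        assert vm.p0 == pytest.approx(0.5)
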
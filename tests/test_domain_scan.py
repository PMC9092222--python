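"""Detection, inclusion, overlap resolution, naming, and extraction."""

import itertools

import numpy as np
import pytest

from tirscan import domain_scan, synthetic_data
from tirscan.records import AMINO_ACIDS, DomainHit, ProteinRecord


def make_hit(env_start, env_end, bits, protein="p", model="TIR_2", ali=None, acc=0.9):
    ali_start, ali_end = ali if ali else (env_start, env_end)
    return DomainHit(
        protein_id=protein,
        model_name=model,
        full_seq_bits=bits,
        domain_bits=bits,
        hmm_start=1,
        hmm_end=10,
        ali_start=ali_start,
        ali_end=ali_end,
        env_start=env_start,
        env_end=env_end,
        accuracy=acc,
    )


def brute_force_dedup(hits):
    """Independent oracle: the lexicographically best maximal accept-set
    under the (bits desc, length desc, accuracy desc, name, start) key."""

    def ok(subset):
        for a, b in itertools.combinations(subset, 2):
            shared = min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1
            if shared > 0 and shared / min(a.env_length, b.env_length) >= 0.33:
                return False
        return True

    valid = [
        s
        for r in range(len(hits) + 1)
        for s in itertools.combinations(hits, r)
        if ok(s)
    ]
    maximal = [
        s
        for s in valid
        if not any(set(s) < set(t) for t in valid)
    ]
    return min(
        maximal,
        key=lambda s: sorted(domain_scan.precedence_key(h) for h in s),
    )


class TestSearchProfile:
    def test_empty_catalog(self, profile):
        assert domain_scan.search_profile([], profile) == []

    def test_consensus_copy_aligns_full_model(self, profile):
        catalog = [
            ProteinRecord(id=f"c{i}", sequence=profile.consensus) for i in range(3)
        ]
        hits = domain_scan.search_profile(catalog, profile)
        assert len(hits) == 3
        for h in hits:
            assert (h.hmm_start, h.hmm_end) == (1, profile.M)
            assert (h.ali_start, h.ali_end) == (1, profile.M)
            assert h.accuracy == 1.0

    def test_planted_domain_recovered_with_90pct_overlap(
        self, profile, planted_catalog
    ):
        catalog, truth = planted_catalog
        hits = {h.protein_id: h for h in domain_scan.search_profile(catalog, profile)}
        recovered = 0
        for pid, intervals in truth.planted_intervals.items():
            start, end, _, _ = intervals[0]
            h = hits.get(pid)
            if h is None:
                continue
            shared = max(0, min(end, h.env_end) - max(start, h.env_start) + 1)
            if shared >= 0.9 * (end - start + 1):
                recovered += 1
        assert recovered / len(catalog) >= 0.95

    def test_sensitivity_nonincreasing_in_divergence(self, panel, profile):
        rates = []
        for sub in (0.0, 0.3, 0.5):
            catalog, _ = synthetic_data.plant_domains(
                40, panel, sub_fraction=sub, master_seed=11
            )
            hits = domain_scan.apply_inclusion(
                domain_scan.search_profile(catalog, profile), profile
            )
            rates.append(len({h.protein_id for h in hits}) / len(catalog))
        assert rates[0] >= 0.95
        assert rates[0] >= rates[1] >= rates[2]

    def test_background_proteins_never_exceed_bit_floor(self, profile):
        rng = np.random.default_rng(1)
        catalog = [
            ProteinRecord(
                id=f"null{i}",
                sequence="".join(
                    AMINO_ACIDS[j] for j in rng.integers(0, 20, 200)
                ),
            )
            for i in range(50)
        ]
        hits = domain_scan.search_profile(catalog, profile)
        assert all(h.domain_bits <= 12 for h in hits)


class TestInclusion:
    def test_noise_cutoff_arm_keeps_high_scores(self):
        prof_stub = type("P", (), {"noise_cutoff": 25.0})()
        hi = make_hit(1, 100, bits=30.0)
        lo = make_hit(1, 100, bits=20.0)
        assert domain_scan.apply_inclusion([hi, lo], prof_stub) == [hi]

    def test_flag_arm_requires_strictly_more_than_12_bits(self):
        prof_stub = type("P", (), {"noise_cutoff": 1000.0})()
        at_floor = make_hit(1, 100, bits=12.0)
        above = make_hit(1, 100, bits=12.01)
        flags = {"p": True}
        assert domain_scan.apply_inclusion([at_floor], prof_stub, flags) == []
        assert domain_scan.apply_inclusion([above], prof_stub, flags) == [above]

    def test_unflagged_protein_fails_flag_arm(self):
        prof_stub = type("P", (), {"noise_cutoff": 1000.0})()
        h = make_hit(1, 100, bits=50.0)
        assert domain_scan.apply_inclusion([h], prof_stub, {"other": True}) == []

    def test_fallback_without_cutoff_or_flags_is_bit_floor(self):
        assert domain_scan.apply_inclusion([make_hit(1, 100, bits=13.0)]) != []
        assert domain_scan.apply_inclusion([make_hit(1, 100, bits=12.0)]) == []

    def test_empty_list(self):
        assert domain_scan.apply_inclusion([]) == []


class TestDedup:
    def test_41pct_overlap_drops_lower_bits(self):
        a = make_hit(1, 100, bits=30.0)
        b = make_hit(60, 160, bits=20.0)  # overlap 41/100 = 41%
        assert domain_scan.dedup_overlaps([a, b]) == [a]

    def test_disjoint_hits_both_kept(self):
        a = make_hit(1, 100, bits=30.0)
        b = make_hit(200, 300, bits=20.0)
        assert domain_scan.dedup_overlaps([a, b]) == [a, b]

    def test_chain_of_three_keeps_first_and_third(self):
        # hit-2 overlaps hit-1 heavily; hit-3 overlaps hit-1 < 33% but
        # hit-2 >= 33%, so the greedy accept-set is {hit-1, hit-3}
        h1 = make_hit(1, 100, bits=30.0)
        h2 = make_hit(50, 150, bits=20.0)
        h3 = make_hit(90, 190, bits=10.0)
        kept = domain_scan.dedup_overlaps([h1, h2, h3])
        assert kept == [h1, h3]
        assert set(brute_force_dedup([h1, h2, h3])) == {h1, h3}

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            hits = []
            for _k in range(n):
                s = int(rng.integers(1, 150))
                e = s + int(rng.integers(20, 120))
                bits = float(rng.choice([10.0, 20.0, 20.0, 30.0]))
                acc = float(rng.choice([0.5, 0.9]))
                hits.append(make_hit(s, e, bits=bits, acc=acc))
            kept = domain_scan.dedup_overlaps(hits)
            oracle = brute_force_dedup(hits)
            assert sorted(domain_scan.precedence_key(h) for h in kept) == sorted(
                domain_scan.precedence_key(h) for h in oracle
            )

    def test_unknown_protein_raises(self):
        with pytest.raises(ValueError, match="unknown proteins"):
            domain_scan.dedup_overlaps([make_hit(1, 50, 20.0)], known_proteins={"q"})


class TestNaming:
    def test_single_hit_name(self):
        h = make_hit(1, 100, 30.0, protein="BXY_39700", model="TIR_2")
        assert domain_scan.name_domains([h])[0].domain_id == "BXY_39700.TIR_2.1"

    def test_second_hit_increments_counter(self):
        h1 = make_hit(1, 100, 30.0, protein="BXY_39700", model="TIR_2")
        h2 = make_hit(200, 300, 25.0, protein="BXY_39700", model="TIR_2")
        named = domain_scan.name_domains([h2, h1])
        assert [h.domain_id for h in named] == [
            "BXY_39700.TIR_2.1",
            "BXY_39700.TIR_2.2",
        ]

    def test_locus_tag_prefix(self):
        h = make_hit(5, 120, 22.0, protein="Bovatus_RS22005", model="TIR_2")
        assert (
            domain_scan.name_domains([h])[0].domain_id
            == "Bovatus_RS22005.TIR_2.1"
        )


class TestExtract:
    @pytest.mark.parametrize(
        "ali_start,expected_start",
        [(10, 6), (3, 1), (1, 1)],
    )
    def test_flank_rule(self, ali_start, expected_start):
        protein = ProteinRecord(id="p", sequence="ACDEFGHIKLMNPQRSTVWY" * 10)
        hit = make_hit(
            max(1, ali_start - 2),
            ali_start + 50,
            30.0,
            ali=(ali_start, ali_start + 40),
        )
        out = domain_scan.extract_domain(hit, protein, flank=4)
        assert out == protein.sequence[expected_start - 1 : hit.env_end]

    def test_full_length_extraction_when_alignment_starts_at_one(self):
        protein = ProteinRecord(id="p", sequence="ACDEFGHIKL" * 20)
        hit = make_hit(1, 150, 30.0, ali=(1, 140))
        assert len(domain_scan.extract_domain(hit, protein)) == 150

    def test_out_of_range_raises(self):
        protein = ProteinRecord(id="p", sequence="ACDEF")
        hit = make_hit(1, 100, 30.0)
        with pytest.raises(ValueError, match="out of range"):
            domain_scan.extract_domain(hit, protein)

    def test_wrong_protein_raises(self):
        protein = ProteinRecord(id="q", sequence="ACDEF" * 40)
        with pytest.raises(ValueError, match="does not belong"):
            domain_scan.extract_domain(make_hit(1, 100, 30.0), protein)


class TestAgainstExternalHMMER:
    def test_envelopes_agree_with_hmmer(self, tmp_path, panel, profile):
        """Independent cross-check: HMMER's hmmsearch (via pyhmmer) finds
        the same domain envelopes as the in-package aligner."""
        pyhmmer = pytest.importorskip("pyhmmer")
        from tirscan import formats_io

        hmm_path = tmp_path / "toy.hmm"
        formats_io.write_profile(profile, hmm_path)
        with pyhmmer.plan7.HMMFile(str(hmm_path)) as fh:
            hmm = next(iter(fh))
        catalog, _ = synthetic_data.plant_domains(
            30, panel, sub_fraction=0.2, master_seed=9
        )
        alpha = pyhmmer.easel.Alphabet.amino()
        seqs = [
            pyhmmer.easel.TextSequence(
                name=c.id.encode(), sequence=c.sequence
            ).digitize(alpha)
            for c in catalog
        ]
        (top,) = pyhmmer.hmmer.hmmsearch([hmm], seqs)
        ours = {h.protein_id: h for h in domain_scan.search_profile(catalog, profile)}
        assert len(top) == len(catalog)
        for hit in top:
            pid = hit.name if isinstance(hit.name, str) else hit.name.decode()
            best = max(hit.domains, key=lambda d: d.score)
            o = ours[pid]
            shared = max(
                0, min(best.env_to, o.env_end) - max(best.env_from, o.env_start) + 1
            )
            assert shared / o.env_length > 0.8
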
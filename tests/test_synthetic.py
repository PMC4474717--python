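import numpy as np
import pytest

from disomcs.annotation import two_state_labels
from disomcs.features import DEFAULT_SS_ALPHABET
from disomcs.mcsbase import MCSDatabase, MCSRecord
from disomcs.mcs_profile import mcs_for_query
from disomcs.synthetic import (
    SynthConfig,
    ToyAlignParams,
    generate_chain,
    generate_corpus,
    generate_family,
    generate_ss,
    pseudo_e_value,
    toy_align,
    write_corpus,
)


class TestGenerateChain:
    def test_same_seed_same_chain(self):
        cfg = SynthConfig(seed=3)
        a = generate_chain(np.random.default_rng(3), cfg)
        b = generate_chain(np.random.default_rng(3), cfg)
        assert a == b

    def test_zero_rates_give_fully_ordered_chains(self):
        cfg = SynthConfig(terminal_disorder_prob=0.0, internal_segment_rate=0.0)
        seq, labels = generate_chain(np.random.default_rng(0), cfg)
        assert set(labels) == {"O"}

    def test_pooled_disorder_fraction_near_target(self):
        cfg = SynthConfig(seed=7)
        rng = np.random.default_rng(7)
        total = dis = 0
        for _ in range(200):
            _, labels = generate_chain(rng, cfg)
            total += len(labels)
            dis += labels.count("D")
        assert 0.03 <= dis / total <= 0.07

    def test_lengths_respect_range(self):
        cfg = SynthConfig(length_range=(50, 60))
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq, labels = generate_chain(rng, cfg)
            assert 50 <= len(seq) <= 60 and len(seq) == len(labels)

    def test_disordered_segments_have_biased_composition(self):
        cfg = SynthConfig(seed=5, terminal_disorder_prob=1.0, segment_length_mean=30)
        rng = np.random.default_rng(5)
        dis_res = ord_res = ""
        for _ in range(100):
            seq, labels = generate_chain(rng, cfg)
            dis_res += "".join(s for s, l in zip(seq, labels) if l == "D")
            ord_res += "".join(s for s, l in zip(seq, labels) if l == "O")
        frac = lambda pool, letters: sum(pool.count(a) for a in letters) / len(pool)
        assert frac(dis_res, "PESKGQ") > frac(ord_res, "PESKGQ")
        assert frac(dis_res, "WCFIYV") < frac(ord_res, "WCFIYV")


class TestGenerateFamily:
    def test_no_noise_copies_parent(self):
        cfg = SynthConfig(substitution_prob=0, indel_prob=0, label_flip_prob=0, n_homologs=2, k=2)
        recs = generate_family(np.random.default_rng(0), "q", "MKVLYMKVLY", "DDOOOOOOOO", cfg)
        assert all(r.sequence == "MKVLYMKVLY" for r in recs)
        from disomcs.annotation import add_near_disorder

        assert all(r.labels == add_near_disorder("DDOOOOOOOO", 2) for r in recs)

    def test_zero_homologs(self):
        cfg = SynthConfig(n_homologs=0)
        assert generate_family(np.random.default_rng(0), "q", "MKV", "OOO", cfg) == []

    def test_mean_identity_tracks_substitution_rate(self):
        cfg = SynthConfig(substitution_prob=0.15, indel_prob=0.0, n_homologs=40)
        seq, labels = generate_chain(np.random.default_rng(2), SynthConfig(length_range=(200, 250)))
        recs = generate_family(np.random.default_rng(2), "q", seq, labels, cfg)
        ident = np.mean(
            [sum(a == b for a, b in zip(seq, r.sequence)) / len(seq) for r in recs]
        )
        assert abs(ident - (1 - cfg.substitution_prob)) < 0.03


class TestGenerateSS:
    def test_length_and_alphabet(self):
        cfg = SynthConfig(seed=0)
        rng = np.random.default_rng(0)
        labels = "DDOOOOOOOODD"
        ss = generate_ss(rng, labels, cfg)
        assert len(ss) == len(labels)
        assert set(ss) <= set(DEFAULT_SS_ALPHABET.symbols)

    def test_noise_free_ss_correlates_with_labels(self):
        cfg = SynthConfig(ss_noise=0.0)
        rng = np.random.default_rng(1)
        ss = generate_ss(rng, "DDDDOOOOOOOO", cfg)
        assert set(ss[:4]) <= {"-", "C"}
        assert set(ss[4:]) <= {"H", "E", "T"}


class TestToyAlign:
    def test_self_alignment_is_full_length_and_gap_free(self):
        seq = "MKVLYEQAGHILKWPT"
        db = MCSDatabase([MCSRecord("s1", seq, "O" * len(seq))])
        hits = toy_align("q", seq, db)
        assert len(hits) == 1
        h = hits[0]
        assert h.aligned_query == seq and h.aligned_subject == seq
        assert (h.query_start, h.query_end) == (1, len(seq))
        assert h.e_value == pytest.approx(
            pseudo_e_value(2.0 * len(seq), len(seq), len(seq))
        )

    def test_empty_db_yields_no_hits(self):
        assert toy_align("q", "MKVLY", MCSDatabase()) == []

    def test_low_scoring_pairs_are_dropped(self):
        db = MCSDatabase([MCSRecord("s1", "WWWW", "OOOO")])
        assert toy_align("q", "MKVLY", db) == []

    def test_pseudo_e_value_monotone_in_score(self):
        evals = [pseudo_e_value(s, 100, 10000) for s in range(10, 200, 7)]
        assert all(a > b for a, b in zip(evals, evals[1:]))

    def test_gapped_alignment_coordinates_are_consistent(self):
        # subject lacks a middle run of the query, forcing a gap
        q = "MKVLYEQAGHILKWPTSSDDE"
        s = "MKVLYEQAILKWPTSSDDE"
        db = MCSDatabase([MCSRecord("s1", s, "O" * len(s))])
        (h,) = toy_align("q", q, db)
        assert h.aligned_query.replace("-", "") == q[h.query_start - 1 : h.query_end]
        assert h.aligned_subject.replace("-", "") == s[h.subject_start - 1 : h.subject_end]
        assert len(h.aligned_query) == len(h.aligned_subject)


class TestCorpus:
    def test_determinism(self, tmp_path):
        cfg = SynthConfig(n_families=3, n_homologs=4, length_range=(60, 90), seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_corpus(generate_corpus(cfg), d1)
        write_corpus(generate_corpus(cfg), d2)
        for name in ("queries.fasta", "resolved.tsv", "mcsbase.fa", "ss.fasta", "hits.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_cross_references_resolve(self, small_corpus):
        ids = {q.chain_id for q in small_corpus.queries}
        assert set(small_corpus.ss) == ids
        for h in small_corpus.hits:
            assert h.query_id in ids
            assert h.subject_id in small_corpus.db

    def test_profile_argmax_recovers_truth_labels(self, small_corpus):
        """Homology counting alone should recover >=90% of covered three-state labels."""
        from disomcs.annotation import add_near_disorder

        match = covered = 0
        by_query = {}
        for h in small_corpus.hits:
            by_query.setdefault(h.query_id, []).append(h)
        for q in small_corpus.queries:
            prof = mcs_for_query(
                q.sequence, small_corpus.db, by_query.get(q.chain_id, [])
            )
            truth3 = add_near_disorder(two_state_labels(q), small_corpus.config.k)
            states = "OND"
            for p in range(len(q.sequence)):
                if prof.coverage[p] > 0:
                    covered += 1
                    match += states[int(np.argmax(prof.values[p]))] == truth3[p]
        assert covered > 0
        assert match / covered >= 0.90
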
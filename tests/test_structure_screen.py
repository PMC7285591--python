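"""Dot-bracket parsing, the maximum-pairing folder (vs exhaustive
enumeration), aptamer-likeness screening and negative-set generation."""

import numpy as np
import pytest

from aptapred.seqio import SequenceRecord
from aptapred.structure_screen import (
    APTAMER_LIKE,
    NOT_APTAMER_LIKE,
    ScreeningThresholds,
    aptamer_likeness,
    fold_record,
    generate_negatives,
    length_stats,
    nussinov_fold,
    parse_dotbracket,
    read_structure_file,
)

from conftest import random_dna


def dna(s, name="t"):
    return SequenceRecord(name, s, "DNA")


def rna(s, name="t"):
    return SequenceRecord(name, s, "RNA")


# ------------------------------------------------------ enumeration oracle
def _enumerate_max_pairs(s, min_loop=3):
    """Exhaustive search over all nested pairings (exponential; L <= 12)."""
    s = s.replace("T", "U")
    allowed = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

    def rec(positions):
        if not positions:
            return 0
        first, rest = positions[0], positions[1:]
        best = rec(rest)  # first unpaired
        for idx, j in enumerate(rest):
            if j - first > min_loop and (s[first], s[j]) in allowed:
                inside = [p for p in rest[:idx] if first < p < j]
                outside = [p for p in rest[idx + 1 :]]
                best = max(best, 1 + rec(tuple(inside)) + rec(tuple(outside)))
        return best

    return rec(tuple(range(len(s))))


class TestParseDotBracket:
    def test_hand_traced_hairpin(self):
        rec = parse_dotbracket(rna("GGGAAACCC"), "(((...)))", -3.0)
        st = rec.stats
        assert st.pair_count == 3
        assert st.hairpin_count == 1
        assert st.unpaired_fraction == pytest.approx(3 / 9)
        assert st.longest_stem == 3
        assert st.stem_count == 1
        assert st.energy_density == pytest.approx(-3.0 / 9)

    def test_fully_unpaired(self):
        st = parse_dotbracket(rna("AAAAAAAAA"), ".........", 0.0).stats
        assert st.pair_count == 0 and st.unpaired_fraction == 1.0

    def test_bulge_and_internal_loop_classification(self):
        # outer pair, one-sided gap -> bulge; two-sided gap -> internal loop
        bulge = parse_dotbracket(rna("GGAGAAACCC"), "((.(...)))", -3.0).stats
        assert bulge.bulge_count == 1 and bulge.internal_loop_count == 0
        internal = parse_dotbracket(rna("GAGAAACACC"), "(.(...).).", -2.0).stats
        assert internal.internal_loop_count == 1 and internal.bulge_count == 0

    def test_multiloop_counted(self):
        db = "((...)(...))"
        st = parse_dotbracket(rna("GGAAACGAAACC"), db, -3.0).stats
        assert st.multiloop_count == 1 and st.hairpin_count == 2

    @pytest.mark.parametrize("db", ["(((", "())", "(.))("])
    def test_unbalanced_rejected(self, db):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_dotbracket(rna("A" * len(db)), db, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            parse_dotbracket(rna("ACGU"), "(....)", -1.0)

    def test_foreign_characters_rejected(self):
        with pytest.raises(ValueError, match="only"):
            parse_dotbracket(rna("ACGU"), "([.)", 0.0)

    def test_reserialize_identity(self, rng):
        for _ in range(20):
            rec = fold_record(random_dna(rng, int(rng.integers(10, 40))))
            again = parse_dotbracket(rec.sequence, rec.dotbracket, rec.energy)
            assert again.dotbracket == rec.dotbracket
            assert again.stats == rec.stats


class TestNussinov:
    def test_perfect_hairpin(self):
        db, pairs, energy = nussinov_fold("GGGAAACCC")
        assert pairs == 3 and db == "(((...)))" and energy == -3.0

    def test_no_complementary_pairs(self):
        assert nussinov_fold("AAAAAA")[1] == 0

    def test_min_loop_blocks_short_range_pairs(self):
        # no i,j with j - i > 3 exists in a length-4 sequence
        assert nussinov_fold("GCGC", min_loop=3)[1] == 0

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="ACGTU"):
            nussinov_fold("ACGX")

    def test_traceback_is_consistent_with_pair_count(self, rng):
        for _ in range(30):
            s = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 35))))
            db, pairs, _ = nussinov_fold(s)
            parsed = parse_dotbracket(rna(s), db, -pairs)
            assert parsed.stats.pair_count == pairs

    def test_matches_exhaustive_enumeration(self, rng):
        # exact agreement with brute-force search over all nested pairings
        for _ in range(200):
            L = int(rng.integers(1, 13))
            s = "".join(rng.choice(list("ACGU"), size=L))
            assert nussinov_fold(s)[1] == _enumerate_max_pairs(s)

    def test_dna_uses_t_as_u(self):
        db_dna, pairs_dna, _ = nussinov_fold("GGGAAACCC".replace("U", "T"))
        db_rna, pairs_rna, _ = nussinov_fold("GGGAAACCC")
        assert pairs_dna == pairs_rna


class TestAptamerLikeness:
    def test_fully_unpaired_is_never_aptamer_like(self):
        rec = parse_dotbracket(rna("A" * 40), "." * 40, 0.0)
        assert aptamer_likeness(rec) == NOT_APTAMER_LIKE

    def test_stable_hairpin_is_aptamer_like(self):
        # 16 pairs over 36 nt: energy density -0.44, unpaired 0.11
        seq = "G" * 16 + "AAAA" + "C" * 16
        db = "(" * 16 + "...." + ")" * 16
        rec = parse_dotbracket(dna(seq), db, -16.0)
        assert aptamer_likeness(rec) == APTAMER_LIKE

    def test_extreme_thresholds_classify_everything_one_way(self, rng):
        accept_all = ScreeningThresholds(
            max_energy_density=1e9,
            max_unpaired_fraction=1.0,
            min_hairpins=0,
            min_longest_stem=0,
        )
        reject_all = ScreeningThresholds(
            max_energy_density=-1e9,
            max_unpaired_fraction=0.0,
            min_hairpins=99,
            min_longest_stem=99,
        )
        for _ in range(10):
            rec = fold_record(random_dna(rng, 40))
            assert aptamer_likeness(rec, accept_all) == APTAMER_LIKE
            assert aptamer_likeness(rec, reject_all) == NOT_APTAMER_LIKE


class TestStructureFile:
    def test_rnafold_style_round_trip(self, tmp_path):
        path = tmp_path / "structures.txt"
        path.write_text(">s1\nGGGAAACCC\n(((...))) (-4.20)\n>s2\nAAAA\n.... (0.0)\n")
        records = read_structure_file(path, "RNA")
        assert [r.sequence.name for r in records] == ["s1", "s2"]
        assert records[0].energy == pytest.approx(-4.2)
        assert records[0].stats.pair_count == 3

    def test_malformed_structure_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(">s1\nGGGAAACCC\n(((...)))\n")
        with pytest.raises(ValueError, match="malformed"):
            read_structure_file(path, "RNA")


class TestLengthStats:
    def test_hand_example(self):
        seqs = [dna("A" * 40), dna("C" * 40), dna("G" * 30)]
        mode, frac, hist = length_stats(seqs, 30, 80)
        assert mode == 40 and frac == 1.0 and hist == {30: 1, 40: 2}

    def test_tie_breaks_to_smallest(self):
        seqs = [dna("A" * 50), dna("C" * 30)]
        assert length_stats(seqs)[0] == 30

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            length_stats([])


class TestGenerateNegatives:
    @pytest.fixture(scope="class")
    @staticmethod
    def positives():
        from aptapred.synthetic import synthesize_aptamers

        rng = np.random.default_rng(7)
        return synthesize_aptamers(60, rng, molecules=("DNA",))

    def test_reproducible_given_seed(self, positives):
        a, _ = generate_negatives(positives, 20, seed=5)
        b, _ = generate_negatives(positives, 20, seed=5)
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_every_negative_fails_the_screen(self, positives):
        negatives, _ = generate_negatives(positives, 25, seed=9)
        for rec in negatives:
            assert aptamer_likeness(fold_record(rec)) == NOT_APTAMER_LIKE

    def test_length_distribution_follows_positives(self, positives):
        negatives, _ = generate_negatives(positives, 60, seed=3)
        from collections import Counter

        ca = Counter(len(p) for p in positives)
        cb = Counter(len(n) for n in negatives)
        tv = 0.5 * sum(
            abs(ca[k] / len(positives) - cb[k] / len(negatives))
            for k in set(ca) | set(cb)
        )
        assert tv <= 0.1

    def test_permissive_thresholds_accept_everything(self, positives):
        accept_nothing_as_aptamer = ScreeningThresholds(
            max_energy_density=-1e9, max_unpaired_fraction=0.0,
            min_hairpins=99, min_longest_stem=99,
        )
        negatives, log = generate_negatives(
            positives, 15, thresholds=accept_nothing_as_aptamer, seed=1
        )
        assert log["rejected"] == 0 and len(negatives) == 15

    def test_aptamer_permissive_thresholds_error_out(self, positives):
        everything_is_aptamer = ScreeningThresholds(
            max_energy_density=1e9, max_unpaired_fraction=1.0,
            min_hairpins=0, min_longest_stem=0,
        )
        with pytest.raises(RuntimeError, match="acceptance rate|screen-failing"):
            generate_negatives(
                positives, 10, thresholds=everything_is_aptamer, seed=1
            )
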
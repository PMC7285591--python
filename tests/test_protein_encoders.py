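"""Protein encoders against hand counts and independent direct-summation
oracles."""

import numpy as np
import pytest

from aptapred import _resources as res
from aptapred.protein_encoders import (
    ProteinEncoderConfig,
    encode_aac,
    encode_ctdc,
    encode_gaac,
    encode_paac,
    encode_protein,
    encode_socn,
)
from aptapred.seqio import SequenceRecord

from conftest import AA, random_protein


def prot(s):
    return SequenceRecord("t", s, "protein")


# ---------------------------------------------------------------- oracles
def paac_oracle(s, lam, w):
    """Chou's type-1 formula evaluated term by term from the raw scales."""
    raw = {
        a: np.array(v)
        for a, v in zip(
            res.AA_ORDER,
            # reload the raw (unstandardized) table and standardize here,
            # independently of the package's cached standardized view
            _raw_scales(),
        )
    }
    vals = np.array([raw[a] for a in res.AA_ORDER])
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0)
    zmap = {a: z[i] for i, a in enumerate(res.AA_ORDER)}

    def theta_pair(a, b):
        return np.mean((zmap[b] - zmap[a]) ** 2)

    n = len(s)
    thetas = []
    for j in range(1, lam + 1):
        thetas.append(
            sum(theta_pair(s[i], s[i + j]) for i in range(n - j)) / (n - j)
        )
    freqs = np.array([s.count(a) for a in res.AA_ORDER]) / n
    denom = freqs.sum() + w * sum(thetas)
    return np.concatenate([freqs / denom, w * np.array(thetas) / denom])


def _raw_scales():
    import pandas as pd
    from importlib import resources as ir

    with ir.files("aptapred.data").joinpath("paac_scales.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#").set_index("aa")
    return df.loc[list(res.AA_ORDER)].to_numpy()


def socn_oracle(s, lam, matrix):
    """Direct double loop over Eq-style coupling sums."""
    mat = res.distance_matrix(matrix)
    out = []
    for d in range(1, lam + 1):
        total = 0.0
        for i in range(len(s) - d):
            total += mat.loc[s[i], s[i + d]] ** 2
        out.append(total)
    return np.array(out)


# ----------------------------------------------------------------- tests
class TestAAC:
    def test_homopolymer(self):
        fv = encode_aac(prot("AAAA"))
        assert fv["AAC_A"] == 1.0 and fv.values.sum() == pytest.approx(1.0)

    def test_hand_count(self):
        fv = encode_aac(prot("ACDC"))
        assert fv["AAC_C"] == 0.5
        assert fv["AAC_A"] == 0.25
        assert fv["AAC_D"] == 0.25

    def test_permutation_invariant(self, rng):
        s = random_protein(rng, 40).residues
        perm = "".join(rng.permutation(list(s)))
        assert np.allclose(encode_aac(prot(s)).values, encode_aac(prot(perm)).values)

    def test_rejects_nucleotide_record(self):
        with pytest.raises(ValueError, match="not a protein"):
            encode_aac(SequenceRecord("d", "ACGT", "DNA"))

    def test_rejects_foreign_letters(self):
        from aptapred.seqio import AlphabetError

        with pytest.raises(AlphabetError):
            encode_aac(prot("ACDX"))


class TestGAAC:
    def test_hand_count_per_group(self):
        # g1 aliphatic GAVLMI, g2 aromatic FYW, g3 positive KRH,
        # g4 negative DE, g5 uncharged STCPNQ
        fv = encode_gaac(prot("GAVLFD"))
        assert fv["GAAC_aliphatic"] == pytest.approx(4 / 6)
        assert fv["GAAC_aromatic"] == pytest.approx(1 / 6)
        assert fv["GAAC_positive_charge"] == 0.0
        assert fv["GAAC_negative_charge"] == pytest.approx(1 / 6)
        assert fv["GAAC_uncharged"] == 0.0

    def test_single_group_homopolymer(self):
        fv = encode_gaac(prot("KKKK"))
        assert fv["GAAC_positive_charge"] == 1.0

    def test_partition_sums_to_one(self, rng):
        for _ in range(10):
            fv = encode_gaac(random_protein(rng, int(rng.integers(5, 80))))
            assert fv.values.sum() == pytest.approx(1.0)


class TestCTDC:
    def test_hydrophobicity_hand_count(self):
        fv = encode_ctdc(prot("RRGG"))
        assert fv["CTDC_hydrophobicity_polar"] == pytest.approx(0.5)
        assert fv["CTDC_hydrophobicity_neutral"] == pytest.approx(0.5)
        assert fv["CTDC_hydrophobicity_hydrophobic"] == 0.0

    def test_single_residue_one_hot_per_property(self):
        fv = encode_ctdc(prot("W"))
        triples = np.reshape(fv.values, (7, 3))
        assert np.all(triples.sum(axis=1) == pytest.approx(1.0))
        assert np.all(np.sort(triples, axis=1)[:, :2] == 0)

    def test_each_property_triple_sums_to_one(self, rng):
        fv = encode_ctdc(random_protein(rng, 60))
        triples = np.reshape(fv.values, (7, 3))
        assert np.allclose(triples.sum(axis=1), 1.0)

    def test_dimension(self):
        assert len(encode_ctdc(prot("ACDEFGHIKL"))) == 21


class TestCTDTransitionDistribution:
    """The off-by-default Transition and Distribution descriptors."""

    def test_transition_hand_count(self):
        from aptapred.protein_encoders import encode_ctdt

        # RRGG adjacencies: RR (within polar), RG (polar->neutral), GG
        fv = encode_ctdt(prot("RRGG"))
        assert fv["CTDT_hydrophobicity_polar.neutral"] == pytest.approx(1 / 3)
        assert fv["CTDT_hydrophobicity_polar.hydrophobic"] == 0.0
        assert len(fv) == 21

    def test_distribution_hand_count(self):
        from aptapred.protein_encoders import encode_ctdd

        fv = encode_ctdd(prot("RRGG"))
        # polar residues at positions 1,2 of 4
        assert fv["CTDD_hydrophobicity_polar_000"] == pytest.approx(25.0)
        assert fv["CTDD_hydrophobicity_polar_075"] == pytest.approx(50.0)
        assert fv["CTDD_hydrophobicity_polar_100"] == pytest.approx(50.0)
        # neutral residues at positions 3,4
        assert fv["CTDD_hydrophobicity_neutral_000"] == pytest.approx(75.0)
        assert fv["CTDD_hydrophobicity_neutral_100"] == pytest.approx(100.0)
        # hydrophobic class absent
        assert fv["CTDD_hydrophobicity_hydrophobic_050"] == 0.0
        assert len(fv) == 105

    def test_not_in_default_feature_set_but_selectable(self, rng):
        fv_default = encode_protein(random_protein(rng, 100))
        assert not any(n.startswith(("CTDT", "CTDD")) for n in fv_default.names)
        cfg = ProteinEncoderConfig(encoders=("ctdc", "ctdt", "ctdd"))
        fv = encode_protein(random_protein(rng, 50), cfg)
        assert len(fv) == 21 + 21 + 105


class TestPseAAC:
    def test_homopolymer_has_zero_pseudo_components(self):
        fv = encode_paac(prot("AAAAA"), lam=2, w=0.05)
        assert fv["PseAAC_A"] == pytest.approx(1.0)
        assert fv["PseAAC_theta1"] == 0.0
        assert fv["PseAAC_theta2"] == 0.0

    def test_sums_to_one(self, rng):
        for _ in range(10):
            fv = encode_paac(random_protein(rng, 50), lam=8)
            assert fv.values.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("lam", [1, 3])
    def test_matches_direct_summation_oracle(self, rng, lam):
        for _ in range(20):
            s = random_protein(rng, int(rng.integers(lam + 2, 40))).residues
            fv = encode_paac(prot(s), lam=lam, w=0.05)
            assert np.allclose(fv.values, paac_oracle(s, lam, 0.05), atol=1e-12)

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError, match="lam"):
            encode_paac(prot("ACD"), lam=5)

    def test_changes_under_adjacent_transposition(self):
        s = "ACDEFGHIKL"
        swapped = "CADEFGHIKL"
        a = encode_paac(prot(s), lam=3).values
        b = encode_paac(prot(swapped), lam=3).values
        assert not np.allclose(a, b)


class TestSOCN:
    def test_single_term_equals_matrix_entry(self):
        fv = encode_socn(prot("AC"), lam=1)
        for mat in ("physchem", "grantham"):
            d = res.distance_matrix(mat).loc["A", "C"]
            assert fv[f"SOCN_{mat}_d1"] == pytest.approx(d**2)

    def test_homopolymer_is_all_zero(self):
        fv = encode_socn(prot("LLLLLLLL"), lam=4)
        assert np.all(fv.values == 0.0)

    def test_short_sequence_raises_with_minimum(self):
        with pytest.raises(ValueError, match="31"):
            encode_socn(prot("ACDEFGHIKL"), lam=30)

    def test_non_negative_and_matches_double_loop_oracle(self, rng):
        for _ in range(15):
            s = random_protein(rng, int(rng.integers(10, 51))).residues
            lam = int(rng.integers(1, min(8, len(s))))
            fv = encode_socn(prot(s), lam=lam)
            assert np.all(fv.values >= 0.0)
            expected = np.concatenate(
                [socn_oracle(s, lam, "physchem"), socn_oracle(s, lam, "grantham")]
            )
            assert np.allclose(fv.values, expected, atol=1e-9)

    def test_changes_under_adjacent_transposition(self):
        a = encode_socn(prot("ACDEFGHIKL"), lam=2).values
        b = encode_socn(prot("CADEFGHIKL"), lam=2).values
        assert not np.allclose(a, b)


class TestGranthamMatrix:
    def test_published_landmark_distances(self):
        # the recomputed matrix reproduces the printed table within rounding
        g = res.distance_matrix("grantham")
        assert g.loc["L", "I"] == pytest.approx(5, abs=0.5)
        assert g.loc["W", "C"] == pytest.approx(215, abs=1.0)
        assert g.loc["S", "R"] == pytest.approx(110, abs=1.0)

    def test_zero_diagonal_both_matrices(self):
        for which in ("grantham", "physchem"):
            m = res.distance_matrix(which)
            assert np.allclose(np.diag(m.to_numpy()), 0.0)


class TestConcatenation:
    def test_aac_gaac_dimension(self, rng):
        fv = encode_protein(
            random_protein(rng, 40), ProteinEncoderConfig(encoders=("aac", "gaac"))
        )
        assert len(fv) == 25

    def test_default_config_dimension(self, rng):
        fv = encode_protein(random_protein(rng, 100))
        assert len(fv) == 156  # 20 + 50 + 5 + 21 + 60

    def test_names_are_prefixed_and_unique(self, rng):
        fv = encode_protein(random_protein(rng, 100))
        assert len(set(fv.names)) == len(fv.names)
        assert all(
            n.split("_")[0] in {"AAC", "PseAAC", "GAAC", "CTDC", "SOCN"}
            for n in fv.names
        )

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ProteinEncoderConfig(encoders=())
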
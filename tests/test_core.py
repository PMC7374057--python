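"""Codon counting and usage statistics (CUF, RSCU, GC3, Nc)."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cubkit import (CodingSequence, FrameError, count_codons, cuf_profile,
                    effective_number_of_codons, gc3_of_counts, rscu_profile)

DNA = st.text(alphabet="ACGT", min_size=3, max_size=120).map(
    lambda s: s[:len(s) - len(s) % 3])


class TestGeneticCode:
    def test_degeneracy_census(self, code):
        assert len(code.sense_codons) == 61
        assert len(code.stop_codons) == 3
        assert code.degeneracy_census() == {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}

    def test_families_partition_sense_codons(self, code):
        seen = [c for aa in code.amino_acids for c in code.family(aa)]
        assert sorted(seen) == list(code.sense_codons)

    def test_single_codon_families(self, code):
        assert code.family("M") == ("ATG",)
        assert code.family("W") == ("TGG",)


class TestCountCodons:
    def test_stop_codons_excluded(self, code):
        table = count_codons([CodingSequence("g", "ATGAAATAA")], code)
        row = table.row("g")
        assert row["ATG"] == 1 and row["AAA"] == 1
        assert row.sum() == 2

    def test_ambiguous_codons_skipped_and_tallied(self, code):
        table = count_codons([CodingSequence("g", "ATGAANGGG")], code)
        row = table.row("g")
        assert row["ATG"] == 1 and row["GGG"] == 1 and row.sum() == 2
        assert table.skipped["g"] == 1

    def test_strict_frame_error_names_gene(self, code):
        with pytest.raises(FrameError, match="odd_gene"):
            count_codons([CodingSequence("odd_gene", "ATGAA")], code)

    def test_trim_mode_drops_partial_codon(self, code):
        with pytest.warns(UserWarning):
            table = count_codons([CodingSequence("g", "ATGAA")], code,
                                 frame="trim")
        assert table.row("g").sum() == 1

    def test_empty_input_gives_empty_table(self, code):
        table = count_codons([], code)
        assert table.counts.shape == (0, 61)

    def test_row_sums_match_bruteforce_scan(self, code):
        rng = np.random.default_rng(0)
        stops = set(code.stop_codons)
        seqs = [CodingSequence(f"g{i}", "".join(
            rng.choice(list("ACGT"), size=900))) for i in range(100)]
        table = count_codons(seqs, code)
        for s in seqs:
            expected = sum(1 for j in range(0, 900, 3)
                           if s.seq[j:j + 3] not in stops)
            assert table.row(s.id).sum() == expected

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=DNA, b=DNA)
    def test_concatenation_additivity(self, code, a, b):
        t_ab = count_codons([CodingSequence("x", a + b)], code)
        t_a = count_codons([CodingSequence("x", a)], code)
        t_b = count_codons([CodingSequence("x", b)], code)
        assert (t_ab.row("x") == t_a.row("x") + t_b.row("x")).all()


class TestUsageProfiles:
    def test_lysine_cuf_arithmetic(self, code):
        p = cuf_profile({"AAA": 3, "AAG": 1}, code)
        assert p.cuf["AAA"] == pytest.approx(0.75)
        assert p.cuf["AAG"] == pytest.approx(0.25)

    def test_uniform_counts_cuf_and_gc3(self, code):
        counts = {c: 1 for c in code.sense_codons}
        p = cuf_profile(counts, code)
        for aa in code.amino_acids:
            fam = code.family(aa)
            for c in fam:
                assert p.cuf[c] == pytest.approx(1.0 / len(fam))
        gc3_brute = sum(1 for c in code.sense_codons if c[2] in "GC") / 61
        assert p.gc3 == pytest.approx(gc3_brute)

    def test_absent_family_is_undefined_not_zero(self, code):
        counts = {c: 2 for c in code.sense_codons if code.aa_of(c) != "H"}
        p = cuf_profile(counts, code)
        assert math.isnan(p.cuf["CAC"]) and math.isnan(p.cuf["CAT"])
        for aa in code.amino_acids:
            if aa == "H":
                continue
            assert p.cuf[list(code.family(aa))].notna().all()

    def test_empty_counts_error(self, code):
        with pytest.raises(ValueError, match="no sense codons"):
            cuf_profile({}, code)

    def test_rscu_examples(self, code):
        p = rscu_profile({"AAA": 3, "AAG": 1}, code)
        assert p.rscu["AAA"] == pytest.approx(1.5)
        assert p.rscu["AAG"] == pytest.approx(0.5)
        uniform = rscu_profile({c: 5 for c in code.sense_codons}, code)
        degenerate = [c for c in code.sense_codons
                      if code.degeneracy_class(code.aa_of(c)) > 1]
        assert np.allclose(uniform.rscu[degenerate], 1.0)

    def test_rscu_matches_per_family_bruteforce(self, code):
        rng = np.random.default_rng(1)
        counts = pd.Series(rng.integers(0, 30, 61),
                           index=list(code.sense_codons))
        p = rscu_profile(counts, code)
        for aa in code.amino_acids:
            fam = list(code.family(aa))
            tot = counts[fam].sum()
            if tot == 0:
                continue
            for c in fam:
                assert p.rscu[c] == pytest.approx(len(fam) * counts[c] / tot)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=61, max_size=61))
    def test_normalization_invariants(self, code, raw):
        counts = pd.Series(raw, index=list(code.sense_codons))
        if counts.sum() == 0:
            return
        p = rscu_profile(counts, code)
        assert p.aa_freq.sum() == pytest.approx(1.0, abs=1e-12)
        for aa in code.amino_acids:
            fam = list(code.family(aa))
            if counts[fam].sum() == 0:
                continue
            assert p.cuf[fam].sum() == pytest.approx(1.0, abs=1e-12)
            assert p.rscu[fam].mean() == pytest.approx(1.0, abs=1e-12)

    def test_gc3_complements_at3(self, code):
        rng = np.random.default_rng(2)
        counts = pd.Series(rng.integers(1, 20, 61),
                           index=list(code.sense_codons))
        at3 = sum(v for c, v in counts.items() if c[2] in "AT") / counts.sum()
        assert gc3_of_counts(counts, code) == pytest.approx(1.0 - at3)


def _nc_oracle(counts, code):
    """Independent Nc evaluation: plug-in homozygosity per amino acid."""
    fbar = {}
    for k in (2, 3, 4, 6):
        fs = []
        for aa in code.amino_acids:
            fam = list(code.family(aa))
            if len(fam) != k:
                continue
            n = sum(counts.get(c, 0) for c in fam)
            if n < 2:
                continue
            fs.append(sum((counts.get(c, 0) / n) ** 2 for c in fam))
        if fs:
            fbar[k] = sum(fs) / len(fs)
    return 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]


class TestEffectiveNumberOfCodons:
    def test_uniform_usage_is_61(self, code):
        nc = effective_number_of_codons({c: 100 for c in code.sense_codons},
                                        code)
        assert nc == pytest.approx(61.0, abs=1e-9)

    def test_one_codon_per_aa_is_20(self, code):
        counts = {code.family(aa)[0]: 100 for aa in code.amino_acids}
        assert effective_number_of_codons(counts, code) == pytest.approx(20.0)

    def test_matches_independent_formula_on_simulated_genes(self, code):
        rng = np.random.default_rng(3)
        for _ in range(50):
            counts = {c: int(rng.integers(2, 40)) for c in code.sense_codons}
            nc = effective_number_of_codons(counts, code)
            assert nc == pytest.approx(_nc_oracle(counts, code), abs=1e-9)

    def test_scale_invariance_and_corrected_limit(self, code):
        rng = np.random.default_rng(4)
        counts = pd.Series(rng.integers(5, 50, 61),
                           index=list(code.sense_codons))
        assert effective_number_of_codons(counts, code) == pytest.approx(
            effective_number_of_codons(10 * counts, code), abs=1e-12)
        # Wright's corrected estimator approaches the plug-in value as counts grow
        gaps = [abs(effective_number_of_codons(
                        m * counts, code, small_sample_correction=True)
                    - effective_number_of_codons(m * counts, code))
                for m in (1, 10, 100)]
        assert gaps[0] > gaps[1] > gaps[2]

    def test_monotone_decrease_as_usage_concentrates(self, code):
        # interpolate from uniform usage to one codon per amino acid
        uniform = pd.Series(60.0, index=list(code.sense_codons))
        concentrated = pd.Series(0.0, index=list(code.sense_codons))
        for aa in code.amino_acids:
            fam = list(code.family(aa))
            concentrated[fam[0]] = 60.0 * len(fam)
        values = []
        for t in np.linspace(0, 1, 6):
            mix = (1 - t) * uniform + t * concentrated
            values.append(effective_number_of_codons(mix, code))
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(61.0, abs=1e-9)
        assert values[-1] == pytest.approx(20.0, abs=1e-9)

    def test_no_computable_family_warns_and_returns_nan(self, code):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            nc = effective_number_of_codons({"ATG": 5}, code)
        assert math.isnan(nc)
        assert any("undefined" in str(w.message) for w in caught)
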
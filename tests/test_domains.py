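"""HEP/LEP selection, codon back-threading, cr/vr column rules."""

import numpy as np
import pandas as pd
import pytest

from cubkit import (AbundanceTable, CodingSequence, backthread,
                    classify_columns, conservation_percent, extract_domains,
                    select_hep_lep)
from cubkit.simulate import (M0Params, balanced_tree, evolve_m0, f3x4,
                             gc3_family_profile, generate_ortholog_family)
from cubkit.modal import modal_sequence


class TestSelectHepLep:
    def test_quantile_arithmetic(self):
        abund = AbundanceTable(pd.Series({f"g{i}": float(i)
                                          for i in range(1, 101)}))
        hep, lep = select_hep_lep(abund, [f"g{i}" for i in range(1, 101)],
                                  hep_q=0.9, lep_q=0.1)
        assert set(hep) == {f"g{i}" for i in range(91, 101)}
        assert set(lep) == {f"g{i}" for i in range(1, 11)}
        assert not set(hep) & set(lep)

    def test_degenerate_distribution_errors(self):
        abund = AbundanceTable(pd.Series({f"g{i}": 5.0 for i in range(30)}))
        with pytest.raises(ValueError, match="degenerate"):
            select_hep_lep(abund, [f"g{i}" for i in range(30)])

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(50)
        values = pd.Series(np.exp(rng.normal(3, 1.2, 1000)),
                           index=[f"g{i}" for i in range(1000)])
        abund = AbundanceTable(values)
        hep, lep = select_hep_lep(abund, list(values.index), 0.9, 0.1)
        ranked = values.sort_values()
        lo, hi = values.quantile(0.1), values.quantile(0.9)
        assert set(lep) == set(ranked.index[ranked <= lo])
        assert set(hep) == set(ranked.index[ranked >= hi])

    def test_genes_without_abundance_excluded(self):
        abund = AbundanceTable(pd.Series({f"g{i}": float(i + 1)
                                          for i in range(40)}))
        with pytest.warns(UserWarning, match="lack abundance"):
            hep, lep = select_hep_lep(abund,
                                      [f"g{i}" for i in range(50)], 0.9, 0.1)
        assert all(g in abund.abundance.index for g in hep + lep)

    def test_invalid_quantiles(self):
        abund = AbundanceTable(pd.Series({f"g{i}": float(i + 1)
                                          for i in range(30)}))
        with pytest.raises(ValueError):
            select_hep_lep(abund, list(abund.abundance.index), 0.1, 0.9)


class TestBackthread:
    def test_ungapped_family_threads_in_order(self, code):
        cds = {"m1": "ATGGCTAAA", "m2": "ATGGCAAAG"}
        aln = backthread({"m1": "MAK", "m2": "MAK"}, cds, code=code)
        assert aln.codon_rows["m1"] == ["ATG", "GCT", "AAA"]
        assert aln.codon_rows["m2"] == ["ATG", "GCA", "AAG"]

    def test_gap_shifts_codons(self, code):
        aln = backthread({"m1": "MAK", "m2": "M-K"},
                         {"m1": "ATGGCTAAA", "m2": "ATGAAA"}, code=code)
        assert aln.codon_rows["m2"] == ["ATG", "---", "AAA"]

    def test_trailing_stop_tolerated(self, code):
        aln = backthread({"m1": "MK", "m2": "MK"},
                         {"m1": "ATGAAATAA", "m2": "ATGAAG"}, code=code)
        assert aln.codon_rows["m1"] == ["ATG", "AAA"]

    def test_translation_mismatch_names_member_and_position(self, code):
        with pytest.raises(ValueError, match="m2.*residue 2"):
            backthread({"m1": "MK", "m2": "MK"},
                       {"m1": "ATGAAA", "m2": "ATGGGG"}, code=code)

    def test_roundtrip_on_generated_family(self, code):
        profile = gc3_family_profile(0.55, code=code)
        aa_rows, cds = generate_ortholog_family(profile, n_members=5,
                                                n_codons=80, seed=3, code=code)
        aln = backthread(aa_rows, cds, code=code)
        for member, row in aln.aa_rows.items():
            threaded = "".join(c for c in aln.codon_rows[member] if "-" not in c)
            assert threaded == cds[member]
            assert code.translate(threaded) == row.replace("-", "")


class TestColumnRules:
    def _aln(self, code, columns):
        """Build a 4-member alignment from per-column residue strings."""
        members = [f"m{i}" for i in range(4)]
        aa_rows = {m: "".join(col[i] for col in columns)
                   for i, m in enumerate(members)}
        cds = {}
        for m, row in aa_rows.items():
            codons = [code.family(aa)[0] if aa != "-" else "" for aa in row]
            cds[m] = "".join(codons)
        return backthread({m: r for m, r in aa_rows.items()}, cds, code=code)

    def test_fully_conserved_column(self, code):
        aln = self._aln(code, ["AAAA"])
        assert classify_columns(aln) == ["conserved"]

    def test_half_proportion_is_variable(self, code):
        aln = self._aln(code, ["AAKK"])   # max proportion exactly 0.5
        assert classify_columns(aln) == ["variable"]

    def test_three_quarters_is_intermediate(self, code):
        aln = self._aln(code, ["AAAK"])
        assert classify_columns(aln) == ["intermediate"]

    def test_gapped_column_never_conserved(self, code):
        aln = self._aln(code, ["AAA-"])
        assert classify_columns(aln) == ["intermediate"]

    def test_extraction_counts(self, code):
        aln = self._aln(code, ["AAAA", "GGGG", "CCCC", "AAKK", "CCDD"])
        classify_columns(aln)
        cr = extract_domains(aln, "cr")
        vr = extract_domains(aln, "vr")
        assert len(cr.seq) == 9 and len(vr.seq) == 6

    def test_fully_conserved_family(self, code):
        aln = self._aln(code, ["AAAA", "KKKK", "LLLL"])
        classify_columns(aln)
        assert extract_domains(aln, "cr").seq == \
            "".join(aln.codon_rows[aln.reference])
        with pytest.warns(UserWarning):
            assert extract_domains(aln, "vr").seq == ""
        assert conservation_percent(aln) == pytest.approx(100.0)

    def test_no_conserved_columns_scores_zero(self, code):
        aln = self._aln(code, ["AAKK", "CCDD"])
        classify_columns(aln)
        assert conservation_percent(aln) == pytest.approx(0.0)

    def test_partition_is_exhaustive(self, code):
        profile = gc3_family_profile(0.5, code=code)
        aa_rows, cds = generate_ortholog_family(profile, n_members=6,
                                                n_codons=120, seed=8, code=code)
        aln = backthread(aa_rows, cds, code=code)
        classes = classify_columns(aln)
        assert len(classes) == 120
        assert set(classes) <= {"conserved", "variable", "intermediate"}
        cr = extract_domains(aln, "cr")
        vr = extract_domains(aln, "vr")
        assert len(cr.seq) + len(vr.seq) <= len(cds[aln.reference])


class TestEvolutionaryConservation:
    def test_omega_zero_family_cr_is_whole_reference(self, code):
        root = modal_sequence(gc3_family_profile(0.5, code=code),
                              min_codons=150, code=code)
        root = CodingSequence("root", root.seq)
        params = M0Params(kappa=2.0, omega=0.0, pi=f3x4([root], code),
                          tree=balanced_tree(4, 0.6))
        leaves = evolve_m0(root, params, seed=11, code=code)
        aa_rows = {n: code.translate(s.seq) for n, s in leaves.items()}
        cds = {n: s.seq for n, s in leaves.items()}
        aln = backthread(aa_rows, cds, code=code)
        classify_columns(aln)
        assert extract_domains(aln, "cr").seq == cds[aln.reference]
        assert conservation_percent(aln) == pytest.approx(100.0)

    def test_conservation_decreases_with_omega(self, code):
        root = modal_sequence(gc3_family_profile(0.5, code=code),
                              min_codons=400, code=code)
        root = CodingSequence("root", root.seq)
        percents = []
        for omega in (0.05, 0.3, 1.0):
            params = M0Params(kappa=2.0, omega=omega, pi=f3x4([root], code),
                              tree=balanced_tree(6, 0.5))
            leaves = evolve_m0(root, params, seed=12, code=code)
            aln = backthread({n: code.translate(s.seq)
                              for n, s in leaves.items()},
                             {n: s.seq for n, s in leaves.items()}, code=code)
            classify_columns(aln)
            percents.append(conservation_percent(aln))
        assert percents[0] > percents[1] > percents[2]

    def test_planted_fast_column_fraction(self, code):
        root = modal_sequence(gc3_family_profile(0.5, code=code),
                              min_codons=600, code=code)
        root = CodingSequence("root", root.seq)
        n = root.n_codons
        rng = np.random.default_rng(13)
        fast = rng.random(n) < 0.3
        omega = np.where(fast, 2.0, 0.01)
        params = M0Params(kappa=2.0, omega=omega, pi=f3x4([root], code),
                          tree=balanced_tree(6, 0.8))
        leaves = evolve_m0(root, params, seed=14, code=code)
        aln = backthread({k: code.translate(s.seq) for k, s in leaves.items()},
                         {k: s.seq for k, s in leaves.items()}, code=code)
        classes = np.array(classify_columns(aln))
        # conserved columns should be concentrated on the slow sites
        conserved = classes == "conserved"
        assert conserved[~fast].mean() > conserved[fast].mean() + 0.3
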
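"""Synthetic genomes, tRNA pool derivation, M0 evolution, NG86 counting."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from cubkit import (CodingSequence, M0Params, absolute_adaptiveness,
                    count_codons, cuf_profile, derive_trna_pool, evolve_m0,
                    f3x4, generate_genome, group_b_config, m0_rate_matrix,
                    modal_sequence, ng86_kaks)
from cubkit.code import revcomp
from cubkit.simulate import (PLANTED_SIJ, balanced_tree, gc3_family_profile,
                             study_profiles)

from conftest import joint_usage


class TestGenerateGenome:
    def test_same_seed_is_byte_identical(self, code):
        cfg = group_b_config(seed=8, genes_per_set=10, n_cores=2)
        g1, g2 = generate_genome(cfg, code), generate_genome(cfg, code)
        assert [s.seq for s in g1.sequences] == [s.seq for s in g2.sequences]
        assert g1.abundance.abundance.equals(g2.abundance.abundance)

    def test_unselected_sets_match_mutational_profile(self, code):
        mut, sel, u = study_profiles(code)
        from cubkit.simulate import GenomeSimConfig
        cfg = GenomeSimConfig(set_sizes={"all": 500}, mix={"all": 0.0},
                              mut_profile=mut, sel_profile=sel, seed=9)
        genome = generate_genome(cfg, code)
        table = count_codons(genome.sequences, code)
        pooled = cuf_profile(table.aggregate(), code)
        l1 = np.abs(joint_usage(pooled, code)
                    - joint_usage(mut, code)).sum()
        assert l1 <= 0.02

    def test_fully_selected_set_matches_selected_profile(self, code):
        mut, sel, _ = study_profiles(code)
        from cubkit.simulate import GenomeSimConfig
        cfg = GenomeSimConfig(set_sizes={"phe": 500}, mix={"phe": 1.0},
                              mut_profile=mut, sel_profile=sel, seed=10)
        genome = generate_genome(cfg, code)
        pooled = cuf_profile(count_codons(genome.sequences, code).aggregate(),
                             code)
        l1 = np.abs(joint_usage(pooled, code)
                    - joint_usage(sel, code)).sum()
        assert l1 <= 0.02

    def test_abundances_track_selection_intensity(self, code):
        cfg = group_b_config(seed=11, genes_per_set=60, n_cores=2)
        genome = generate_genome(cfg, code)
        med = {name: np.median([genome.abundance.abundance[g]
                                for g in genome.partition.sets[name]])
               for name in ("singletons", "PHE")}
        assert med["PHE"] > 10 * med["singletons"]


class TestDeriveTrnaPool:
    def test_uniform_profile_near_uniform_copies(self, code):
        profile = gc3_family_profile(0.5, code=code)
        pool = derive_trna_pool(profile, code=code)
        copies = np.array(list(pool.tgcn.values()))
        assert copies.max() <= 10 * max(1, copies.min())

    def test_preferred_codon_gets_dominant_decoder(self, code):
        from cubkit import profile_from_cuf
        from cubkit.simulate import BACTERIAL_AA_FREQ
        cuf = {c: 1.0 for c in code.sense_codons}
        cuf.update({"TTC": 0.9, "TTT": 0.1})
        profile = profile_from_cuf(cuf, BACTERIAL_AA_FREQ, code)
        pool = derive_trna_pool(profile, code=code)
        assert pool.copies("GAA") >= 1          # decodes TTC by WC
        assert pool.copies("GAA") > pool.copies("AAA")

    def test_pool_decodes_every_codon(self, code):
        profile = gc3_family_profile(0.62, code=code)
        pool = derive_trna_pool(profile, code=code)
        adapt = absolute_adaptiveness(pool, code=code)
        assert (adapt.w > 0).all()

    def test_recovery_loop_with_expressible_preference(self, code):
        # a preference shaped by the pairing table itself (w*-shaped) is
        # recovered, family by family, from the pool it induces
        from cubkit import profile_from_cuf
        from cubkit.simulate import BACTERIAL_AA_FREQ
        _, sel_seed, _ = study_profiles(code)
        pool0 = derive_trna_pool(sel_seed, code=code)
        w_star = absolute_adaptiveness(pool0, PLANTED_SIJ, code).w
        planted = profile_from_cuf(
            {c: float(w_star[c]) ** 2 for c in code.sense_codons},
            BACTERIAL_AA_FREQ, code)
        pool = derive_trna_pool(planted, code=code)
        w = absolute_adaptiveness(pool, PLANTED_SIJ, code).w
        argmax_hits, per_family = 0, []
        families = [aa for aa in code.amino_acids
                    if code.degeneracy_class(aa) > 1]
        for aa in families:
            fam = list(code.family(aa))
            cuf = [float(planted.cuf[c]) for c in fam]
            ws = [float(w[c]) for c in fam]
            argmax_hits += fam[int(np.argmax(cuf))] == fam[int(np.argmax(ws))]
            per_family.append(spearmanr(cuf, ws).statistic)
        assert argmax_hits >= len(families) - 2
        assert np.mean(per_family) >= 0.8

    def test_u_biased_preference_escapes_the_index(self, code):
        # a U bias in 4-fold boxes cannot be expressed by the pairing table
        # (no A34 decoder, U:U excluded), so the preferred U-ending codon
        # never carries its family's top adaptiveness
        _, sel, _ = study_profiles(code)
        pool = derive_trna_pool(sel, code=code)
        w = absolute_adaptiveness(pool, PLANTED_SIJ, code).w
        from cubkit import U_BIAS_CODONS
        for codon in U_BIAS_CODONS:
            fam = list(code.family(code.aa_of(codon)))
            assert float(w[codon]) < max(float(w[c]) for c in fam)


class TestM0Model:
    def test_generator_rows_sum_to_zero(self, code):
        root = modal_sequence(gc3_family_profile(0.5, code=code),
                              min_codons=200, code=code)
        params = M0Params(kappa=2.0, omega=0.5, pi=f3x4([root], code),
                          tree="(a:0.1,b:0.1);")
        q = m0_rate_matrix(params, code)
        assert np.abs(q.to_numpy().sum(axis=1)).max() < 1e-12

    def test_omega_zero_keeps_proteins_identical(self, code):
        root = CodingSequence(
            "r", modal_sequence(gc3_family_profile(0.5, code=code),
                                min_codons=200, code=code).seq)
        params = M0Params(kappa=2.0, omega=0.0, pi=f3x4([root], code),
                          tree=balanced_tree(4, 1.0))
        leaves = evolve_m0(root, params, seed=12, code=code)
        root_protein = code.translate(root.seq)
        assert all(code.translate(s.seq) == root_protein
                   for s in leaves.values())
        # but synonymous changes did happen
        assert any(s.seq != root.seq for s in leaves.values())

    def test_long_branch_reaches_stationarity(self, code):
        base = "".join(code.sense_codons)
        root = CodingSequence("r", base * 82)       # ~5000 codons
        pi = f3x4([root], code)
        params = M0Params(kappa=2.0, omega=1.0, pi=pi, tree="(a:20);")
        leaves = evolve_m0(root, params, seed=13, code=code)
        obs = count_codons([leaves["a"]], code).row("a").reindex(pi.index)
        _, p = chisquare(obs, pi * obs.sum())
        assert p > 0.01

    def test_root_with_stop_rejected(self, code):
        params = M0Params(kappa=2.0, omega=1.0,
                          pi=f3x4(["ATGAAACCC"], code), tree="(a:0.1);")
        with pytest.raises(ValueError, match="stop"):
            evolve_m0(CodingSequence("r", "ATGTAAAAA"), params, 1, code)

    def test_f3x4_excludes_stop_mass(self, code):
        pi = f3x4(["ATGTTTAAAGGG"], code)
        assert pi.sum() == pytest.approx(1.0)
        assert set(pi.index) == set(code.sense_codons)


class TestNg86:
    def test_identical_sequences_zero(self, code):
        r = ng86_kaks("ATGGCTAAA" * 30, "ATGGCTAAA" * 30, code)
        assert r.ka == pytest.approx(0.0) and r.ks == pytest.approx(0.0)

    def test_single_synonymous_change(self, code):
        s1 = "AAA" + "ATGGCT" * 50
        s2 = "AAG" + "ATGGCT" * 50
        r = ng86_kaks(s1, s2, code)
        assert r.ka == pytest.approx(0.0)
        assert r.ks > 0

    def test_single_nonsynonymous_change(self, code):
        s1 = "AAA" + "ATGGCT" * 50
        s2 = "GAA" + "ATGGCT" * 50
        r = ng86_kaks(s1, s2, code)
        assert r.ks == pytest.approx(0.0)
        assert r.ka > 0

    def test_matches_biopython_ng86(self, code):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.Align import Alignment, analysis
        base = "".join(code.sense_codons)
        root = CodingSequence("r", base * 5)
        params = M0Params(kappa=2.0, omega=0.6, pi=f3x4([root], code),
                          tree="(a:0.1,b:0.1);")
        leaves = evolve_m0(root, params, seed=3, code=code)
        s1, s2 = leaves["a"].seq, leaves["b"].seq
        dn, ds = analysis.calculate_dn_ds(Alignment([s1, s2]), method="NG86")
        r = ng86_kaks(s1, s2, code)
        assert r.ka == pytest.approx(dn, abs=1e-9)
        assert r.ks == pytest.approx(ds, abs=1e-9)

    def test_measured_ratio_monotone_in_omega(self, code):
        base = "".join(code.sense_codons)
        root = CodingSequence("r", base * 25)       # ~1500 codons
        pi = f3x4([root], code)
        ratios = []
        for omega in (0.1, 0.5, 1.0):
            params = M0Params(kappa=2.0, omega=omega, pi=pi,
                              tree="(a:0.15,b:0.15);")
            leaves = evolve_m0(root, params, seed=14, code=code)
            ratios.append(ng86_kaks(leaves["a"], leaves["b"], code).ratio)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_length_mismatch_rejected(self, code):
        with pytest.raises(ValueError, match="length"):
            ng86_kaks("ATGGCT", "ATGGCTAAA", code)
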
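"""Composition analyses: profiles, residue-set sums, z/t tests, OGT
correlation, normalization, GC3 — each checked against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from thermopath.core_io import AMINO_ACIDS, IVYWREL, DataError, OrthologAlignment, ResidueSet
from thermopath import composition as comp


def make_alignment(seqs: dict[str, str]) -> OrthologAlignment:
    return OrthologAlignment("g", seqs)


class TestGapFreeColumns:
    def test_single_gap_drops_column(self):
        aln = make_alignment({"a": "AC-DE", "b": "ACDDE", "c": "ACDDE", "d": "ACDDE"})
        assert comp.gap_free_columns(aln) == [0, 1, 3, 4]

    def test_gapless_keeps_all(self):
        aln = make_alignment({"a": "ACDE", "b": "ACDE"})
        assert comp.gap_free_columns(aln) == [0, 1, 2, 3]

    def test_every_column_gapped_empty(self):
        aln = make_alignment({"a": "A--", "b": "-C-", "c": "--X"})
        assert comp.gap_free_columns(aln) == []


class TestFrequencies:
    def test_single_ivywrel_sequence(self):
        aln = make_alignment({"a": "IVYWREL", "b": "IVYWREL"})
        prof = comp.aa_frequencies([aln], ["a"])["a"]
        assert prof.n_positions == 7
        for residue in "IVYWREL":
            assert prof.frequency(residue) == pytest.approx(1 / 7)
        assert prof.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_species_identical_profiles(self):
        aln = make_alignment({"a": "MNPQRSTV", "b": "MNPQRSTV", "c": "AAAAAAAA"})
        profs = comp.aa_frequencies([aln], ["a", "b"])
        assert np.array_equal(profs["a"].counts, profs["b"].counts)

    def test_missing_entity_rejected(self):
        aln = make_alignment({"a": "MNPQ", "b": "MNPQ"})
        with pytest.raises(DataError, match="'z'"):
            comp.aa_frequencies([aln], ["z"])

    def test_ancestral_skips_ambiguous(self):
        aln = make_alignment({"a": "MNPQ", "b": "MNPQ"})
        profs = comp.aa_frequencies([aln], ["anc"], ancestral=[{"anc": "MXPQ"}])
        assert profs["anc"].n_positions == 3

    def test_group_comparison_with_ancestral_entities(self):
        """Thermophiles plus their reconstructed ancestors can be compared
        against mesophiles plus theirs; ancestral profiles count only
        unambiguous columns."""
        from thermopath.parsimony import ancestral_sequences
        from thermopath.simulate import SimulationConfig, simulate_alignments, simulate_tree

        tree = simulate_tree(3, 3, 0.1, seed=21)
        cfg = SimulationConfig(tree=tree, n_proteins=4, n_columns=100, seed=21)
        alignments, _ = simulate_alignments(cfg)
        ancestral = [ancestral_sequences(a, tree) for a in alignments]
        thermo = [s for s, i in tree.species_meta.items() if i.phenotype == "thermophile"]
        meso = [s for s, i in tree.species_meta.items() if i.phenotype == "mesophile"]
        nodes = tree.internal_names()
        profiles = comp.aa_frequencies(alignments, thermo + meso + nodes, ancestral)
        for name in nodes:
            assert 0 < profiles[name].n_positions <= 400
        tests = comp.t_test_groups(
            [profiles[e] for e in thermo + nodes[:2]],
            [profiles[e] for e in meso + nodes[2:4]],
        )
        assert len(tests) == 20
        assert all(0 <= t.p_value <= 1 for t in tests)

    def test_converges_to_stationary(self):
        """Simulated profiles approach the configured (uniform) stationary
        frequencies as positions grow."""
        from thermopath.simulate import SimulationConfig, simulate_alignments, simulate_tree

        tree = simulate_tree(2, 2, 0.05, seed=20)
        cfg = SimulationConfig(tree=tree, n_proteins=1, n_columns=50000, seed=20)
        alignments, _ = simulate_alignments(cfg)
        prof = comp.aa_frequencies(alignments, [tree.leaf_names()[0]])
        freq = prof[tree.leaf_names()[0]].frequencies
        se = np.sqrt(0.05 * 0.95 / 50000)
        assert np.all(np.abs(freq - 0.05) < 3.5 * se)


class TestResidueSetSum:
    def test_full_set_is_one(self):
        aln = make_alignment({"a": "IVYWREL", "b": "IVYWREL"})
        prof = comp.aa_frequencies([aln], ["a"])["a"]
        assert comp.residue_set_sum(prof, IVYWREL) == pytest.approx(1.0)

    def test_disjoint_set_is_zero(self):
        aln = make_alignment({"a": "IVYWREL", "b": "IVYWREL"})
        prof = comp.aa_frequencies([aln], ["a"])["a"]
        assert comp.residue_set_sum(prof, ResidueSet(frozenset("MNPQ"))) == 0.0

    def test_complement_sums_to_one(self):
        aln = make_alignment({"a": "ACDEFGHIKLMNPQRSTVWY", "b": "ACDEFGHIKLMNPQRSTVWY"})
        prof = comp.aa_frequencies([aln], ["a"])["a"]
        assert comp.residue_set_sum(prof, IVYWREL) + \
            comp.residue_set_sum(prof, IVYWREL.complement()) == pytest.approx(1.0)


def oracle_two_proportion_z(x1, n1, x2, n2):
    p = (x1 + x2) / (n1 + n2)
    z = (x1 / n1 - x2 / n2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    return z, 2 * stats.norm.sf(abs(z))


class TestZTest:
    def make_profiles(self, focal_counts, bg_counts):
        return (
            comp.FrequencyProfile("f", focal_counts),
            comp.FrequencyProfile("b", bg_counts),
        )

    def test_equal_proportions_give_zero(self):
        counts = np.full(20, 50)
        focal, bg = self.make_profiles(counts, counts * 3)
        for t in comp.z_test_species_vs_group(focal, bg):
            assert t.statistic == pytest.approx(0.0)
            assert t.p_value == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(30)
        for _ in range(200):
            f = rng.integers(0, 200, size=20) + 1
            b = rng.integers(0, 500, size=20) + 1
            focal, bg = self.make_profiles(f, b)
            tests = comp.z_test_species_vs_group(focal, bg)
            n1, n2 = f.sum(), b.sum()
            for i, t in enumerate(tests):
                z, p = oracle_two_proportion_z(f[i], n1, b[i], n2)
                assert t.statistic == pytest.approx(z, abs=1e-10)
                assert t.p_value == pytest.approx(p, abs=1e-10)

    def test_antisymmetric_under_swap(self):
        f = np.arange(1, 21) * 3
        b = np.arange(20, 0, -1) * 5
        focal, bg = self.make_profiles(f, b)
        forward = comp.z_test_species_vs_group(focal, bg)
        backward = comp.z_test_species_vs_group(bg, focal)
        for a, c in zip(forward, backward):
            assert a.statistic == pytest.approx(-c.statistic)
            assert a.p_value == pytest.approx(c.p_value)

    def test_absent_residue_skipped(self):
        f = np.full(20, 10)
        f[0] = 0
        b = np.full(20, 10)
        b[0] = 0
        focal, bg = self.make_profiles(f, b)
        assert comp.z_test_species_vs_group(focal, bg)[0].skipped

    def test_residue_set_row_present(self):
        f = np.full(20, 10)
        focal, bg = self.make_profiles(f, f * 2)
        tests = comp.z_test_species_vs_group(focal, bg, residue_sets=[IVYWREL])
        assert tests[-1].residue == "IVYWREL"


class TestTTest:
    def profile(self, freq, n=1000):
        return comp.FrequencyProfile("x", np.round(np.asarray(freq) * n).astype(int))

    def test_identical_groups_null(self):
        a = [self.profile(np.full(20, 0.05)) for _ in range(3)]
        for t in comp.t_test_groups(a, a):
            assert t.statistic == pytest.approx(0.0)
            assert t.p_value == pytest.approx(1.0)

    def test_disjoint_constant_groups_flagged(self):
        a = [self.profile(np.full(20, 0.05)) for _ in range(2)]
        shifted = np.full(20, 0.05)
        shifted[0] = 0.08
        shifted[1:] -= 0.03 / 19
        b = [comp.FrequencyProfile("y", np.round(shifted * 1900).astype(int))
             for _ in range(2)]
        tests = comp.t_test_groups(a, b)
        assert tests[0].p_value == 0.0
        assert tests[0].note

    def test_matches_welch_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            a = [comp.FrequencyProfile("a", rng.integers(1, 100, 20)) for _ in range(4)]
            b = [comp.FrequencyProfile("b", rng.integers(1, 100, 20)) for _ in range(5)]
            tests = comp.t_test_groups(a, b)
            fa = np.array([p.frequencies for p in a])
            fb = np.array([p.frequencies for p in b])
            for i, t in enumerate(tests):
                ref_t, ref_p = stats.ttest_ind(fa[:, i], fb[:, i], equal_var=False)
                assert t.statistic == pytest.approx(ref_t, abs=1e-10)
                assert t.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_small_group_rejected(self):
        a = [self.profile(np.full(20, 0.05))]
        with pytest.raises(DataError):
            comp.t_test_groups(a, a * 3)


class TestOgtCorrelation:
    def test_linear_relation_gives_r_one(self):
        ogt = {f"s{i}": 20.0 + 5 * i for i in range(5)}
        profiles = {}
        for i in range(5):
            counts = np.full(20, 100)
            counts[0] = 100 + 10 * i  # alanine gains with OGT...
            counts[1] = 100 - 10 * i  # ...at cysteine's expense: total fixed
            profiles[f"s{i}"] = comp.FrequencyProfile(f"s{i}", counts)
        tests = comp.ogt_correlation(profiles, ogt)
        assert tests[0].statistic == pytest.approx(1.0, abs=1e-6)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(32)
        species = [f"s{i}" for i in range(8)]
        ogt = {s: float(rng.uniform(20, 60)) for s in species}
        profiles = {
            s: comp.FrequencyProfile(s, rng.integers(1, 100, 20)) for s in species
        }
        tests = comp.ogt_correlation(profiles, ogt)
        temps = np.array([ogt[s] for s in species])
        for i, t in enumerate(tests):
            values = np.array([profiles[s].frequencies[i] for s in species])
            r, p = stats.pearsonr(values, temps)
            assert t.statistic == pytest.approx(r, abs=1e-10)
            assert t.p_value == pytest.approx(p, abs=1e-10)

    def test_permuted_ogt_mean_r_near_zero(self):
        rng = np.random.default_rng(33)
        species = [f"s{i}" for i in range(10)]
        profiles = {
            s: comp.FrequencyProfile(s, rng.integers(50, 150, 20)) for s in species
        }
        temps = np.linspace(20, 60, 10)
        rs = []
        for _ in range(200):
            perm = rng.permutation(temps)
            ogt = dict(zip(species, perm))
            tests = comp.ogt_correlation(profiles, ogt)
            rs.append(np.nanmean([t.statistic for t in tests]))
        assert abs(np.mean(rs)) < 0.05

    def test_constant_ogt_flagged(self):
        species = [f"s{i}" for i in range(4)]
        profiles = {s: comp.FrequencyProfile(s, np.full(20, 10)) for s in species}
        tests = comp.ogt_correlation(profiles, dict.fromkeys(species, 37.0))
        assert all(t.skipped for t in tests)

    def test_spearman_option(self):
        species = [f"s{i}" for i in range(5)]
        rng = np.random.default_rng(34)
        profiles = {s: comp.FrequencyProfile(s, rng.integers(1, 50, 20)) for s in species}
        ogt = {s: float(20 + 10 * i) for i, s in enumerate(species)}
        tests = comp.ogt_correlation(profiles, ogt, method="spearman")
        assert all(-1 <= t.statistic <= 1 for t in tests if not t.skipped)


class TestNormalizedProfiles:
    def test_two_entities_give_plus_minus_one(self):
        a = comp.FrequencyProfile("a", np.arange(1, 21))
        b = comp.FrequencyProfile("b", np.arange(21, 41))
        matrix, flagged = comp.normalized_profile_matrix([a, b])
        assert np.allclose(np.abs(matrix.to_numpy()), 1.0)

    def test_column_means_zero_sd_one(self):
        rng = np.random.default_rng(35)
        profs = [comp.FrequencyProfile(f"e{i}", rng.integers(1, 100, 20)) for i in range(6)]
        matrix, flagged = comp.normalized_profile_matrix(profs)
        values = matrix.to_numpy()
        assert np.allclose(values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(values.std(axis=0), 1.0, atol=1e-12)
        assert flagged == []

    def test_zero_variance_residue_flagged_zero(self):
        profs = [comp.FrequencyProfile(f"e{i}", np.full(20, 10)) for i in range(3)]
        matrix, flagged = comp.normalized_profile_matrix(profs)
        assert flagged == list(AMINO_ACIDS)
        assert np.all(matrix.to_numpy() == 0.0)


class TestGC3:
    def test_lysine_half_gc(self):
        # AAA and AAG both encode K; one of the two third positions is G
        table = comp.gc3_by_residue({"sp": [("AAAAAG", "KK")]})
        assert table.loc["sp", "K"] == pytest.approx(0.5)
        assert table.loc["sp", "overall"] == pytest.approx(0.5)

    def test_all_gcg_is_one(self):
        table = comp.gc3_by_residue({"sp": [("GCGGCGGCG", "AAA")]})
        assert table.loc["sp", "A"] == 1.0
        assert table.loc["sp", "overall"] == 1.0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(36)
        from Bio.Seq import Seq

        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        coding = [c for c in codons if str(Seq(c).translate()) not in "*"]
        cds = "".join(rng.choice(coding, size=300))
        protein = str(Seq(cds).translate())
        table = comp.gc3_by_residue({"sp": [(cds, protein)]})
        expected_overall = sum(cds[i + 2] in "GC" for i in range(0, len(cds), 3)) / 300
        assert table.loc["sp", "overall"] == pytest.approx(expected_overall)
        # per-residue: direct recount
        for aa in set(protein):
            thirds = [cds[3 * i + 2] for i, p in enumerate(protein) if p == aa]
            assert table.loc["sp", aa] == pytest.approx(
                sum(t in "GC" for t in thirds) / len(thirds)
            )

    def test_internal_stop_skipped(self):
        table = comp.gc3_by_residue({"sp": [("AAATAAAAA", "K*K"), ("AAAAAG", "KK")]})
        assert table.loc["sp", "K"] == pytest.approx(0.5)

    def test_frame_error_rejected(self):
        with pytest.raises(DataError):
            comp.gc3_by_residue({"sp": [("AAAA", "K")]})
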
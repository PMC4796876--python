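"""Statistical potentials: counting, PMF formulas, correction, smoothing."""

import numpy as np
import pytest

import hotmusic as hm
from hotmusic.potentials import (
    ELEMENT_SPECS,
    STANDARD_FORMS,
    TDEP_ORDER,
    FrequencyTable,
    count_frequencies,
    derive_standard_potentials,
    derive_t_dependent_potentials,
    energy_table,
    max_abs_energy,
    pmf_higher,
    pmf_pair,
    smooth_distance_axis,
    sparse_correct,
)
from hotmusic.structures import DescriptorConfig

from _oracle import observations, pmf_energy
from conftest import toy_structure


class TestCounting:
    def test_residue_spec_conserves_residue_count(self, small_corpus, synth_config):
        ft = count_frequencies(small_corpus, "sa", synth_config)
        n_residues = sum(sd.n_res for sd in small_corpus)
        assert ft.total == n_residues

    def test_pair_spec_counts_two_per_pair(self, synth_config):
        st = toy_structure("ACDE", centroid_spacing=5.0)
        sd = hm.structure_arrays(st, synth_config)
        assert len(sd.pairs) == 3
        ft = count_frequencies([sd], "sd", synth_config)
        assert ft.total == 6  # each of 3 pairs contributes both directions
        # hand count: pairs (A,C), (C,D), (D,E), all at bin 10
        for aa in "ACDE":
            expected = 2 if aa in "CD" else 1
            assert ft.counts[hm.AMINO_ACIDS.index(aa), 10] == expected

    def test_counts_are_additive_over_structures(self, small_corpus, synth_config):
        one = count_frequencies(small_corpus[:1], "sds", synth_config)
        two = count_frequencies(small_corpus[:1] * 2, "sds", synth_config)
        assert np.array_equal(two.counts, 2 * one.counts)

    def test_undefined_torsions_are_skipped(self, small_corpus, synth_config):
        sd = small_corpus[0]
        ft = count_frequencies([sd], "st", synth_config)
        assert ft.total == (sd.tor_idx >= 0).sum()

    def test_empty_structure_list_raises(self, synth_config):
        with pytest.raises(ValueError, match="empty"):
            count_frequencies([], "sa", synth_config)

    def test_marginal_consistency(self, small_corpus, synth_config):
        for form in ("sa", "sd", "sds", "stt"):
            ft = count_frequencies(small_corpus, form, synth_config)
            ft.check_marginal_consistency()
            for axes in ([0], [1], [0, 1]):
                assert ft.marginal(axes).sum() == pytest.approx(ft.total)


class TestPmfFormulas:
    def test_factorised_counts_give_zero_energy(self):
        m0 = np.array([30.0, 70.0])
        m1 = np.array([40.0, 60.0])
        counts = np.outer(m0, m1) / 100.0
        ft = FrequencyTable(ELEMENT_SPECS["sa"], counts)
        for i in range(2):
            for j in range(2):
                assert pmf_pair(ft, i, j) == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_log_ratio(self):
        # F(c,s) = 0.04, F(c) = 0.1, F(s) = 0.2  ->  -ln 2
        counts = np.array([[4.0, 6.0], [16.0, 74.0]])
        ft = FrequencyTable(ELEMENT_SPECS["sa"], counts)
        assert pmf_pair(ft, 0, 0) == pytest.approx(-np.log(2.0))

    def test_zero_count_cell_with_correction_is_finite_and_damped(self):
        counts = np.array([[0.0, 10.0], [10.0, 80.0]])
        ft = FrequencyTable(ELEMENT_SPECS["sa"], counts)
        e10 = pmf_pair(ft, 0, 0, n0=10.0)
        e100 = pmf_pair(ft, 0, 0, n0=100.0)
        assert np.isfinite(e10) and e10 > 0  # expected but never seen
        assert abs(e100) < abs(e10)          # pulled toward 0 as n0 grows

    def test_higher_order_factorised_counts_give_zero(self):
        p = np.einsum("i,j,k->ijk", [0.3, 0.7], [0.4, 0.6], [0.2, 0.8]) * 1000
        ft = FrequencyTable(ELEMENT_SPECS["sds"], p)
        for cell in np.ndindex(2, 2, 2):
            assert pmf_higher(ft, *cell) == pytest.approx(0.0, abs=1e-12)

    def test_conditional_independence_reduces_to_pair_term(self):
        """If s and s' interact only through c, the three-body energy equals
        minus the direct (s, s') pairwise energy: the correction term removes
        the association already explained by the two (s, c) channels."""
        rng = np.random.default_rng(3)
        pc = np.array([0.4, 0.6])
        ps_c = rng.dirichlet([2, 2, 2], size=2)    # P(s | c)
        pt_c = rng.dirichlet([2, 2], size=2)       # P(s' | c)
        joint = np.einsum("c,cs,ct->sct", pc, ps_c, pt_c) * 1e6
        ft3 = FrequencyTable(ELEMENT_SPECS["sds"], joint)
        pss = joint.sum(axis=1)
        ft2 = FrequencyTable(ELEMENT_SPECS["sa"], pss)
        for s in range(3):
            for t in range(2):
                w3 = pmf_higher(ft3, s, 0, t)
                assert w3 == pytest.approx(-pmf_pair(ft2, s, t), abs=1e-10)

    def test_oracle_equivalence_on_fixture_corpus(self, small_corpus,
                                                  small_structures, synth_config):
        """Every potential form must reproduce an independent brute-force
        -ln(frequency ratio) computed from raw tuple dictionaries."""
        idx = {lab: k for k, lab in enumerate(synth_config.torsion_labels)}
        aa_idx = {aa: k for k, aa in enumerate(hm.AMINO_ACIDS)}
        for form in STANDARD_FORMS:
            obs = observations(small_structures, form, synth_config)
            ft = count_frequencies(small_corpus, form, synth_config)
            assert ft.total == len(obs)
            E = energy_table(ft, n0=0.0)
            seen = sorted(set(obs))
            for cell in seen[:: max(1, len(seen) // 50)]:
                key = []
                for e, v in zip(ELEMENT_SPECS[form].elements, cell):
                    key.append(aa_idx[v] if e.kind == "aa" else v)
                assert E[tuple(key)] == pytest.approx(
                    pmf_energy(obs, cell), abs=1e-10
                ), form


class TestSparseCorrection:
    @pytest.mark.parametrize(
        "ratio,n_eff,n0,expected",
        [(5.0, 0.0, 10.0, 1.0), (2.0, 10.0, 10.0, 1.5), (3.0, 1e12, 10.0, 3.0)],
    )
    def test_shrinkage_arithmetic(self, ratio, n_eff, n0, expected):
        assert sparse_correct(ratio, n_eff, n0) == pytest.approx(expected, rel=1e-9)


class TestSmoothing:
    def test_constant_table_unchanged(self):
        t = np.full((4, 25), 1.7)
        assert np.allclose(smooth_distance_axis(t, axis=1), t)

    def test_spike_spreads_with_triangular_profile(self):
        t = np.zeros(25)
        t[10] = 9.0
        s = smooth_distance_axis(t, axis=0, half_width=2)
        assert np.allclose(s[8:13], np.array([1, 2, 3, 2, 1.0]))
        assert s.sum() == pytest.approx(9.0)

    def test_zero_half_width_is_identity(self):
        t = np.random.default_rng(0).normal(size=(3, 25))
        assert np.array_equal(smooth_distance_axis(t, axis=1, half_width=0), t)


class TestDerivedSets:
    def test_standard_set_has_the_nine_table_ids(self, standard_potentials):
        assert standard_potentials.ids == STANDARD_FORMS
        assert all(
            np.isfinite(p.energy).all()
            for comps in standard_potentials.potentials.values()
            for p in comps
        )

    def test_rederivation_is_bit_identical(self, small_corpus, synth_config,
                                           standard_potentials):
        again = derive_standard_potentials(small_corpus, synth_config)
        for form in STANDARD_FORMS:
            assert np.array_equal(
                again.potentials[form][0].energy,
                standard_potentials.potentials[form][0].energy,
            )

    def test_tdep_split_and_grouping(self, small_corpus, synth_config):
        tms = [sd.structure.tm for sd in small_corpus]
        thr = float(np.median(tms))
        meso, thermo = derive_t_dependent_potentials(
            small_corpus, tm_threshold=thr, config=synth_config
        )
        assert meso.ids == TDEP_ORDER and thermo.ids == TDEP_ORDER
        assert meso.provenance["n_structures"] == sum(t < thr for t in tms)
        assert thermo.provenance["n_structures"] == sum(t >= thr for t in tms)
        # grouped potentials keep their component tables
        assert tuple(p.form for p in meso.potentials["acc"]) == ("sa", "saa")
        assert tuple(p.form for p in meso.potentials["tor"]) == ("st", "stt", "sst")

    def test_empty_subset_raises_with_subset_name(self, small_corpus, synth_config):
        with pytest.raises(ValueError, match="thermostable"):
            derive_t_dependent_potentials(
                small_corpus, tm_threshold=1000.0, config=synth_config
            )
        with pytest.raises(ValueError, match="mesostable"):
            derive_t_dependent_potentials(
                small_corpus, tm_threshold=-1000.0, config=synth_config
            )

    def test_identical_subsets_give_identical_sets(self, small_corpus, synth_config):
        meso1, _ = derive_t_dependent_potentials(small_corpus, 65.0,
                                                 config=synth_config)
        meso2, _ = derive_t_dependent_potentials(small_corpus, 65.0,
                                                 config=synth_config)
        for gid in TDEP_ORDER:
            for p1, p2 in zip(meso1.potentials[gid], meso2.potentials[gid]):
                assert np.array_equal(p1.energy, p2.energy)

    def test_json_round_trip(self, standard_potentials, tmp_path):
        path = tmp_path / "pots.json"
        standard_potentials.to_json(path)
        back = hm.PotentialSet.from_json(path)
        assert back.ids == standard_potentials.ids
        assert back.config_hash == standard_potentials.config_hash
        for form in STANDARD_FORMS:
            assert np.array_equal(
                back.potentials[form][0].energy,
                standard_potentials.potentials[form][0].energy,
            )


class TestIndependenceLimit:
    def test_uncoupled_corpora_shrink_with_size(self):
        """With sequence drawn independently of structure, energies are pure
        sampling noise and the largest |energy| must fall as the corpus
        grows.  Checked in a coarse-binned regime where every cell is well
        populated relative to the pseudocount."""
        coarse = DescriptorConfig(
            d_bin_width=2.5,
            acc_bin_edges=(0.0, 50.0, 100.0),
            torsion_domains=(("helical", -160.0, -20.0, -120.0, 50.0),),
        )
        coarse = coarse.with_max_asa(
            {aa: 106.4 for aa in hm.AMINO_ACIDS}
        )
        maxima = []
        for n in (40, 160):
            spec = hm.SyntheticSpec(
                n_structures=n, chain_length_range=(50, 70), coupling=0.0, seed=19
            )
            sds = [hm.structure_arrays(s, coarse)
                   for s in hm.generate_structures(spec)]
            pots = derive_standard_potentials(sds, coarse)
            maxima.append(max_abs_energy(pots))
        assert maxima[1] < maxima[0]
        assert maxima[1] < 0.4  # residual sampling noise at the larger size
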
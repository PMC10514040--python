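"""Synthetic generator: von Mises coupling model, determinism, cohort layout."""

import numpy as np
import pytest
from scipy.special import i0, i1

from plvnet.connectivity import epoch_averaged_plv
from plvnet.montage import MontageSpec, biosemi64
from plvnet.preprocess import BAND_BY_NAME
from plvnet.synth import (
    GROUP_HS,
    GROUP_LS,
    CouplingBlock,
    CouplingPlan,
    default_coupling_plan,
    generate_cohort,
    generate_subject,
    pair_plan,
    stratified_vonmises,
    vm_kappa_from_resultant,
    vm_resultant,
)

BETA = BAND_BY_NAME["beta"]


class TestVonMisesHelpers:
    @pytest.mark.parametrize("kappa", [0.1, 0.5, 1.0, 2.0, 5.0, 20.0])
    def test_resultant_matches_bessel_ratio(self, kappa):
        assert vm_resultant(kappa) == pytest.approx(i1(kappa) / i0(kappa), rel=1e-10)

    @pytest.mark.parametrize("r", [0.0, 0.1, 0.45, 0.9, 0.99])
    def test_kappa_inversion_roundtrip(self, r):
        assert vm_resultant(vm_kappa_from_resultant(r)) == pytest.approx(r, abs=1e-8)

    def test_resultant_monotone_in_kappa(self):
        ks = [0.0, 0.5, 1.0, 2.0, 5.0]
        rs = [vm_resultant(k) for k in ks]
        assert np.all(np.diff(rs) > 0)

    def test_stratified_sample_pins_the_resultant(self, rng):
        for kappa in (0.5, 2.0):
            vals = stratified_vonmises(kappa, 400, rng)
            emp = np.abs(np.mean(np.exp(1j * vals)))
            assert emp == pytest.approx(vm_resultant(kappa), abs=0.01)

    def test_stratified_uniform_phasors_cancel(self, rng):
        vals = stratified_vonmises(0.0, 64, rng)
        assert np.abs(np.mean(np.exp(1j * vals))) < 0.05


class TestCouplingPlan:
    def test_pair_kappa_symmetric_nonnegative_zero_diagonal(self):
        m = biosemi64()
        K = default_coupling_plan(m).pair_kappa(m)
        assert np.allclose(K, K.T)
        assert K.min() >= 0
        assert np.all(np.diag(K) == 0)

    def test_group_effect_modifies_planted_blocks_only(self):
        m = biosemi64()
        plan = default_coupling_plan(m)
        K_ls = plan.pair_kappa(m, group=GROUP_LS)
        K_hs = plan.pair_kappa(m, group=GROUP_HS)
        t = m.region_indices("temporal_frontotemporal_left")
        o = m.region_indices("occipital_parieto_occipital")
        assert K_hs[np.ix_(t, t)][0, 1] < K_ls[np.ix_(t, t)][0, 1]
        assert K_hs[np.ix_(o, o)][0, 1] > K_ls[np.ix_(o, o)][0, 1]

    def test_negative_effect_multiplier_rejected(self):
        m = MontageSpec(("A", "B"))
        block = CouplingBlock("b", ("A", "B"), 1.0)
        with pytest.raises(ValueError, match="negative"):
            CouplingPlan(blocks=(block,), group_effect={"HS-like": {"b": -0.5}})

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="multiple blocks"):
            CouplingPlan(
                blocks=(
                    CouplingBlock("a", ("X", "Y"), 1.0),
                    CouplingBlock("b", ("Y", "Z"), 1.0),
                )
            )


class TestGenerateSubject:
    def test_locked_pair_reaches_plv_one(self, kappa_pairs_recording):
        kappas, rec = kappa_pairs_recording
        P = epoch_averaged_plv(rec, BETA, use_truth_phases=True).values
        i = 2 * kappas.index(1e6)
        assert P[i, i + 1] == pytest.approx(1.0, abs=1e-3)

    def test_uncoupled_pair_plv_near_zero(self):
        # kappa=0 pairs: PLV shrinks with epoch count; 50 independent seeds
        vals = []
        plan, montage = pair_plan([0.0])
        for seed in range(50):
            rec = generate_subject(plan, montage, n_epochs=1, seed=seed, snr_db=None,
                                   bands=[BETA])
            vals.append(epoch_averaged_plv(rec, BETA, use_truth_phases=True).values[0, 1])
        assert np.mean(vals) < 0.1

    def test_bessel_ratio_recovery_kappa2(self):
        plan, montage = pair_plan([2.0])
        rec = generate_subject(plan, montage, n_epochs=100, seed=3, snr_db=None,
                               bands=[BETA])
        plv = epoch_averaged_plv(rec, BETA, use_truth_phases=True).values[0, 1]
        assert plv == pytest.approx(i1(2) / i0(2), abs=0.03)

    def test_recovery_curve_monotone_in_kappa(self, kappa_pairs_recording):
        kappas, rec = kappa_pairs_recording
        P = epoch_averaged_plv(rec, BETA, use_truth_phases=True).values
        curve = [P[2 * p, 2 * p + 1] for p in range(len(kappas))]
        assert np.all(np.diff(curve) > 0)

    def test_identical_seed_bit_identical(self):
        m = biosemi64()
        plan = default_coupling_plan(m)
        a = generate_subject(plan, m, seed=9, bands=[BETA], n_epochs=2)
        b = generate_subject(plan, m, seed=9, bands=[BETA], n_epochs=2)
        assert np.array_equal(a.data, b.data)

    def test_shapes_and_metadata(self, small_subject, montage64):
        assert small_subject.data.shape == (64, 1024, 20)
        assert small_subject.fs == 256.0
        assert small_subject.montage is montage64

    def test_fs_too_low_rejected(self):
        plan, montage = pair_plan([1.0])
        with pytest.raises(ValueError, match="at least 128"):
            generate_subject(plan, montage, fs=64)
        from plvnet.preprocess import BandDefinition

        with pytest.raises(ValueError, match="too low"):
            generate_subject(plan, montage, fs=128,
                             bands=[BandDefinition("high_gamma", 60.0, 70.0)])

    def test_snr_controls_noise_power(self):
        plan, montage = pair_plan([2.0])
        quiet = generate_subject(plan, montage, seed=1, snr_db=20, n_epochs=2, bands=[BETA])
        loud = generate_subject(plan, montage, seed=1, snr_db=-10, n_epochs=2, bands=[BETA])
        assert loud.data.var() > quiet.data.var()


class TestGenerateCohort:
    def test_cell_count_matches_design(self):
        m = biosemi64()
        recs = list(
            generate_cohort(n_ls=2, n_hs=2, montage=m, moods=("neutral", "anxiety"),
                            target_frequencies=(8, 10), n_epochs=1, bands=[BETA])
        )
        assert len(recs) == 4 * 2 * 2
        assert sum(r.group == GROUP_LS for r in recs) == 2 * 4
        cells = {(r.subject_id, r.condition.mood, r.condition.target_frequency) for r in recs}
        assert len(cells) == len(recs)

    def test_group_mean_plv_ordering_in_planted_regions(self):
        # temporal coupling: LS-like above HS-like, by construction
        m = biosemi64()
        plan = default_coupling_plan(m)
        t = m.region_indices("temporal_frontotemporal_left")
        o = m.region_indices("occipital_parieto_occipital")
        means = {GROUP_LS: [], GROUP_HS: []}
        means_occ = {GROUP_LS: [], GROUP_HS: []}
        for rec in generate_cohort(n_ls=5, n_hs=5, plan=plan, montage=m,
                                   moods=("anxiety",), target_frequencies=(16,),
                                   n_epochs=10, bands=[BETA], seed=2, keep_truth=True):
            P = epoch_averaged_plv(rec, BETA, use_truth_phases=True).values
            block = P[np.ix_(t, t)]
            means[rec.group].append(block[np.triu_indices_from(block, 1)].mean())
            blk_o = P[np.ix_(o, o)]
            means_occ[rec.group].append(blk_o[np.triu_indices_from(blk_o, 1)].mean())
        assert np.mean(means[GROUP_LS]) > np.mean(means[GROUP_HS])
        assert np.mean(means_occ[GROUP_LS]) < np.mean(means_occ[GROUP_HS])

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            list(generate_cohort(n_ls=1, n_hs=2))
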
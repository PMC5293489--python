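"""Covariance clustering: CCS matrices, filters, clusters, SVD validation."""

import numpy as np
import pytest

from allonmr import chesca, simulate
from allonmr.chesca import (
    ChescaMatrix,
    build_ccs_matrix,
    correlation_clusters,
    filter_by_activation_shift,
    validate_network,
)
from allonmr.peaklist import (
    AtomGroup,
    NucleusClass,
    PeakEntry,
    PeakList,
    ResonanceKey,
    StateSet,
)
from conftest import make_peaklist


def matrix_from_profiles(profiles, state_ids=None):
    """ChescaMatrix from {residue_number: per-state CCS values}."""
    residues = [ResonanceKey(n, "G") for n in sorted(profiles)]
    ccs = np.array([profiles[k.residue_number] for k in residues], dtype=float)
    state_ids = state_ids or [f"s{i}" for i in range(ccs.shape[1])]
    return ChescaMatrix(residues=residues, state_ids=state_ids, ccs=ccs)


class TestBuildCCS:
    def test_hand_value(self):
        states = StateSet(
            states=[make_peaklist(s, {1: (8.0, 120.0)}) for s in "abc"],
            spectrometer_h_mhz=600.0,
        )
        m = build_ccs_matrix(states)
        assert m.ccs[0, 0] == pytest.approx(0.2 * 120.0 + 8.0)  # 32.0

    def test_fewer_than_three_states_rejected(self):
        states = StateSet(
            states=[make_peaklist(s, {1: (8.0, 120.0)}) for s in "ab"],
            spectrometer_h_mhz=600.0,
        )
        with pytest.raises(ValueError, match="3 states"):
            build_ccs_matrix(states)

    def test_elementwise_oracle_on_simulated_panel(self, state_set):
        from allonmr.peaklist import align_states

        m = build_ccs_matrix(state_set)
        aligned = align_states(state_set)
        np.testing.assert_allclose(m.ccs, 0.2 * aligned.shift_x + aligned.shift_h)


class TestActivationFilter:
    def make_states(self, deltas_hz, mhz=600.0):
        """deltas_hz: {residue: (dH_hz, dN_hz)} between unphos and phos."""
        from allonmr.peaklist import GYRO_RATIO

        base = {n: (8.0, 120.0) for n in deltas_hz}
        phos = {
            n: (8.0 + dh / mhz, 120.0 + dn / (mhz * GYRO_RATIO["N15"]))
            for n, (dh, dn) in deltas_hz.items()
        }
        mut = {n: (8.0 + 0.001, 120.0 + 0.01) for n in deltas_hz}
        return StateSet(
            states=[make_peaklist("WT_unphos", base), make_peaklist("K659E", mut),
                    make_peaklist("WT_phos", phos)],
            spectrometer_h_mhz=mhz,
        )

    def test_unmoved_residue_excluded(self):
        ss = self.make_states({1: (0.0, 0.0), 2: (30.0, 20.0)})
        out = filter_by_activation_shift(ss)
        kept = {k.residue_number for k in out.get("WT_unphos").entries}
        assert kept == {2}

    def test_and_rule_keeps_single_dimension_movers(self):
        ss = self.make_states({1: (20.0, 0.0)})
        out = filter_by_activation_shift(ss, rule="and")
        assert len(out.get("WT_unphos").entries) == 1

    def test_or_rule_drops_single_dimension_movers(self):
        ss = self.make_states({1: (20.0, 0.0)})
        out = filter_by_activation_shift(ss, rule="or")
        assert len(out.get("WT_unphos").entries) == 0

    def test_brute_force_oracle(self, rng):
        deltas = {n: (float(rng.uniform(0, 30)), float(rng.uniform(0, 15)))
                  for n in range(1, 60)}
        ss = self.make_states(deltas)
        out = filter_by_activation_shift(ss)
        expected = {n for n, (dh, dn) in deltas.items() if not (dh < 10 and dn < 5)}
        assert {k.residue_number for k in out.get("WT_phos").entries} == expected

    def test_missing_reference_state_is_error(self):
        ss = StateSet(
            states=[make_peaklist(s, {1: (8.0, 120.0)}) for s in "abc"],
            spectrometer_h_mhz=600.0,
        )
        with pytest.raises(KeyError):
            filter_by_activation_shift(ss)


class TestCorrelationClusters:
    def test_identical_profiles_cluster_with_r_one(self):
        m = matrix_from_profiles({1: [0, 1, 2, 3], 2: [5, 6, 7, 8],
                                  3: [0.3, -1, 2.2, 0.1]})
        (cl,) = correlation_clusters(m)
        assert {k.residue_number for k in cl.members} == {1, 2}
        assert cl.min_abs_corr == pytest.approx(1.0)

    def test_anticorrelated_pair_clusters_by_absolute_value(self):
        m = matrix_from_profiles({1: [0, 1, 2, 3], 2: [3, 2, 1, 0],
                                  3: [0.3, -1, 2.2, 0.1]})
        (cl,) = correlation_clusters(m)
        assert {k.residue_number for k in cl.members} == {1, 2}

    def test_planted_network_recovered_exactly(self):
        """18 residues sharing a latent activation profile + 80 noise residues.

        The noise level is set so planted pairs stay above |r| = 0.98 while
        every spurious pair stays below the 0.97 cutoff (asserted as a
        premise: with only 7 states, random profiles correlate easily).
        """
        n_states = 7
        rng = np.random.default_rng(44)
        latent = np.linspace(0, 1, n_states)
        profiles = {}
        for i in range(18):
            amp = rng.uniform(0.15, 0.4) * rng.choice([-1, 1])
            profiles[i + 1] = amp * latent + rng.normal(0, 0.003, n_states)
        for i in range(80):
            profiles[100 + i] = rng.normal(0, 0.2, n_states)
        m = matrix_from_profiles(profiles)
        corr = np.abs(np.corrcoef(m.ccs))
        planted_idx = [i for i, k in enumerate(m.residues) if k.residue_number < 100]
        noise_idx = [i for i, k in enumerate(m.residues) if k.residue_number >= 100]
        assert corr[np.ix_(planted_idx, planted_idx)].min() > 0.98
        spurious = corr[np.ix_(noise_idx, noise_idx)].copy()
        np.fill_diagonal(spurious, 0.0)
        assert max(spurious.max(), corr[np.ix_(planted_idx, noise_idx)].max()) < 0.97
        clusters = correlation_clusters(m)
        recovered = {k.residue_number for c in clusters for k in c.members}
        assert recovered == set(range(1, 19))

    def test_within_cluster_guarantee_holds_posthoc(self, rng):
        profiles = {i: list(rng.normal(0, 1, 6)) for i in range(1, 40)}
        m = matrix_from_profiles(profiles)
        corr = np.corrcoef(m.ccs)
        for cl in correlation_clusters(m, cutoff=0.9):
            idx = [m.residues.index(k) for k in cl.members]
            sub = np.abs(corr[np.ix_(idx, idx)])
            off = sub[~np.eye(len(idx), dtype=bool)]
            assert off.min() >= 0.9

    def test_invariant_to_residue_input_order(self, rng):
        profiles = {i: list(rng.normal(0, 1, 7)) for i in range(1, 30)}
        latent = np.arange(7.0)
        for i in (3, 9, 17):
            profiles[i] = list(2.0 * latent)
        m = matrix_from_profiles(profiles)
        perm = ChescaMatrix(
            residues=list(reversed(m.residues)), state_ids=m.state_ids,
            ccs=m.ccs[::-1].copy(),
        )
        a = [{k.residue_number for k in c.members} for c in correlation_clusters(m)]
        b = [{k.residue_number for k in c.members} for c in correlation_clusters(perm)]
        assert a == b

    def test_correlation_matrix_symmetric_unit_diagonal(self, rng):
        ccs = rng.normal(0, 1, (12, 7))
        corr = np.corrcoef(ccs)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_zero_variance_profile_dropped_with_warning(self):
        m = matrix_from_profiles({1: [1, 1, 1, 1], 2: [0, 1, 2, 3],
                                  3: [0, 2, 4, 6]})
        with pytest.warns(UserWarning, match="zero-variance"):
            (cl,) = correlation_clusters(m)
        assert {k.residue_number for k in cl.members} == {2, 3}


class TestValidateNetwork:
    def test_rank_one_submatrix_has_pc1_fraction_one(self):
        latent = np.array([0.0, 0.2, 0.5, 0.7, 1.0])
        profiles = {i: list(i * latent) for i in range(1, 6)}
        m = matrix_from_profiles(profiles)
        clusters = correlation_clusters(m)
        val = validate_network(m, clusters)
        assert val.pc1_variance_fraction == pytest.approx(1.0, abs=1e-10)

    def test_single_latent_factor_loads_on_pc1_with_consistent_sign(self, rng):
        latent = np.linspace(0, 1, 7)
        profiles = {i: list(rng.uniform(0.2, 0.5) * latent
                            + rng.normal(0, 0.004, 7)) for i in range(1, 19)}
        m = matrix_from_profiles(profiles)
        clusters = correlation_clusters(m)
        val = validate_network(m, clusters)
        assert val.pc1_variance_fraction > 0.95
        signs = np.sign(val.svd_loadings[:, 0])
        assert len(set(signs)) == 1

    def test_two_independent_factors_give_two_clusters_distinct_dendrograms(self, rng):
        f1 = np.array([0.0, 0.1, 0.5, 0.9, 1.0, 0.2, 0.6])
        f2 = np.array([1.0, 0.0, 0.8, 0.1, 0.5, 0.9, 0.3])
        profiles = {}
        for i in range(1, 7):
            profiles[i] = list(rng.uniform(0.2, 0.5) * f1)
        for i in range(10, 16):
            profiles[i] = list(rng.uniform(0.2, 0.5) * f2)
        for i in range(50, 70):
            profiles[i] = list(rng.normal(0, 0.3, 7))
        m = matrix_from_profiles(profiles)
        clusters = correlation_clusters(m)
        member_sets = [{k.residue_number for k in c.members} for c in clusters]
        assert set(range(1, 7)) in member_sets
        assert set(range(10, 16)) in member_sets
        val = validate_network(m, clusters)
        assert len(val.state_newicks) == len(clusters)
        assert val.state_newicks[0] != val.state_newicks[1]

    def test_no_clusters_is_an_error(self):
        m = matrix_from_profiles({1: [0, 1, 2, 3]})
        with pytest.raises(ValueError):
            validate_network(m, [])


def test_pipeline_recovers_planted_network_from_simulated_panel(two_state_spec):
    """End to end: simulate 7 states, filter, cluster; members = planted set."""
    ss = simulate.simulate_states(two_state_spec)
    ss = filter_by_activation_shift(ss)
    matrix = build_ccs_matrix(ss)
    clusters = correlation_clusters(matrix)
    recovered = {k.residue_number for c in clusters for k in c.members}
    assert recovered == set(two_state_spec.network_residue_numbers())
    val = validate_network(matrix, clusters)
    assert val.pc1_variance_fraction > 0.95
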
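import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specs import (
    FixtureSpec,
    SpecsConfig,
    evaluate,
    make_decoy,
    make_native,
    score_dca,
    score_dihedral,
    score_planar,
    score_rsc,
    specs_total,
)
from specs.specs_metric import NormalizationError

from conftest import random_rigid, structure_pair, transform_structure
from oracles import cumulative_bin_score, mean_threshold_fraction

CONFIG = SpecsConfig()


class TestScoreDca:
    def test_worked_example(self):
        distances = [0.4, 1.5, 3.0, 9.0]
        counts = [sum(d <= t for d in distances) for t in CONFIG.ca_thresholds]
        dca, profile = score_dca(counts, n_native=4)
        expected, expected_profile = mean_threshold_fraction(
            distances, CONFIG.ca_thresholds, 4
        )
        assert profile == (0.25, 0.25, 0.5, 0.75)
        assert dca == pytest.approx(0.4375, abs=1e-15)
        assert dca == pytest.approx(expected, abs=1e-15)
        assert profile == expected_profile

    def test_all_within_smallest(self):
        dca, _ = score_dca([5, 5, 5, 5], n_native=5)
        assert dca == 1.0

    def test_all_beyond_largest(self):
        dca, _ = score_dca([0, 0, 0, 0], n_native=5)
        assert dca == 0.0

    def test_zero_native_raises(self):
        with pytest.raises(NormalizationError):
            score_dca([1, 1, 1, 1], n_native=0)


class TestScoreRsc:
    def test_worked_example(self):
        rsc, _ = score_rsc([0.3, 1.2, 4.8, 6.0], n_sc=4)
        assert rsc == pytest.approx(23.0 / 55.0, abs=1e-15)

    def test_all_in_first_bin(self):
        rsc, profile = score_rsc([0.1, 0.4, 0.5], n_sc=3)
        assert rsc == 1.0
        assert profile == (1.0,) * 10

    def test_all_beyond_last_bin(self):
        rsc, _ = score_rsc([5.1, 80.0], n_sc=2)
        assert rsc == 0.0

    def test_zero_n_sc_raises(self):
        with pytest.raises(NormalizationError):
            score_rsc([1.0], n_sc=0)


class TestScorePlanar:
    def test_worked_example(self):
        score, profile = score_planar([math.radians(20), math.radians(95)], n_sc=2)
        assert profile == (0.5, 0.5, 0.5, 1.0)
        assert score == pytest.approx(0.55, abs=1e-15)

    def test_all_in_first_bin(self):
        score, _ = score_planar([math.radians(10)] * 3, n_sc=3)
        assert score == 1.0

    def test_all_beyond_last_bin(self):
        score, _ = score_planar([math.radians(150)] * 3, n_sc=3)
        assert score == 0.0


class TestScoreDihedral:
    def test_worked_example(self):
        angles = [math.radians(a) for a in (10.0, 190.0, 310.0)]
        score, _ = score_dihedral(angles, n_sc=3)
        assert score == pytest.approx((65.0 / 3.0) / 55.0, abs=1e-14)

    def test_all_in_first_bin(self):
        score, _ = score_dihedral([math.radians(5)] * 4, n_sc=4)
        assert score == 1.0

    def test_all_beyond_last_bin(self):
        score, _ = score_dihedral([math.radians(330)] * 4, n_sc=4)
        assert score == 0.0

    def test_bin7_variant(self):
        config = SpecsConfig.with_dihedral_bin7(201.0)
        angle = [math.radians(205.0)]
        default_score, _ = score_dihedral(angle, n_sc=1)
        variant_score, _ = score_dihedral(angle, n_sc=1, config=config)
        assert default_score > variant_score  # 205 <= 210 but not <= 201


class TestOracleEquivalence:
    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=200, deadline=None)
    def test_rsc_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        values = rng.uniform(0.0, 7.0, n)
        n_norm = n + int(rng.integers(0, 5))
        score, profile = score_rsc(values, n_norm)
        expected, expected_profile = cumulative_bin_score(values, CONFIG.sc_bins, n_norm)
        assert score == pytest.approx(expected, abs=1e-12)
        assert profile == pytest.approx(expected_profile, abs=1e-15)

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=200, deadline=None)
    def test_planar_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, math.pi, int(rng.integers(1, 30)))
        score, _ = score_planar(values, len(values))
        expected, _ = cumulative_bin_score(values, CONFIG.planar_bins_rad, len(values))
        assert score == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=200, deadline=None)
    def test_dihedral_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, 2.0 * math.pi, int(rng.integers(1, 30)))
        score, _ = score_dihedral(values, len(values))
        expected, _ = cumulative_bin_score(values, CONFIG.dihedral_bins_rad, len(values))
        assert score == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None)
    def test_monotone_under_scaling_and_offset(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, 6.0, 15)
        base, _ = score_rsc(values, 15)
        scaled, _ = score_rsc(values * rng.uniform(1.0, 3.0), 15)
        assert scaled <= base + 1e-15
        distances = rng.uniform(0.0, 6.0, 15)
        counts = [int(np.count_nonzero(distances <= t)) for t in CONFIG.ca_thresholds]
        shifted = distances + rng.uniform(0.0, 3.0)
        counts_shifted = [int(np.count_nonzero(shifted <= t)) for t in CONFIG.ca_thresholds]
        base_dca, _ = score_dca(counts, 15)
        shifted_dca, _ = score_dca(counts_shifted, 15)
        assert shifted_dca <= base_dca + 1e-15


class TestSpecsTotal:
    def test_all_ones(self):
        assert specs_total(1.0, 1.0, 1.0, 1.0, 1.0) == 1.0

    def test_all_zeros(self):
        assert specs_total(0.0, 0.0, 0.0, 0.0, 0.0) == 0.0

    def test_worked_example(self):
        # exact weighted form on the exact component fractions:
        # (4*0.4375 + 23/55 + 0.55 + 0.55 + (65/3)/55) / 8
        total = specs_total(0.4375, 23.0 / 55.0, 0.55, 0.55, (65.0 / 3.0) / 55.0)
        assert total == pytest.approx(0.4577651515151515, abs=1e-12)

    @given(
        components=st.tuples(*[st.floats(0.0, 1.0, allow_nan=False) for _ in range(5)])
    )
    @settings(max_examples=1000, deadline=None)
    def test_weighted_form_exact(self, components):
        dca, rsc, t1, t2, phi = components
        assert specs_total(dca, rsc, t1, t2, phi) == (4.0 * dca + rsc + t1 + t2 + phi) / 8.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            specs_total(1.2, 0.5, 0.5, 0.5, 0.5)


class TestConfig:
    def test_non_increasing_bins_rejected(self):
        with pytest.raises(ValueError):
            SpecsConfig(planar_bins_deg=(30.0, 30.0, 90.0, 120.0))

    def test_dca_profile_equals_gdt_ha_formula(self):
        # single-transform component == GDT-HA with thresholds 0.5/1/2/4
        rng = np.random.default_rng(17)
        distances = rng.uniform(0.0, 6.0, 40)
        counts = [int(np.count_nonzero(distances <= t)) for t in CONFIG.ca_thresholds]
        dca, _ = score_dca(counts, 40)
        gdt_ha = sum(
            np.count_nonzero(distances <= t) / 40 for t in (0.5, 1.0, 2.0, 4.0)
        ) / 4.0
        assert dca == pytest.approx(gdt_ha, abs=1e-15)


class TestEvaluate:
    def test_self_identity(self, helix_native):
        components = evaluate(helix_native, helix_native)
        assert components.dca == 1.0
        assert components.rsc == 1.0
        assert components.theta1 == 1.0
        assert components.theta2 == 1.0
        assert components.phi == 1.0
        assert components.total == 1.0

    def test_rigid_motion_gives_perfect_score(self, helix_native):
        rng = np.random.default_rng(5)
        rotation, translation = random_rigid(rng)
        moved = transform_structure(helix_native, rotation, translation)
        components = evaluate(moved, helix_native)
        assert components.total == pytest.approx(1.0, abs=1e-6)

    def test_rigid_motion_invariance_of_decoy_score(self):
        model, native = structure_pair(seed=21, n=18)
        base = evaluate(model, native)
        rng = np.random.default_rng(123)
        rotation, translation = random_rigid(rng)
        moved = evaluate(transform_structure(model, rotation, translation), native)
        for name in ("dca", "rsc", "theta1", "theta2", "phi", "total"):
            assert getattr(moved, name) == pytest.approx(getattr(base, name), abs=1e-6)

    def test_perfect_ca_rotated_sidechains(self, helix_native):
        spec = FixtureSpec(n_residues=25, sc_rotation_deg=160.0, seed=11)
        decoy = make_decoy(helix_native, spec)
        components = evaluate(decoy, helix_native)
        assert components.dca == 1.0
        assert components.total < 1.0

    def test_components_in_unit_interval(self):
        for seed in range(40, 46):
            model, native = structure_pair(seed=seed, n=15, sigma=1.5, rotation=120.0)
            components = evaluate(model, native)
            for name in ("dca", "rsc", "theta1", "theta2", "phi", "total"):
                value = getattr(components, name)
                assert 0.0 <= value <= 1.0
            for profile in components.bin_profiles.values():
                assert list(profile) == sorted(profile)  # cumulative => non-decreasing

    def test_total_reproduces_weighted_form(self):
        model, native = structure_pair(seed=50, n=20)
        c = evaluate(model, native)
        assert c.total == (4.0 * c.dca + c.rsc + c.theta1 + c.theta2 + c.phi) / 8.0

    def test_poly_glycine_native(self):
        native = make_native(FixtureSpec(n_residues=8, gly_fraction=1.0, seed=2))
        components = evaluate(native, native)
        assert components.rsc is None
        assert components.total == components.dca == 1.0
        assert not components.sc_defined
        assert any("side-chain" in w for w in components.warnings)

    def test_missing_model_sidechain_penalized(self, helix_native):
        from copy import deepcopy

        model = deepcopy(helix_native)
        stripped = 0
        for res in model.residues:
            if res.res_name != "GLY" and stripped < 4:
                for name in list(res.atoms):
                    if name not in ("N", "CA", "C", "O"):
                        del res.atoms[name]
                stripped += 1
        components = evaluate(model, helix_native)
        assert components.dca == 1.0
        n_sc = components.n_native_sc
        assert components.rsc == pytest.approx((n_sc - stripped) / n_sc, abs=1e-12)
        assert components.total < 1.0

    def test_missing_model_residues_penalize_dca(self, helix_native):
        from specs.structure_io import Structure

        kept = helix_native.residues[:20]
        model = Structure(list(kept), "partial")
        components = evaluate(model, helix_native)
        assert components.n_pairs == 20
        assert components.n_native == 25
        assert components.dca == pytest.approx(20.0 / 25.0, abs=1e-12)

    def test_too_few_pairs_raises(self, helix_native):
        from specs.structure_io import Structure
        from specs.superposition import SuperpositionError

        model = Structure(list(helix_native.residues[:2]), "tiny")
        with pytest.raises(SuperpositionError):
            evaluate(model, helix_native)
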
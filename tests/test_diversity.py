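import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gvpop.diversity import (
    AlleleProfile,
    dN_density_by_group,
    harmonic_number,
    pi_between_hosts,
    pi_within_host,
    profiles_from_matrix,
    theta_per_orf,
    watterson_theta,
)
from gvpop.io_formats import FunctionalGroup, OrfAnnotation
from gvpop.synthetic_data import SimConfig, simulate_cohort
from gvpop.variant_filtering import SegregatingSiteSet

from conftest import build_matrix


def brute_force_pi(genotypes):
    """Average over all sample pairs of (pairwise differences / sites compared),
    counting only sites where both samples are called."""
    n_sites, n_samples = genotypes.shape
    pair_vals = []
    for a, b in itertools.combinations(range(n_samples), 2):
        diffs = per_site = 0
        for i in range(n_sites):
            ga, gb = genotypes[i, a], genotypes[i, b]
            if ga < 0 or gb < 0:
                continue
            per_site += 1
            diffs += int(ga != gb)
        if per_site:
            pair_vals.append(diffs)
    return pair_vals


class TestPiBetween:
    def test_monomorphic_limit(self):
        m = build_matrix(np.zeros((5, 6), dtype=np.int16))
        assert pi_between_hosts(m) == 0.0

    def test_two_samples_two_of_ten_sites(self):
        g = np.zeros((10, 2), dtype=np.int16)
        g[0, 1] = g[1, 1] = 1
        assert pi_between_hosts(build_matrix(g)) == pytest.approx(0.2, abs=1e-12)

    def test_three_sample_worked_example(self):
        # columns (A,A,T) and (A,T,T): per-site 3/2 * (1 - 5/9) = 2/3
        g = np.array([[0, 0, 1], [0, 1, 1]], dtype=np.int16)
        pi = pi_between_hosts(build_matrix(g))
        assert pi == pytest.approx(2 / 3, abs=1e-12)
        # equals brute force: 4 mismatches / 3 pairs / 2 sites
        assert pi == pytest.approx(4 / 3 / 2, abs=1e-12)

    def test_total_length_denominator(self):
        g = np.array([[0, 1]], dtype=np.int16)
        pi = pi_between_hosts(build_matrix(g), None, total_length=100)
        assert pi == pytest.approx(2 * 0.5 / 100, abs=1e-12)

    def test_site_restriction(self):
        g = np.array([[0, 1], [0, 1], [0, 0]], dtype=np.int16)
        m = build_matrix(g, positions=[5, 15, 25])
        seg = SegregatingSiteSet(positions=np.array([5, 25]), min_carrier_count=0)
        assert pi_between_hosts(m, seg) == pytest.approx(0.5, abs=1e-12)

    def test_sparse_site_skipped_with_warning(self):
        g = np.array([[0, -1, -1], [0, 1, 0]], dtype=np.int16)
        with pytest.warns(UserWarning, match="skipped"):
            pi = pi_between_hosts(build_matrix(g))
        assert pi == pytest.approx(1.5 * (1 - 5 / 9), abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        st.integers(2, 20).flatmap(
            lambda n: st.lists(
                st.lists(st.integers(-1, 1), min_size=n, max_size=n),
                min_size=1,
                max_size=50,
            )
        )
    )
    def test_equals_exhaustive_pairwise_oracle(self, rows):
        """The corrected-heterozygosity form equals the mean pairwise
        difference count per pair, averaged over sites, to 1e-12."""
        g = np.asarray(rows, dtype=np.int16)
        # oracle on fully-called matrices (the pairwise identity holds per site
        # with missing data only under per-site n; restrict to called case)
        g = np.abs(g)
        n_sites = g.shape[0]
        m = build_matrix(g)
        pairs = brute_force_pi(g)
        expected = np.mean(pairs) / n_sites if pairs else 0.0
        assert pi_between_hosts(m) == pytest.approx(expected, abs=1e-12)


class TestPiWithin:
    def test_fixed_allele_limit(self):
        prof = AlleleProfile("s", [0, 1, 2], [0.0, 1.0, 0.0], [50, 50, 50])
        sites = SegregatingSiteSet(np.array([0, 1, 2]), 0)
        assert pi_within_host(prof, sites) == 0.0

    def test_single_site_worked_example(self):
        prof = AlleleProfile("s", [0], [0.5], [100])
        sites = SegregatingSiteSet(np.array([0]), 0)
        assert pi_within_host(prof, sites) == pytest.approx(0.5050505050505051, abs=1e-9)

    def test_two_site_worked_example(self):
        prof = AlleleProfile("s", [0, 1], [0.2, 0.0], [50, 50])
        sites = SegregatingSiteSet(np.array([0, 1]), 0)
        assert pi_within_host(prof, sites) == pytest.approx((0.32653061224489793 + 0) / 2, abs=1e-9)

    def test_uncorrected_flag(self):
        prof = AlleleProfile("s", [0], [0.5], [100])
        sites = SegregatingSiteSet(np.array([0]), 0)
        assert pi_within_host(prof, sites, corrected=False) == pytest.approx(0.5, abs=1e-12)

    def test_absent_sites_count_as_fixed_reference(self):
        prof = AlleleProfile("s", [0], [0.5], [100])
        sites = SegregatingSiteSet(np.array([0, 7]), 0)
        expected = (2 * 0.25 * 100 / 99 + 0.0) / 2
        assert pi_within_host(prof, sites) == pytest.approx(expected, abs=1e-12)

    def test_low_depth_sites_skipped(self):
        prof = AlleleProfile("s", [0, 1], [0.5, 0.5], [1, 100])
        sites = SegregatingSiteSet(np.array([0, 1]), 0)
        assert pi_within_host(prof, sites) == pytest.approx(0.5050505050505051, abs=1e-9)

    def test_empty_site_set_rejected(self):
        prof = AlleleProfile("s", [0], [0.5], [100])
        with pytest.raises(ValueError):
            pi_within_host(prof, SegregatingSiteSet(np.array([], dtype=int), 0))

    def test_invariant_to_site_ordering(self):
        rng = np.random.default_rng(4)
        pos = np.arange(30)
        p = rng.random(30)
        d = rng.integers(2, 200, 30)
        sites = SegregatingSiteSet(pos, 0)
        a = pi_within_host(AlleleProfile("s", pos, p, d), sites)
        perm = rng.permutation(30)
        b = pi_within_host(AlleleProfile("s", pos[perm], p[perm], d[perm]), sites)
        assert a == pytest.approx(b, abs=1e-12)

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AlleleProfile("s", [0, 0], [0.5, 0.5], [10, 10])


class TestWattersonTheta:
    def test_no_polymorphism(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_worked_example(self):
        # n=4: a_n = 1 + 1/2 + 1/3 = 1.833333; 3/(1.833333*100)
        assert watterson_theta(3, 4, 100) == pytest.approx(0.016364, abs=5e-7)

    def test_base_case_n2(self):
        assert watterson_theta(5, 2, 50) == pytest.approx(5 / 50, abs=1e-15)
        assert harmonic_number(2) == 1.0

    def test_rejects_single_sequence(self):
        with pytest.raises(ValueError):
            watterson_theta(1, 1, 100)

    def test_monotone_in_S_and_decreasing_in_n(self):
        for S in range(0, 5):
            assert watterson_theta(S + 1, 8, 100) > watterson_theta(S, 8, 100)
        vals = [watterson_theta(3, n, 100) for n in range(2, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_per_orf_counts(self):
        g = np.array([[0, 1, 0], [0, 0, 0], [1, 1, 1], [0, 1, 1]], dtype=np.int16)
        m = build_matrix(g, positions=[5, 50, 105, 140])
        orfs = [OrfAnnotation("a", 0, 120, "+"), OrfAnnotation("b", 120, 300, "+")]
        # site 5 polymorphic, 50 monomorphic, 105 fixed-alt (monomorphic), 140 polymorphic
        out = theta_per_orf(m, orfs)
        assert out["a"] == pytest.approx(watterson_theta(1, 3, 120), abs=1e-15)
        assert out["b"] == pytest.approx(watterson_theta(1, 3, 180), abs=1e-15)


class TestDnDensity:
    def test_unit_arithmetic_and_group_mean(self):
        orfs = [
            OrfAnnotation("x", 0, 1000, "+", FunctionalGroup.AUXILIARY),
            OrfAnnotation("y", 1000, 2000, "+", FunctionalGroup.AUXILIARY),
            OrfAnnotation("z", 2000, 2500, "+", FunctionalGroup.REPLICATION),
        ]
        with pytest.warns(UserWarning, match="no ORFs"):
            dens = dN_density_by_group({"x": 4, "y": 6, "z": 0}, orfs)
        assert dens["auxiliary"] == pytest.approx(5.0, abs=1e-12)
        assert dens["replication"] == 0.0
        assert "transcription" not in dens

    def test_zero_calls_give_zero_density(self):
        orfs = [OrfAnnotation("x", 0, 900, "+", FunctionalGroup.UNKNOWN)]
        with pytest.warns(UserWarning):
            dens = dN_density_by_group({}, orfs)
        assert dens["unknown"] == 0.0


def test_single_strain_cohort_has_near_zero_within_host_pi():
    """Every host in a single-strain cohort stays below the sequencing-noise
    bound 3/mean_depth."""
    cfg = SimConfig(
        genome_length=8_000,
        n_years=1,
        seasons_per_year=1,
        reservoir_size=12,
        year_pool_size=12,
        reservoir_mutation_rate=2e-3,
        founder_count_per_wave=(8, 4, 2),
        hosts_per_wave=6,
        multiplicity_probs=(1.0, 0.0, 0.0),
        sequencing_error_rate=1e-3,
        read_depth=100.0,
        n_orfs=6,
        n_hr_regions=0,
        total_isolates=None,
        seed=21,
    )
    cohort = simulate_cohort(cfg)
    from gvpop.variant_filtering import find_segregating_sites

    seg = find_segregating_sites(cohort.matrix, min_carriers=0)
    profiles = profiles_from_matrix(cohort.matrix)
    for sid, prof in profiles.items():
        assert pi_within_host(prof, seg) <= 3 / cfg.read_depth
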
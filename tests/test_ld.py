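"""LD statistics: exact haplotype counting, profiles, persistence, weights."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multibreed import (
    gld_weights,
    ld_decay,
    neighbor_profiles,
    pairwise_ld,
    phase_persistence,
)
from multibreed.ld import LdError, LdProfile

from conftest import phased_panel_from_haplotypes


def haplotype_panel_from_counts(n_AB, n_Ab, n_aB, n_ab, **kw):
    hap = np.array(
        [[1, 1]] * n_AB + [[1, 0]] * n_Ab + [[0, 1]] * n_aB + [[0, 0]] * n_ab,
        dtype=np.int8,
    )
    return phased_panel_from_haplotypes(hap, **kw)


class TestPairwiseLd:
    def test_complete_ld(self):
        panel = haplotype_panel_from_counts(50, 0, 0, 50)
        D, r, r2 = pairwise_ld(panel, 0, 1)
        assert D == pytest.approx(0.25)
        assert r2 == pytest.approx(1.0)

    def test_linkage_equilibrium(self):
        panel = haplotype_panel_from_counts(25, 25, 25, 25)
        D, r, r2 = pairwise_ld(panel, 0, 1)
        assert D == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        """f(AB)=0.4, D=0.15, r2=0.0225/0.0625=0.36 by hand evaluation."""
        panel = haplotype_panel_from_counts(40, 10, 10, 40)
        D, r, r2 = pairwise_ld(panel, 0, 1)
        assert D == pytest.approx(0.15)
        assert r2 == pytest.approx(0.36)
        assert r == pytest.approx(0.6)

    def test_matches_bruteforce_counting(self, rng):
        """Phased-panel LD equals brute-force haplotype-frequency counting
        on random panels with <= 50 haplotypes."""
        for _ in range(30):
            n_hap = int(rng.integers(4, 51)) * 2 // 2
            n_hap += n_hap % 2
            hap = rng.integers(0, 2, size=(n_hap, 2)).astype(np.int8)
            if hap[:, 0].std() == 0 or hap[:, 1].std() == 0:
                continue
            panel = phased_panel_from_haplotypes(hap)
            D, r, r2 = pairwise_ld(panel, 0, 1)
            fAB = np.mean((hap[:, 0] == 1) & (hap[:, 1] == 1))
            fA, fB = hap[:, 0].mean(), hap[:, 1].mean()
            D_ref = fAB - fA * fB
            r2_ref = D_ref**2 / (fA * (1 - fA) * fB * (1 - fB))
            assert D == pytest.approx(D_ref, abs=1e-12)
            assert r2 == pytest.approx(r2_ref, abs=1e-12)

    def test_allele_swap_invariance(self):
        panel = haplotype_panel_from_counts(40, 10, 10, 40)
        hap = panel.haplotypes().copy()
        hap[:, 0] = 1 - hap[:, 0]  # swap labels at marker 1
        swapped = phased_panel_from_haplotypes(hap)
        _, r0, r2_0 = pairwise_ld(panel, 0, 1)
        _, r1, r2_1 = pairwise_ld(swapped, 0, 1)
        assert r2_1 == pytest.approx(r2_0, abs=1e-12)
        assert r1 == pytest.approx(-r0, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(1, 25), st.integers(1, 25),
        st.integers(1, 25), st.integers(1, 25),
    )
    def test_bounds_and_swap_property(self, n_AB, n_Ab, n_aB, n_ab):
        """For any polymorphic haplotype table: r2 in [0,1], |r| <= 1, r2
        invariant under an allele-label swap while r flips sign."""
        # counts doubled so haplotypes always pair into diploids
        n_AB, n_Ab, n_aB, n_ab = 2 * n_AB, 2 * n_Ab, 2 * n_aB, 2 * n_ab
        panel = haplotype_panel_from_counts(n_AB, n_Ab, n_aB, n_ab)
        D, r, r2 = pairwise_ld(panel, 0, 1)
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
        assert 0.0 <= r2 <= 1.0 + 1e-12
        swapped = haplotype_panel_from_counts(n_aB, n_ab, n_AB, n_Ab)  # swap at marker 1
        D2, r_s, r2_s = pairwise_ld(swapped, 0, 1)
        assert r2_s == pytest.approx(r2, abs=1e-12)
        assert r_s == pytest.approx(-r, abs=1e-12)

    def test_monomorphic_is_explicit_error(self):
        hap = np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=np.int8)
        with pytest.raises(LdError, match="monomorphic"):
            pairwise_ld(phased_panel_from_haplotypes(hap), 0, 1)

    def test_unphased_fallback_matches_composite_ld(self, rng):
        hap = rng.integers(0, 2, size=(60, 2)).astype(np.int8)
        panel = phased_panel_from_haplotypes(hap)
        unphased = phased_panel_from_haplotypes(hap)
        unphased.phase = None
        _, r_u, _ = pairwise_ld(unphased, 0, 1)
        dos = panel.dosages
        assert r_u == pytest.approx(np.corrcoef(dos[:, 0], dos[:, 1])[0, 1])


class TestNeighborProfiles:
    def make_panel(self, n_markers, rng, chrom=None):
        hap = rng.integers(0, 2, size=(40, n_markers)).astype(np.int8)
        hap[0] = 1 - hap[1]  # guard against monomorphism
        return phased_panel_from_haplotypes(hap, chrom=chrom)

    def test_middle_marker_has_k_neighbors(self, rng):
        panel = self.make_panel(11, rng)
        profs = neighbor_profiles(panel, k=10)
        mid = profs[5]
        assert mid.neighbor_indices.size == 10
        assert set(mid.neighbor_indices) == set(range(11)) - {5}

    def test_first_marker_neighbors_are_next_k(self, rng):
        panel = self.make_panel(15, rng)
        profs = neighbor_profiles(panel, k=10)
        assert list(profs[0].neighbor_indices) == list(range(1, 11))

    def test_truncated_at_small_chromosome(self, rng):
        panel = self.make_panel(6, rng)
        profs = neighbor_profiles(panel, k=10)
        assert profs[2].neighbor_indices.size == 5

    def test_never_crosses_chromosomes(self, rng):
        chrom = np.array([1] * 6 + [2] * 6)
        panel = self.make_panel(12, rng, chrom=chrom)
        profs = neighbor_profiles(panel, k=10)
        for p in profs[:6]:
            assert np.all(p.neighbor_indices < 6)
        for p in profs[6:]:
            assert np.all(p.neighbor_indices >= 6)

    def test_profiles_match_pairwise_ld(self, rng):
        panel = self.make_panel(8, rng)
        profs = neighbor_profiles(panel, k=4)
        for p in profs:
            for nb, r2 in zip(p.neighbor_indices, p.r2_values):
                if np.isnan(r2):
                    continue
                _, _, r2_ref = pairwise_ld(panel, p.marker_index, int(nb))
                assert r2 == pytest.approx(r2_ref, abs=1e-10)


class TestPhasePersistence:
    def test_self_comparison_is_one(self, sim_two_breed):
        pa = sim_two_breed["panel"].select_breed("A")
        pp = phase_persistence(pa, pa)
        for val in pp.per_chromosome.values():
            assert val == pytest.approx(1.0, abs=1e-12)
        assert pp.genome_average == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, sim_two_breed):
        pa = sim_two_breed["panel"].select_breed("A")
        pb = sim_two_breed["panel"].select_breed("B")
        ab = phase_persistence(pa, pb)
        ba = phase_persistence(pb, pa)
        assert ab.genome_average == pytest.approx(ba.genome_average, abs=1e-12)

    def test_schemes_bounded(self, sim_two_breed):
        pa = sim_two_breed["panel"].select_breed("A")
        pb = sim_two_breed["panel"].select_breed("B")
        for scheme in ("signed_r", "r_squared"):
            pp = phase_persistence(pa, pb, scheme=scheme)
            assert -1.0 <= pp.genome_average <= 1.0

    def test_map_mismatch_rejected(self, sim_two_breed):
        pa = sim_two_breed["panel"].select_breed("A")
        pb = sim_two_breed["panel"].select_breed("B").subset(markers=np.arange(10))
        with pytest.raises(ValueError):
            phase_persistence(pa, pb.subset(markers=np.arange(5)))


class TestLdDecay:
    def test_two_markers_single_bin(self):
        panel = haplotype_panel_from_counts(40, 10, 10, 40, pos=[1000, 2000])
        table = ld_decay(panel, max_distance_bp=5000, n_bins=5)
        populated = table[table["n_pairs"] > 0]
        assert len(populated) == 1
        assert populated["mean_r2"].iloc[0] == pytest.approx(0.36)

    def test_out_of_range_pairs_leave_bins_empty(self):
        panel = haplotype_panel_from_counts(40, 10, 10, 40, pos=[1000, 900000])
        table = ld_decay(panel, max_distance_bp=1000, n_bins=3)
        assert (table["n_pairs"] == 0).all()
        assert table["mean_r2"].isna().all()

    def test_decay_trend_on_simulated_panel(self, sim_two_breed):
        from scipy.stats import spearmanr

        pa = sim_two_breed["panel"].select_breed("A")
        table = ld_decay(pa, max_distance_bp=40_000_000, n_bins=8)
        ok = table["n_pairs"] > 0
        rho, _ = spearmanr(np.arange(ok.sum()), table.loc[ok, "mean_r2"])
        assert rho <= 0


class TestGldWeights:
    def test_identical_panels_give_unit_weights(self, sim_two_breed):
        pa = sim_two_breed["panel"].select_breed("A")
        profs = neighbor_profiles(pa, k=6)
        w = gld_weights(profs, profs)
        assert np.all(w <= 1.0 + 1e-12)
        assert np.mean(w > 0.999999) > 0.95  # degenerate profiles may fall back

    def test_anticorrelated_profile_floored_to_zero(self):
        r2a = np.array([0.1, 0.5, 0.9])
        r2b = np.array([0.9, 0.5, 0.1])
        p1 = [LdProfile(0, np.array([1, 2, 3]), r2a, np.sqrt(r2a))]
        p2 = [LdProfile(0, np.array([1, 2, 3]), r2b, np.sqrt(r2b))]
        w = gld_weights(p1, p2)
        assert w[0] == 0.0

    def test_single_shared_pair_gets_global_mean(self):
        good_a = LdProfile(0, np.array([1, 2, 3]), np.array([0.1, 0.4, 0.8]),
                           np.zeros(3))
        good_b = LdProfile(0, np.array([1, 2, 3]), np.array([0.2, 0.5, 0.7]),
                           np.zeros(3))
        lone_a = LdProfile(1, np.array([0, 2]), np.array([0.3, np.nan]), np.zeros(2))
        lone_b = LdProfile(1, np.array([0, 2]), np.array([0.6, np.nan]), np.zeros(2))
        w = gld_weights([good_a, lone_a], [good_b, lone_b])
        expected = np.corrcoef([0.1, 0.4, 0.8], [0.2, 0.5, 0.7])[0, 1]
        assert w[0] == pytest.approx(expected)
        assert w[1] == pytest.approx(max(expected, 0.0))  # global mean of raw weights

    def test_weights_decrease_with_divergence(self):
        """More divergence generations -> lower mean LD-consistency weight."""
        from multibreed import SimConfig, simulate_base_population, split_and_drift

        means = []
        for gens in (0, 8, 25):
            vals = []
            for seed in range(4):
                cfg = SimConfig(
                    n_base_haplotypes=300, n_markers=240, n_chromosomes=2,
                    base_generations=30, breed_sizes={"A": 75, "B": 75},
                    divergence_generations=gens, seed=700 + seed,
                )
                base = simulate_base_population(cfg)
                panel = split_and_drift(base, cfg)
                pa, pb = panel.select_breed("A"), panel.select_breed("B")
                wa = gld_weights(neighbor_profiles(pa, k=8),
                                 neighbor_profiles(pb, k=8))
                vals.append(wa.mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
        assert 0.0 < means[2] < 1.0
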
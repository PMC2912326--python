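"""EM haplotype-frequency estimation against a grid-search likelihood
oracle, closed-form R-squared checks, and hotspot flagging semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popflow.ld_hotspots import (
    EstimationError,
    HaplotypeFrequencies,
    em_haplotype_freqs,
    flag_hotspots,
    genotype_pair_table,
    loglik,
    pair_r2,
    r_squared,
    window_mean_r2,
)

from conftest import make_matrix


# ---------------------------------------------------------------- oracles
def profile_freqs(table, f_ab):
    """Haplotype frequencies with f_AB given and allele frequencies fixed
    at their observed (sufficient-statistic) values."""
    n = table.sum()
    p_a = (2 * table[0, :].sum() + table[1, :].sum()) / (2 * n)
    p_b = (2 * table[:, 0].sum() + table[:, 1].sum()) / (2 * n)
    return np.array([f_ab, p_a - f_ab, p_b - f_ab, 1 - p_a - p_b + f_ab])


def grid_search_loglik(table, step=0.001):
    """Best multinomial log-likelihood on a step-grid over f_AB.

    The marginal genotype counts pin the allele-frequency MLEs, so the
    maximisation reduces to this one-dimensional profile; validated
    against a full-simplex grid in
    ``test_profile_reduction_matches_full_simplex_grid``.
    """
    n = table.sum()
    p_a = (2 * table[0, :].sum() + table[1, :].sum()) / (2 * n)
    p_b = (2 * table[:, 0].sum() + table[:, 1].sum()) / (2 * n)
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    grid = np.arange(0.0, 1.0 + step, step)
    grid = grid[(grid >= lo - 1e-12) & (grid <= hi + 1e-12)]
    if grid.size == 0:
        grid = np.array([lo])
    return max(loglik(table, profile_freqs(table, g)) for g in grid)


def full_simplex_grid_loglik(table, step=0.05):
    """Exhaustive coarse grid over the whole haplotype-frequency simplex."""
    best = -np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for fab in ticks:
        for fAb in ticks:
            if fab + fAb > 1 + 1e-12:
                break
            for faB in ticks:
                rest = 1.0 - fab - fAb - faB
                if rest < -1e-12:
                    break
                f = np.array([fab, fAb, faB, max(rest, 0.0)])
                best = max(best, loglik(table, f))
    return best


def random_tables(seed, count, nmax=50):
    rng = np.random.default_rng(seed)
    for _ in range(count):
        hap = rng.dirichlet([1, 1, 1, 1])
        n = int(rng.integers(4, nmax + 1))
        draws = rng.choice(4, size=(n, 2), p=hap)
        tab = np.zeros((3, 3), dtype=int)
        for h1, h2 in draws:
            a = (h1 < 2) + (h2 < 2)
            b = (h1 % 2 == 0) + (h2 % 2 == 0)
            tab[2 - a, 2 - b] += 1
        yield tab


# ------------------------------------------------------------------- EM
class TestEm:
    def test_unambiguous_single_cell(self):
        tab = np.zeros((3, 3), int)
        tab[0, 0] = 10  # all AA,BB
        f = em_haplotype_freqs(tab)
        assert f.f_AB == pytest.approx(1.0, abs=1e-9)
        assert f.f_Ab + f.f_aB + f.f_ab == pytest.approx(0.0, abs=1e-9)

    def test_no_double_heterozygotes_is_exact_counting(self):
        tab = np.zeros((3, 3), int)
        tab[0, 0] = 5  # AA,BB -> AB haplotypes
        tab[2, 2] = 5  # aa,bb -> ab haplotypes
        f = em_haplotype_freqs(tab)
        assert f.f_AB == pytest.approx(0.5, abs=1e-9)
        assert f.f_ab == pytest.approx(0.5, abs=1e-9)
        assert f.f_Ab == pytest.approx(0.0, abs=1e-9)

    def test_mixed_table_matches_grid_oracle(self):
        tab = np.zeros((3, 3), int)
        tab[0, 0], tab[1, 1], tab[2, 2], tab[1, 0], tab[0, 1] = 2, 4, 2, 1, 1
        f = em_haplotype_freqs(tab)
        assert loglik(tab, f.as_array()) >= grid_search_loglik(tab) - 1e-4

    def test_em_attains_grid_likelihood_on_random_tables(self):
        for tab in random_tables(seed=202, count=60):
            f = em_haplotype_freqs(tab)
            assert loglik(tab, f.as_array()) >= grid_search_loglik(tab) - 1e-6

    def test_per_iteration_loglik_nondecreasing(self):
        for tab in random_tables(seed=7, count=40):
            traj: list[float] = []
            em_haplotype_freqs(tab, trajectory=traj)
            assert all(b >= a - 1e-9 for a, b in zip(traj, traj[1:]))

    def test_profile_reduction_matches_full_simplex_grid(self):
        # the 1-D profile over f_AB dominates every full-simplex point
        for tab in random_tables(seed=99, count=15, nmax=30):
            assert grid_search_loglik(tab) >= full_simplex_grid_loglik(tab) - 1e-9

    def test_empty_table_rejected(self):
        with pytest.raises(EstimationError):
            em_haplotype_freqs(np.zeros((3, 3), int))

    def test_frequencies_sum_to_one(self):
        for tab in random_tables(seed=55, count=20):
            f = em_haplotype_freqs(tab)
            assert f.as_array().sum() == pytest.approx(1.0, abs=1e-9)


# -------------------------------------------------------------- R-squared
class TestRSquared:
    def test_two_haplotype_system_perfect_ld(self):
        assert r_squared(HaplotypeFrequencies(0.5, 0, 0, 0.5)) == pytest.approx(1.0)

    def test_equilibrium_zero(self):
        assert r_squared(HaplotypeFrequencies(0.25, 0.25, 0.25, 0.25)) == pytest.approx(0.0)

    def test_worked_example(self):
        # D = 0.4 - 0.5*0.5 = 0.15; R2 = 0.0225 / 0.0625 = 0.36
        assert r_squared(HaplotypeFrequencies(0.4, 0.1, 0.1, 0.4)) == pytest.approx(0.36)

    def test_monomorphic_undefined(self):
        assert np.isnan(r_squared(HaplotypeFrequencies(0.7, 0.3, 0.0, 0.0)))

    @given(
        f=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        n=st.integers(20, 60),
    )
    @settings(max_examples=50, deadline=None)
    def test_r2_in_unit_interval_and_symmetric(self, f, n):
        hap = np.asarray(f) / np.sum(f)
        rng = np.random.default_rng(n)
        draws = rng.choice(4, size=(n, 2), p=hap)
        d1 = ((draws < 2).sum(axis=1)).astype(np.int8)
        d2 = ((draws % 2 == 0).sum(axis=1)).astype(np.int8)
        r2 = pair_r2(d1, d2)
        r2_swap = pair_r2(d2, d1)
        if not np.isnan(r2):
            assert 0.0 <= r2 <= 1.0 + 1e-9
            # agreement is limited by the EM stopping tolerance
            assert r2 == pytest.approx(r2_swap, abs=1e-6)
            # allele relabeling at locus 1 leaves R2 unchanged
            assert pair_r2((2 - d1).astype(np.int8), d2) == pytest.approx(r2, abs=1e-6)


# ------------------------------------------------------------- windowing
class TestWindows:
    def test_within_two_founder_block_mean_is_one(self):
        from popflow.synthetic_data import (
            SimulationConfig,
            draw_genotypes,
            simulate_block_haplotypes,
            simulate_frequencies,
        )

        cfg = SimulationConfig(
            n_pops=1, n_per_pop=100, n_markers=40, fst_per_pop=(0.1,),
            block_length=40, founder_haplotypes_per_block=2,
            founder_mutation_rate=0.0, missing_rate=0.0, seed=2,
        )
        pools = simulate_block_haplotypes(simulate_frequencies(cfg), cfg)
        mat = draw_genotypes(pools, cfg)
        mean = window_mean_r2(mat, 20, flank=5, population="POP1")
        assert mean == pytest.approx(1.0, abs=1e-6)

    def test_window_truncated_at_chromosome_end(self):
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.integers(0, 3, size=(40, 6)))
        # focal at the first marker: only right flank exists, no error
        mean = window_mean_r2(mat, 0, flank=10, population="POP1")
        assert np.isnan(mean) or 0.0 <= mean <= 1.0

    def test_monomorphic_focal_undefined(self):
        dosage = np.ones((10, 3), dtype=np.int8)
        dosage[:, 0] = 2  # focal monomorphic
        dosage[:5, 1] = 0
        dosage[:3, 2] = 2
        mat = make_matrix(dosage)
        assert np.isnan(window_mean_r2(mat, 0, flank=2, population="POP1"))


class TestFlagging:
    def test_single_two_founder_block_yields_no_hotspots(self):
        from popflow.synthetic_data import (
            SimulationConfig,
            draw_genotypes,
            simulate_block_haplotypes,
            simulate_frequencies,
        )

        cfg = SimulationConfig(
            n_pops=1, n_per_pop=150, n_markers=30, fst_per_pop=(0.1,),
            block_length=30, founder_haplotypes_per_block=2,
            founder_mutation_rate=0.0, missing_rate=0.0, seed=13,
        )
        pools = simulate_block_haplotypes(simulate_frequencies(cfg), cfg)
        mat = draw_genotypes(pools, cfg)
        scan = flag_hotspots(mat, flank=5, threshold=0.7)
        assert not any(r.is_hotspot for r in scan)

    def test_boundary_markers_flagged_interior_not(self, block_sim):
        mat = block_sim.matrix
        scan = flag_hotspots(mat, flank=25, threshold=0.7)
        flagged = np.array([r.is_hotspot for r in scan])
        boundaries = block_sim.pools.boundary_markers
        hits = np.flatnonzero(flagged)
        for b in boundaries:
            assert (np.abs(hits - b) <= 25).any()
        # interior: more than a flank away from any boundary
        near = np.zeros(mat.n_markers, dtype=bool)
        for b in boundaries:
            near[max(0, b - 25) : b + 26] = True
        assert flagged[~near].mean() <= 0.1

    def test_empty_population_list_rejected(self, block_sim):
        with pytest.raises(ValueError):
            flag_hotspots(block_sim.matrix, populations=[])

    def test_pair_table_pairwise_deletion(self):
        d1 = np.array([0, 1, 2, -1, 2], dtype=np.int8)
        d2 = np.array([2, 1, -1, 0, 0], dtype=np.int8)
        t = genotype_pair_table(d1, d2)
        assert t.sum() == 3  # two pairs dropped
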
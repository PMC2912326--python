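"""Regional-specific-marker selection: frequency arithmetic, the
hand-computed z-score oracle, the Samuelson bound on z, planted-marker
recovery at the 24-group design, and positional thinning."""

import numpy as np
import pandas as pd
import pytest

from popflow import rsm
from popflow.matrix import MISSING
from popflow.synthetic_data import PlantedMarker, SimulationConfig, simulate

from conftest import make_matrix


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "n11,n12,n22,expected",
        [(10, 0, 0, 1.0), (5, 4, 5, 0.5), (3, 4, 1, 0.625)],
    )
    def test_counting(self, n11, n12, n22, expected):
        assert rsm.allele_frequency(n11, n12, n22) == pytest.approx(expected)

    def test_no_calls_undefined(self):
        assert np.isnan(rsm.allele_frequency(0, 0, 0))


def ten_pop_outlier_matrix():
    """Nine populations at p = 0.5 exactly, one at p = 0.9, 50 samples
    each — the spreadsheet-style oracle gives z_outlier = 3.0 exactly:
    p_bar = 0.54, var_outlier = 0.36^2 = 0.1296, var_null = 0.04^2 =
    0.0016, mu = 0.0144, sigma = 0.0384."""
    cols = []
    pops = []
    null_pop = np.array([2] * 25 + [0] * 25, dtype=np.int8)  # p = 0.5
    outlier = np.array([2] * 40 + [1] * 10, dtype=np.int8)  # p = 0.9
    for k in range(9):
        cols.append(null_pop)
        pops += [f"P{k + 1}"] * 50
    cols.append(outlier)
    pops += ["P10"] * 50
    dosage = np.concatenate(cols)[:, None]
    return make_matrix(dosage, pops=pops), "P10"


class TestMarkerVariances:
    def test_identical_frequencies_give_zero_z(self):
        dosage = np.tile(
            np.array([2, 0] * 10, dtype=np.int8)[:, None], (1, 3)
        )
        pops = ["A"] * 10 + ["B"] * 10
        table = rsm.marker_variance_table(make_matrix(dosage, pops=pops), ["A", "B"])
        assert (table[["z_A", "z_B"]].to_numpy() == 0).all()

    def test_hand_computed_outlier_oracle(self):
        mat, outlier_pop = ten_pop_outlier_matrix()
        table = rsm.marker_variance_table(mat)
        row = table.iloc[0]
        assert row["p_bar"] == pytest.approx(0.54)
        assert row[f"var_{outlier_pop}"] == pytest.approx(0.1296)
        z = {p: row[f"z_{p}"] for p in mat.populations}
        assert z[outlier_pop] == pytest.approx(3.0, abs=1e-9)
        assert z[outlier_pop] > 2.9
        assert z[outlier_pop] == max(z.values())
        assert sum(v == z[outlier_pop] for v in z.values()) == 1

    def test_z_scores_sum_to_zero(self):
        mat, _ = ten_pop_outlier_matrix()
        table = rsm.marker_variance_table(mat)
        zs = [table.iloc[0][f"z_{p}"] for p in mat.populations]
        assert sum(zs) == pytest.approx(0.0, abs=1e-9)

    def test_doubling_sample_sizes_leaves_z_unchanged(self):
        mat, outlier_pop = ten_pop_outlier_matrix()
        doubled = make_matrix(
            np.concatenate([mat.dosage, mat.dosage]),
            pops=list(mat.pop_labels) * 2,
        )
        z1 = rsm.marker_variance_table(mat).iloc[0][f"z_{outlier_pop}"]
        z2 = rsm.marker_variance_table(doubled).iloc[0][f"z_{outlier_pop}"]
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_allele_label_swap_invariant(self):
        mat, outlier_pop = ten_pop_outlier_matrix()
        swapped = make_matrix((2 - mat.dosage).astype(np.int8), pops=list(mat.pop_labels))
        z1 = rsm.marker_variance_table(mat).iloc[0][f"z_{outlier_pop}"]
        z2 = rsm.marker_variance_table(swapped).iloc[0][f"z_{outlier_pop}"]
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_samuelson_bound_on_z(self):
        # with K populations and a denominator-K sigma, no |z| can exceed
        # sqrt(K-1); the 10-population fixture peaks at exactly 3
        mat, outlier_pop = ten_pop_outlier_matrix()
        table = rsm.marker_variance_table(mat)
        zcols = [c for c in table.columns if c.startswith("z_")]
        assert np.abs(table[zcols].to_numpy()).max() <= np.sqrt(9) + 1e-9

    def test_uncalled_population_excluded(self):
        dosage = np.array(
            [[2], [0], [1], [MISSING]], dtype=np.int8
        )
        pops = ["A", "A", "B", "C"]
        table = rsm.marker_variance_table(make_matrix(dosage, pops=pops))
        assert np.isnan(table.iloc[0]["p_C"])
        assert table.iloc[0]["n_pops_defined"] == 2
        assert not table.iloc[0]["usable"]


def planted_24_group_sim(seed=41, n_markers=400, n_planted=25):
    """Drifted 24-group cohort with one-population frequency outliers
    planted at +/-0.4, mirroring a worldwide regional-group design."""
    rng = np.random.default_rng(seed)
    plant_at = rng.choice(n_markers, size=n_planted, replace=False)
    cfg0 = SimulationConfig(
        n_pops=24, n_per_pop=50, n_markers=n_markers,
        fst_per_pop=[0.01] * 24,
        founder_haplotypes_per_block=None, block_length=1,
        missing_rate=0.0, seed=seed,
    )
    from popflow.synthetic_data import simulate_frequencies

    anc = simulate_frequencies(cfg0).ancestral
    planted = [
        PlantedMarker(int(i), f"POP{(k % 24) + 1}", 0.4 if anc[i] <= 0.55 else -0.4)
        for k, i in enumerate(plant_at)
    ]
    cfg = SimulationConfig(
        n_pops=24, n_per_pop=50, n_markers=n_markers,
        fst_per_pop=[0.01] * 24,
        founder_haplotypes_per_block=None, block_length=1,
        missing_rate=0.0, planted_markers=planted, seed=seed,
    )
    return simulate(cfg), set(int(i) for i in plant_at)


class TestSelection:
    def test_default_threshold_is_four(self):
        assert rsm.DEFAULT_Z_THRESHOLD == 4.0

    def test_planted_markers_recovered_at_24_groups(self):
        sim, plant_at = planted_24_group_sim()
        table = rsm.select_rsm(rsm.marker_variance_table(sim.matrix), 4.0)
        selected = set(np.flatnonzero(table["selected"].to_numpy()))
        sens = len(selected & plant_at) / len(plant_at)
        assert sens >= 0.9

    def test_null_selection_rate_below_one_percent(self):
        cfg = SimulationConfig(
            n_pops=10, n_per_pop=50, n_markers=5000,
            fst_per_pop=[1e-6] * 10,
            founder_haplotypes_per_block=None, block_length=1,
            missing_rate=0.0, seed=77,
        )
        sim = simulate(cfg)
        table = rsm.select_rsm(rsm.marker_variance_table(sim.matrix), 4.0)
        assert table["selected"].mean() < 0.01


class TestThinning:
    def base(self, positions, selected=None, chrom=None):
        n = len(positions)
        df = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(n)],
                "chrom": chrom or ["1"] * n,
                "pos_bp": positions,
                "selected": selected if selected is not None else [True] * n,
            }
        )
        return df

    def test_single_marker_kept(self):
        out = rsm.thin_by_distance(self.base([100_000]))
        assert out["retained_after_thinning"].tolist() == [True]

    def test_run_collapse_worked_example(self):
        out = rsm.thin_by_distance(self.base([100_000, 400_000, 1_200_000]))
        assert out["retained_after_thinning"].tolist() == [True, False, True]

    def test_chromosomes_never_thin_each_other(self):
        out = rsm.thin_by_distance(
            self.base([100_000, 150_000], chrom=["1", "2"])
        )
        assert out["retained_after_thinning"].tolist() == [True, True]

    def test_unsorted_input_rejected(self):
        with pytest.raises(rsm.RsmError):
            rsm.thin_by_distance(self.base([500_000, 100_000]))

    def test_retained_subset_of_selected_with_gaps(self):
        rng = np.random.default_rng(12)
        pos = np.sort(rng.choice(10_000_000, size=60, replace=False))
        sel = rng.random(60) < 0.5
        out = rsm.thin_by_distance(self.base(list(pos), selected=list(sel)))
        kept = out[out["retained_after_thinning"]]
        assert kept["selected"].all()
        # no two retained markers within the same maximal run: every
        # retained marker starts a run, so consecutive retained markers
        # are separated by a gap > 500 kb between *selected* neighbours
        sel_pos = out.loc[out["selected"], "pos_bp"].to_numpy()
        kept_pos = kept["pos_bp"].to_numpy()
        for a, b in zip(kept_pos, kept_pos[1:]):
            between = sel_pos[(sel_pos >= a) & (sel_pos <= b)]
            gaps = np.diff(between)
            assert (gaps > 500_000).any()
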
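"""Layer clustering, subset assignment and morphology metrics."""

import numpy as np
import pandas as pd
import pytest

from dualpath import synthgen
from dualpath.layers import (
    CellMap,
    Morphology,
    assign_layers,
    colocalization,
    fit_layer_gmm,
    intensity_profile,
    morph_metrics,
    sholl_from_reference,
    subset_layer_fractions,
)
from dualpath.synthgen import SynthCellMapConfig, gen_cellmap


def _local_maxima(profile: np.ndarray) -> int:
    # brute-force peak count on the smoothed histogram
    return int(np.sum((profile[1:-1] > profile[:-2]) & (profile[1:-1] > profile[2:])))


class TestIntensityProfile:
    def test_peak_normalized(self, default_cellmap):
        cm, _ = default_cellmap
        prof = intensity_profile(cm)["intensity"].to_numpy()
        assert prof.max() == 1.0

    def test_two_radial_peaks_on_default_generator(self, default_cellmap):
        cm, _ = default_cellmap
        prof = intensity_profile(cm, axis="radial")["intensity"].to_numpy()
        assert _local_maxima(prof) == 2

    def test_peaks_near_radial_extremes(self):
        cfg = SynthCellMapConfig(
            n_cells=2000, component_means=((0.15, 0.5), (0.85, 0.5)), seed=2
        )
        cm, _ = gen_cellmap(cfg)
        df = intensity_profile(cm, axis="radial")
        prof = df["intensity"].to_numpy()
        pos = df["position"].to_numpy()
        peaks = pos[1:-1][(prof[1:-1] > prof[:-2]) & (prof[1:-1] > prof[2:])]
        assert np.any(np.abs(peaks - 0.15) < 0.08)
        assert np.any(np.abs(peaks - 0.85) < 0.08)

    def test_empty_map_rejected(self):
        cm = CellMap(cells=pd.DataFrame({"radial": [], "longitudinal": []}))
        with pytest.raises(ValueError, match="empty"):
            intensity_profile(cm)


class TestFitLayerGMM:
    def test_single_tight_gaussian_selects_k1(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SynthCellMapConfig(
                n_cells=500,
                component_means=((0.5, 0.5),),
                component_sds=((0.02, 0.02),),
                component_weights=(1.0,),
                subset_rules={"ctxb": (1.0,)},
                seed=seed,
            )
            cm, _ = gen_cellmap(cfg)
            model = fit_layer_gmm(cm, n_init=3, seed=seed)
            hits += model.selected_k == 1
        assert hits >= 27  # >= 90% (spec simulation oracle says >= 95/100)

    def test_default_two_layer_generator_selects_k2(self, default_cellmap):
        cm, _ = default_cellmap
        model = fit_layer_gmm(cm, seed=0)
        assert model.selected_k == 2
        assert model.bics[2] == min(
            b for k, b in model.bics.items() if model.converged[k]
        )

    def test_three_separated_components_select_k3(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SynthCellMapConfig(
                n_cells=600,
                component_means=((0.1, 0.5), (0.5, 0.5), (0.9, 0.5)),
                component_sds=((0.04, 0.1), (0.04, 0.1), (0.04, 0.1)),
                component_weights=(1 / 3, 1 / 3, 1 / 3),
                subset_rules={"ctxb": (1.0, 1.0, 1.0)},
                seed=seed,
            )
            cm, _ = gen_cellmap(cfg)
            model = fit_layer_gmm(cm, n_init=3, seed=seed)
            hits += model.selected_k == 3
        assert hits >= 27

    def test_too_few_cells_rejected(self):
        cm, _ = gen_cellmap(SynthCellMapConfig(n_cells=5, seed=0))
        with pytest.raises(ValueError, match="at least"):
            fit_layer_gmm(cm)


class TestAssignLayers:
    def test_cell_at_component_mean_has_high_posterior(self, default_cellmap):
        cm, _ = default_cellmap
        model = fit_layer_gmm(cm, seed=0)
        means = model.selected.means_
        probe = CellMap(
            cells=pd.DataFrame(
                {"radial": means[:, 0], "longitudinal": means[:, 1]}
            )
        )
        out = assign_layers(model, probe)
        assert (out["posterior"] > 0.5).all()
        assert list(out["component"]) == [0, 1]

    def test_assignment_accuracy_vs_truth(self):
        cfg = SynthCellMapConfig(n_cells=1000, seed=21)  # ~11 SD radial separation
        cm, truth = gen_cellmap(cfg)
        model = fit_layer_gmm(cm, seed=0)
        out = assign_layers(model, cm)
        # ground-truth component 0 has radial mean 0.15 -> deep
        truth_names = np.where(truth.layer_labels == 0, "deep", "superficial")
        accuracy = (out["layer"].to_numpy() == truth_names).mean()
        assert accuracy >= 0.95

    def test_deep_is_component_nearest_alveus(self, default_cellmap):
        cm, _ = default_cellmap
        model = fit_layer_gmm(cm, seed=0)
        out = assign_layers(model, cm)
        assert out.loc[out["layer"] == "deep", "radial"].mean() < \
            out.loc[out["layer"] == "superficial", "radial"].mean()

    def test_posteriors_sum_to_one(self, default_cellmap):
        cm, _ = default_cellmap
        model = fit_layer_gmm(cm, seed=0)
        resp = model.selected.predict_proba(cm.coords)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)

    def test_k_not_2_rejects_layer_names(self):
        cfg = SynthCellMapConfig(
            n_cells=500, component_means=((0.5, 0.5),), component_sds=((0.02, 0.02),),
            component_weights=(1.0,), subset_rules={"ctxb": (1.0,)}, seed=0,
        )
        cm, _ = gen_cellmap(cfg)
        model = fit_layer_gmm(cm, n_init=3, seed=0)
        assert model.selected_k == 1
        with pytest.raises(ValueError, match="k = 2"):
            assign_layers(model, cm, use_names=True)
        out = assign_layers(model, cm, use_names=False)
        assert "component" in out.columns and "layer" not in out.columns


class TestSubsetFractions:
    def _assignments(self, seed=13, n=2000, rules=None):
        rules = rules or {"ctxb": (1.0, 1.0), "rabies": (0.8, 0.2)}
        cfg = SynthCellMapConfig(n_cells=n, subset_rules=rules, seed=seed)
        cm, truth = gen_cellmap(cfg)
        model = fit_layer_gmm(cm, seed=0)
        return assign_layers(model, cm), truth

    def test_fractions_sum_to_one(self):
        out, _ = self._assignments()
        frac = subset_layer_fractions(out, "rabies")["pooled"]
        assert abs(frac.sum() - 1.0) < 1e-12

    def test_all_superficial_gives_fraction_one(self):
        df = pd.DataFrame(
            {"radial": [0.9, 0.85], "longitudinal": [0.5, 0.5],
             "flagx": [True, True], "layer": ["superficial", "superficial"]}
        )
        frac = subset_layer_fractions(df, "flagx")["pooled"]
        assert frac["superficial"] == 1.0

    def test_deep_rule_recovered_binomially(self):
        out, _ = self._assignments()
        frac = subset_layer_fractions(out, "rabies")["pooled"]
        n_flagged = int(out["rabies"].sum())
        se = np.sqrt(0.8 * 0.2 / n_flagged)
        # extra slack for component-count variance on top of the binomial SE
        assert abs(frac["deep"] - 0.8) < 3 * se + 0.02

    def test_no_flagged_cells_warns_nan(self):
        df = pd.DataFrame(
            {"radial": [0.2], "longitudinal": [0.5], "flagx": [False], "layer": ["deep"]}
        )
        with pytest.warns(UserWarning):
            frac = subset_layer_fractions(df, "flagx")["pooled"]
        assert frac.isna().all()


class TestColocalization:
    def _df(self, a, b, layers=None):
        n = len(a)
        df = pd.DataFrame(
            {"radial": np.linspace(0.1, 0.9, n), "longitudinal": 0.5,
             "A": a, "B": b}
        )
        if layers is not None:
            df["layer"] = layers
        return df

    def test_disjoint_flags(self):
        df = self._df([True, False] * 10, [False, True] * 10)
        out = colocalization(CellMap(cells=df), "A", "B")
        assert out["dual_over_union"] == 0.0

    def test_identical_flags(self):
        df = self._df([True] * 10, [True] * 10)
        out = colocalization(CellMap(cells=df), "A", "B")
        assert out["dual_over_union"] == 1.0

    def test_generator_dual_rate_and_deep_share(self):
        # per-component independent flags: deep dual rate 0.5*0.4=0.2,
        # superficial 0.25*0.2=0.05 -> 80% of duals deep at equal weights
        cfg = SynthCellMapConfig(
            n_cells=4000,
            subset_rules={"A": (0.5, 0.25), "B": (0.4, 0.2)},
            seed=8,
        )
        cm, truth = gen_cellmap(cfg)
        model = fit_layer_gmm(cm, seed=0)
        out = colocalization(cm, "A", "B", assignments=assign_layers(model, cm))
        dual = cm.cells["A"] & cm.cells["B"]
        n_dual = int(dual.sum())
        deep_share = out["dual_layer_split"]["deep"]
        se = np.sqrt(0.8 * 0.2 / n_dual)
        assert abs(deep_share - 0.8) < 3 * se + 0.02
        # overall dual rate: expectation 0.125 of all cells
        se_rate = np.sqrt(0.125 * 0.875 / len(cm))
        assert abs(n_dual / len(cm) - 0.125) < 3 * se_rate

    def test_empty_union_nan(self):
        df = self._df([False] * 4, [False] * 4)
        out = colocalization(CellMap(cells=df), "A", "B")
        assert np.isnan(out["dual_over_union"])


def _swc(rows, reference=((0.0, 0.0), (1.0, 0.0))):
    df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    return Morphology(nodes=df, reference_line=reference)


class TestSholl:
    def test_perpendicular_dendrite_uniform_bins(self):
        rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
        rows += [(i + 2, 4, 0.0, 10.0 * (i + 1), 0.0, 1.0, i + 1) for i in range(10)]
        out = sholl_from_reference(_swc(rows), bin_width=10.0)
        np.testing.assert_allclose(out["apical"].to_numpy(), 10.0)
        assert len(out) == 10

    def test_parallel_dendrite_single_bin(self):
        d = 42.0
        rows = [(1, 1, 0.0, d, 0.0, 5.0, -1)]
        rows += [(i + 2, 3, 10.0 * (i + 1), d, 0.0, 1.0, i + 1) for i in range(5)]
        out = sholl_from_reference(_swc(rows), bin_width=10.0)
        basal = out["basal"].to_numpy()
        bin_of_d = int(d // 10.0)
        assert basal[bin_of_d] == 50.0
        assert basal.sum() == 50.0

    def test_branched_tree_manual_oracle(self):
        # soma at y=0; trunk to y=20 (len 20, midpoints 5, 15);
        # branch A to (30, 20) (len 30, midpoint y=20); branch B to (0, 50) (len 30, mids 25,45... )
        rows = [
            (1, 1, 0.0, 0.0, 0.0, 5.0, -1),
            (2, 4, 0.0, 20.0, 0.0, 1.0, 1),   # len 20, mid y=10 -> bin 1
            (3, 4, 30.0, 20.0, 0.0, 1.0, 2),  # len 30, mid y=20 -> bin 2
            (4, 4, 0.0, 50.0, 0.0, 1.0, 2),   # len 30, mid y=35 -> bin 3
        ]
        out = sholl_from_reference(_swc(rows), bin_width=10.0)
        apical = out["apical"].to_numpy()
        assert apical[1] == 20.0
        assert apical[2] == 30.0
        assert apical[3] == 30.0

    def test_conservation_of_total_length(self):
        rng = np.random.default_rng(5)
        rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
        total = 0.0
        pos = {1: np.zeros(3)}
        for i in range(2, 40):
            parent = int(rng.integers(1, i))
            step = rng.normal(size=3) * 5
            pos[i] = pos[parent] + step
            total += float(np.linalg.norm(step))
            rows.append((i, 4 if rng.random() < 0.5 else 3, *pos[i], 1.0, parent))
        out = sholl_from_reference(_swc(rows), bin_width=7.0)
        assert abs(out[["apical", "basal"]].to_numpy().sum() - total) < 1e-6

    def test_missing_reference_rejected(self):
        rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1), (2, 4, 0.0, 10.0, 0.0, 1.0, 1)]
        morph = _swc(rows, reference=None)
        with pytest.raises(ValueError, match="reference"):
            sholl_from_reference(morph)


class TestMorphMetrics:
    def test_farthest_tip(self):
        rows = [
            (1, 1, 0.0, 0.0, 0.0, 5.0, -1),
            (2, 4, 0.0, 120.0, 0.0, 1.0, 1),
            (3, 3, 0.0, -80.0, 0.0, 1.0, 1),
        ]
        m = morph_metrics(_swc(rows))
        assert m["farthest_tip_um"] == 120.0

    def test_unbranched_apical_nan_bifurcation(self):
        rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1), (2, 4, 0.0, 100.0, 0.0, 1.0, 1)]
        m = morph_metrics(_swc(rows))
        assert np.isnan(m["apical_bifurcation_um"])
        assert not m["has_apical_bifurcation"]

    def test_bifurcation_path_distance(self):
        # soma -> 30 up -> 15 up (bifurcation at path length 45) -> two children
        rows = [
            (1, 1, 0.0, 0.0, 0.0, 5.0, -1),
            (2, 4, 0.0, 30.0, 0.0, 1.0, 1),
            (3, 4, 0.0, 45.0, 0.0, 1.0, 2),
            (4, 4, 20.0, 60.0, 0.0, 1.0, 3),
            (5, 4, -20.0, 60.0, 0.0, 1.0, 3),
        ]
        m = morph_metrics(_swc(rows))
        assert abs(m["apical_bifurcation_um"] - 45.0) < 1e-9


class TestCellMapValidation:
    def test_out_of_range_coordinate_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            CellMap(cells=pd.DataFrame({"radial": [1.2], "longitudinal": [0.5]}))

    def test_missing_flag_column_rejected(self):
        with pytest.raises(ValueError, match="tracer"):
            CellMap(
                cells=pd.DataFrame({"radial": [0.5], "longitudinal": [0.5]}),
                tracer_flags=("rabies",),
            )
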
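import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from spatialtma.errors import ConfigurationError, GenerationError, NoEventsError
from spatialtma.synth import (
    AttractionSpec,
    CellTypeSpec,
    CoreSpec,
    NestSpec,
    SurvivalSpec,
    SynthConfig,
    default_cell_types,
    generate_cohort,
    place_core,
    simulate_outcomes,
)


def _core_spec(counts, attractions=(), nest=None, group="NR"):
    return CoreSpec(
        sample_id="s0",
        counts=counts,
        group=group,
        nest_spec=nest or NestSpec(),
        attractions=list(attractions),
        hotspot=None,
        core_radius_um=500.0,
        margin_distance_um=30.0,
    )


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        types = [
            CellTypeSpec("Treg", ("CD45",), 0.5, 0.5),
            CellTypeSpec("Monocyte", ("CD14",), 0.4, 0.4),
        ]
        with pytest.raises(ConfigurationError, match="sum"):
            SynthConfig(cell_types=types)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(n_cores=0)
        with pytest.raises(ConfigurationError):
            SynthConfig(cells_per_core=-5)

    def test_nest_radius_must_fit_core(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(nest_spec=NestSpec(radius_um=600.0))

    def test_packing_infeasible(self):
        with pytest.raises(GenerationError, match="packing"):
            SynthConfig(cells_per_core=500_000)

    def test_scaled_defaults_renormalize(self):
        types = default_cell_types(scale={"Treg": (1.0, 2.0)})
        for attr in ("prop_r", "prop_nr"):
            assert sum(getattr(t, attr) for t in types) == pytest.approx(1.0)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        paths = []
        for run in range(2):
            cells, clinical, _ = generate_cohort(
                SynthConfig(n_cores=3, cells_per_core=300, seed=42)
            )
            p = tmp_path / f"run{run}.csv"
            cells.to_csv(p, index=False)
            clinical.to_csv(tmp_path / f"clin{run}.csv", index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "clin0.csv").read_bytes() == (
            tmp_path / "clin1.csv"
        ).read_bytes()

    def test_different_seed_differs(self):
        a, _, _ = generate_cohort(SynthConfig(n_cores=2, cells_per_core=200, seed=1))
        b, _, _ = generate_cohort(SynthConfig(n_cores=2, cells_per_core=200, seed=2))
        assert not a.equals(b)


class TestPlaceCore:
    def test_single_nest_full_tumour_fraction(self):
        rng = np.random.default_rng(0)
        spec = _core_spec(
            {"Tumour HLADR": 200, "Stroma": 100},
            nest=NestSpec(n_nests=1, radius_um=100.0, tumour_fraction=1.0),
        )
        out = place_core(spec, rng)
        tum = out[out["true_type"] == "Tumour HLADR"]
        xy = tum[["x_um", "y_um"]].to_numpy()
        # all tumour cells lie in one disc of radius 100 -> max pairwise
        # distance bounded by the diameter
        assert cdist(xy, xy).max() <= 200.0 + 1e-9
        assert (tum["true_compartment"] == "tumour").all()

    def test_attraction_strength_one_guarantees_satellite(self):
        rng = np.random.default_rng(1)
        att = AttractionSpec("Treg", "Monocyte", 20.0, strength_nr=1.0)
        spec = _core_spec({"Treg": 50, "Monocyte": 100, "Stroma": 200}, [att])
        out = place_core(spec, rng)
        tregs = out[out["true_type"] == "Treg"][["x_um", "y_um"]].to_numpy()
        monos = out[out["true_type"] == "Monocyte"][["x_um", "y_um"]].to_numpy()
        nearest = cdist(tregs, monos).min(axis=1)
        assert (nearest <= 20.0 + 1e-9).all()

    def test_attraction_strength_half_binomial(self):
        # fraction of anchors with a satellite ~ strength + background,
        # within 3 SE over 20 replicates (binomial oracle)
        strength = 0.5
        fractions, backgrounds = [], []
        rng = np.random.default_rng(7)
        for _ in range(20):
            att = AttractionSpec("Treg", "Monocyte", 20.0, strength_nr=strength)
            for strengths, sink in ((att, fractions), (None, backgrounds)):
                spec = _core_spec(
                    {"Treg": 200, "Monocyte": 400, "Stroma": 400},
                    [strengths] if strengths else [],
                )
                out = place_core(spec, rng)
                tregs = out[out["true_type"] == "Treg"][["x_um", "y_um"]].to_numpy()
                monos = out[out["true_type"] == "Monocyte"][["x_um", "y_um"]].to_numpy()
                frac = float((cdist(tregs, monos).min(axis=1) <= 20.0).mean())
                sink.append(frac)
        n_total = 200 * 20
        se = np.sqrt(strength * (1 - strength) / n_total) + np.std(backgrounds) / np.sqrt(20)
        observed_extra = np.mean(fractions) - np.mean(backgrounds)
        # planted satellites can coincide with background hits -> slight shrink
        expected_extra = strength * (1 - np.mean(backgrounds))
        assert abs(observed_extra - expected_extra) <= 3 * se + 0.02

    def test_nest_radius_too_large_raises(self):
        rng = np.random.default_rng(0)
        spec = _core_spec(
            {"Stroma": 10}, nest=NestSpec(n_nests=1, radius_um=600.0)
        )
        with pytest.raises(GenerationError):
            place_core(spec, rng)


class TestGroundTruth:
    def test_every_cell_has_type_and_compartment(self, small_cohort):
        cells, _, truth = small_cohort
        assert truth.cells["true_type"].notna().all()
        assert set(truth.cells["true_compartment"]) <= {"tumour", "margin", "stroma"}
        assert len(truth.cells) == len(cells)
        assert truth.cells["cell_id"].is_unique

    def test_coordinates_inside_core_disc(self, small_cohort):
        cells, _, _ = small_cohort
        r = np.hypot(cells["x_um"], cells["y_um"])
        assert (r <= 500.0 + 1e-6).all()

    def test_planted_double_treg_composition(self):
        cells, _, truth = generate_cohort(
            SynthConfig(
                n_cores=16,
                cells_per_core=3000,
                cell_types=default_cell_types(scale={"Treg": (1.0, 2.0)}),
                include_intensities=False,
                seed=5,
            )
        )
        props = (
            cells.groupby("sample_id")["true_type"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)["Treg"]
        )
        groups = truth.response
        log2fc = np.log2(
            props[groups == "NR"].mean() / props[groups == "R"].mean()
        )
        assert 0.75 <= log2fc <= 1.25


class TestSimulateOutcomes:
    def _features(self, n, rng):
        return pd.DataFrame(
            {"f": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)]
        )

    def test_all_censored_and_no_events_error(self):
        rng = np.random.default_rng(0)
        spec = SurvivalSpec(censor_prob=1.0)
        clin = simulate_outcomes(self._features(30, rng), spec, rng)
        assert (clin["event"] == 0).all()
        from spatialtma.outcomes import cox_continuous

        clin["response"] = "R"
        feat = pd.Series(
            rng.normal(size=30), index=clin["sample_id"], name="f"
        )
        with pytest.raises(NoEventsError):
            cox_continuous(feat, clin)

    def test_null_logrank_calibrated(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(3)
        spec = SurvivalSpec(censor_prob=0.2, coefs={})
        hits = 0
        reps = 40
        for _ in range(reps):
            feats = self._features(60, rng)
            clin = simulate_outcomes(feats, spec, rng)
            split = feats["f"].to_numpy() <= np.median(feats["f"])
            lr = logrank_test(
                clin.loc[split, "os_days"],
                clin.loc[~split, "os_days"],
                clin.loc[split, "event"],
                clin.loc[~split, "event"],
            )
            hits += lr.p_value < 0.05
        assert hits / reps <= 0.2  # ~alpha under the null

    def test_negative_hazard_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError):
            simulate_outcomes(
                self._features(5, rng), SurvivalSpec(baseline_hazard=-1.0), rng
            )

    def test_positive_times(self):
        rng = np.random.default_rng(0)
        clin = simulate_outcomes(self._features(100, rng), SurvivalSpec(), rng)
        assert (clin["os_days"] > 0).all()
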
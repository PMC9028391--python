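"""Generator contracts: templates, pixels, nodules and cohort designs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from thyromsi.errors import ParameterError
from thyromsi.model import MZ_RANGE, default_mz_grid
from thyromsi.synthetic import (
    CELLULARITY_BANDS,
    ClassTemplate,
    CohortConfig,
    NoiseModel,
    cohort_design,
    iter_cohort,
    make_class_templates,
    simulate_cohort,
    simulate_nodule,
    simulate_pixel,
)


class TestClassTemplates:
    def test_construction_contract(self):
        t = make_class_templates(rng_seed=1, n_peaks_per_class=10, shared_peak_fraction=0.3)
        assert set(t) == {"HP", "HT", "PTC"}
        sets = {lab: set(np.round(tt.peak_mzs, 6)) for lab, tt in t.items()}
        for lab, tt in t.items():
            assert tt.n_peaks == 10
            assert np.all(np.diff(tt.peak_mzs) > 0)
            assert np.all(tt.peak_heights > 0)
            assert MZ_RANGE[0] <= tt.peak_mzs[0] and tt.peak_mzs[-1] <= MZ_RANGE[1]
            others = set().union(*(s for k, s in sets.items() if k != lab))
            assert sets[lab] - others, f"{lab} has no unique peak"

    def test_benign_classes_share_more_with_each_other_than_with_ptc(self):
        t = make_class_templates(rng_seed=2, n_peaks_per_class=10, shared_peak_fraction=0.4)
        sets = {lab: set(np.round(tt.peak_mzs, 6)) for lab, tt in t.items()}
        assert len(sets["HP"] & sets["HT"]) > len(sets["HP"] & sets["PTC"])
        assert len(sets["HP"] & sets["HT"]) > len(sets["HT"] & sets["PTC"])

    def test_deterministic_given_seed(self):
        a = make_class_templates(3, 8, 0.25)
        b = make_class_templates(3, 8, 0.25)
        for lab in a:
            assert np.array_equal(a[lab].peak_mzs, b[lab].peak_mzs)
            assert np.array_equal(a[lab].peak_heights, b[lab].peak_heights)

    def test_disjoint_when_no_sharing(self):
        t = make_class_templates(rng_seed=4, n_peaks_per_class=6, shared_peak_fraction=0.0)
        sets = [set(np.round(tt.peak_mzs, 6)) for tt in t.values()]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_shared_fraction_rejected(self, bad):
        with pytest.raises(ParameterError):
            make_class_templates(1, 10, bad)

    def test_template_invariants_enforced(self):
        with pytest.raises(ParameterError):
            ClassTemplate("HP", [5000.0, 4000.0], [1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ParameterError):
            ClassTemplate("HP", [5000.0], [-1.0], [2.0])
        with pytest.raises(ParameterError):
            ClassTemplate("HP", [500.0], [1.0], [2.0])  # below range


class TestSimulatePixel:
    def test_noiseless_pixel_is_pure_gaussian_mixture(self, grid_3da):
        grid = default_mz_grid(1.0)
        t = ClassTemplate(
            "PTC", [5000.0, 7000.0, 9000.0], [10.0, 20.0, 30.0], [2.0, 2.8, 3.6]
        )
        rng = np.random.default_rng(0)
        spec = simulate_pixel(t, NoiseModel.noiseless(), grid, rng)
        assert np.all(spec.intensity >= 0)
        for mu, h in zip(t.peak_mzs, t.peak_heights):
            i = int(np.searchsorted(grid, mu))
            assert abs(spec.intensity[i] - h) < 1e-9  # grid hits the apex

    def test_full_dropout_leaves_baseline_only(self, grid_3da):
        t = ClassTemplate("HP", [5000.0], [10.0], [2.0])
        noise = NoiseModel(baseline_amplitude=5.0, baseline_decay=1e-4,
                           additive_noise_sd=0.0, intensity_jitter_cv=0.0, dropout_prob=1.0)
        spec = simulate_pixel(t, noise, grid_3da, np.random.default_rng(0))
        expected = 5.0 * np.exp(-1e-4 * (grid_3da - grid_3da[0]))
        np.testing.assert_allclose(spec.intensity, expected, rtol=1e-12)

    def test_empty_grid_rejected(self):
        t = ClassTemplate("HP", [5000.0], [10.0], [2.0])
        with pytest.raises(ParameterError):
            simulate_pixel(t, NoiseModel.noiseless(), np.array([]), np.random.default_rng(0))

    def test_replicate_mean_converges_to_noiseless_plus_noise_mean(self):
        # additive noise is half-normal per point: mean sd/sqrt(2*pi)
        grid = default_mz_grid(20.0)
        t = ClassTemplate("HP", [5000.0, 9000.0], [30.0, 50.0], [40.0, 40.0])
        sd = 4.0
        noise = NoiseModel(0.0, 0.0, sd, 0.0, 0.0)
        rng = np.random.default_rng(42)
        n_rep = 1000
        acc = np.zeros_like(grid)
        for _ in range(n_rep):
            acc += simulate_pixel(t, noise, grid, rng).intensity
        mean = acc / n_rep
        expected = t.signal_on_grid(grid) + sd / np.sqrt(2 * np.pi)
        se = np.sqrt(sd**2 * (0.5 - 1 / (2 * np.pi)) / n_rep)
        # pointwise within 5 SE, grand mean within 3 SE
        assert np.all(np.abs(mean - expected) < 5 * se)
        grand = np.abs((mean - expected).mean())
        assert grand < 3 * se / np.sqrt(grid.size)  # 3 SE of the grand mean


class TestSimulateNodule:
    def config(self, **kw):
        base = dict(pixels_per_nodule=100, rois_per_nodule=3, mz_step=10.0,
                    noise=NoiseModel.noiseless(), rng_seed=9)
        base.update(kw)
        return CohortConfig(**base)

    def test_pure_ptc_optimal_has_70pct_informative_all_ptc(self, templates_disjoint):
        cfg = self.config()
        s = simulate_nodule("malignant", {"PTC": 1.0}, cfg, np.random.default_rng(1),
                            templates=templates_disjoint, cellularity="optimal")
        classes = list(s.pixel_classes.values())
        n_inf = sum(c is not None for c in classes)
        assert n_inf >= 0.70 * len(classes)
        assert all(c == "PTC" for c in classes if c is not None)

    def test_pure_hp_nodule_has_zero_ptc_pixels(self, templates_disjoint):
        cfg = self.config()
        s = simulate_nodule("benign", {"HP": 1.0}, cfg, np.random.default_rng(2),
                            templates=templates_disjoint)
        assert s.n_pixels == 100
        assert all(c in ("HP", None) for c in s.pixel_classes.values())

    def test_composition_conservation_within_rounding(self, templates_disjoint):
        cfg = self.config(pixels_per_nodule=200)
        comp = {"HP": 0.6, "HT": 0.25, "PTC": 0.15}
        s = simulate_nodule("benign", comp, cfg, np.random.default_rng(3),
                            templates=templates_disjoint, cellularity="optimal")
        classes = [c for c in s.pixel_classes.values() if c is not None]
        n_inf = len(classes)
        for lab, f in comp.items():
            assert abs(sum(c == lab for c in classes) - f * n_inf) <= 1

    def test_bad_composition_rejected(self, templates_disjoint):
        cfg = self.config()
        with pytest.raises(ParameterError):
            simulate_nodule("benign", {"HP": 0.5, "PTC": 0.4}, cfg,
                            np.random.default_rng(0), templates=templates_disjoint)

    def test_rois_are_single_class_and_nonoverlapping(self, templates_disjoint):
        cfg = self.config(pixels_per_nodule=144, rois_per_nodule=4)
        s = simulate_nodule("malignant", {"HP": 0.5, "PTC": 0.5}, cfg,
                            np.random.default_rng(4), templates=templates_disjoint,
                            cellularity="optimal")
        assert s.rois  # NoduleSample construction already validated non-overlap
        for roi in s.rois:
            labels = {s.pixel_classes[p] for p in roi.pixels}
            assert labels == {roi.label}

    def test_cellularity_band_respected(self, templates_disjoint):
        for grade, (lo, hi) in CELLULARITY_BANDS.items():
            cfg = self.config()
            s = simulate_nodule("benign", {"HP": 1.0}, cfg, np.random.default_rng(5),
                                templates=templates_disjoint, cellularity=grade)
            frac = sum(c is not None for c in s.pixel_classes.values()) / s.n_pixels
            assert lo - 0.01 <= frac <= hi + 0.01


class TestCohortDesign:
    def test_training_counts_match_study_design(self):
        design = cohort_design(CohortConfig())
        df = design.to_frame()
        tr = df[df.dataset == "training"]
        assert len(tr) == 70
        assert (tr.subtype == "HP").sum() == 40
        assert (tr.subtype == "HT").sum() == 10
        assert (tr.subtype == "PTC").sum() == 20
        assert set(tr[tr.truth_label == "benign"].cytology_class) == {"TIR2"}
        assert (tr.truth_label == "benign").sum() == 50

    def test_validation_counts_match_study_design(self):
        df = cohort_design(CohortConfig()).to_frame()
        va = df[df.dataset == "validation"]
        assert len(va) == 170
        counts = va.cytology_class.value_counts()
        assert counts["TIR2"] == 33 and counts["TIR3"] == 77
        assert counts["TIR4"] == 19 and counts["TIR5"] == 41
        assert (va.truth_label == "malignant").sum() == 65

    def test_manifest_reproducible(self, tmp_path):
        a = cohort_design(CohortConfig(rng_seed=1)).to_frame().to_csv(index=False)
        b = cohort_design(CohortConfig(rng_seed=1)).to_frame().to_csv(index=False)
        assert a == b

    def test_simulated_nodules_reproducible(self, noiseless_config):
        s1 = next(iter_cohort(noiseless_config, subset="validation"))
        s2 = next(iter_cohort(noiseless_config, subset="validation"))
        assert s1.sample_id == s2.sample_id
        np.testing.assert_array_equal(s1.pixels[0].intensity, s2.pixels[0].intensity)

    def test_subset_iteration_matches_full_sweep(self, noiseless_config):
        full = {s.sample_id: s for s in iter_cohort(noiseless_config)}
        val_first = next(iter_cohort(noiseless_config, subset="validation"))
        np.testing.assert_array_equal(
            full[val_first.sample_id].pixels[3].intensity, val_first.pixels[3].intensity
        )

    def test_simulate_cohort_structure(self, noiseless_config):
        train, val, manifest = simulate_cohort(noiseless_config)
        assert len(train) == 9 and len(val) == 7
        assert len(manifest) == 16
        assert all(s.n_pixels == noiseless_config.pixels_per_nodule for s in train)
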
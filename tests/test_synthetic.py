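"""Synthetic cohort generator: design invariants, determinism, persistence."""

import dataclasses

import numpy as np
import pytest

from specfuse.blocks import FTIR, RAMAN
from specfuse.synthetic import (CohortSpec, DISEASE, HEALTHY,
                                default_effect_bands, generate_cohort,
                                noiseless_spec, read_cohort, write_cohort)


class TestDesignGeometry:
    def test_default_grids_match_design(self):
        spec = CohortSpec()
        assert spec.raman_grid.size == 1015
        assert spec.raman_grid[0] == 610 and spec.raman_grid[-1] == 1720
        assert spec.ftir_grid.size == 1868
        assert spec.ftir_grid[0] == 400 and spec.ftir_grid[-1] == 4000

    def test_fingerprint_subgrid_has_727_points(self):
        spec = CohortSpec()
        assert int(np.sum(spec.ftir_grid <= 1800)) == 727

    def test_default_replicate_counts(self):
        spec = CohortSpec()
        assert spec.n_replicates_raman == 25
        assert spec.n_replicates_ftir == 10


class TestEffectBands:
    def test_marker_centers_present(self):
        bands = default_effect_bands()
        raman = {c for m, c, _, _ in bands if m == RAMAN}
        ftir = {c for m, c, _, _ in bands if m == FTIR}
        assert 1125.0 in raman
        assert 1699.0 in ftir
        assert {624.0, 966.0, 1051.0, 1248.0, 1587.0, 1650.0} <= raman
        assert 1062.0 in ftir

    def test_centers_inside_modality_grid(self):
        spec = CohortSpec()
        for m, c, w, a in default_effect_bands():
            axis = spec.grid(m)
            assert axis[0] <= c <= axis[-1]
            assert w > 0 and a > 0


class TestGeneration:
    def test_seeded_determinism(self):
        spec = CohortSpec(n_per_class=3, n_replicates_raman=4,
                          n_replicates_ftir=2, seed=9)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for sid in a.subject_ids:
            np.testing.assert_array_equal(a.raman_replicates[sid].X,
                                          b.raman_replicates[sid].X)
            np.testing.assert_array_equal(a.ftir_replicates[sid].X,
                                          b.ftir_replicates[sid].X)

    def test_growing_cohort_keeps_existing_subjects(self):
        small = generate_cohort(CohortSpec(n_per_class=3, n_replicates_raman=2,
                                           n_replicates_ftir=2, seed=9))
        large = generate_cohort(CohortSpec(n_per_class=5, n_replicates_raman=2,
                                           n_replicates_ftir=2, seed=9))
        for sid in small.subject_ids:
            np.testing.assert_array_equal(small.raman_replicates[sid].X,
                                          large.raman_replicates[sid].X)

    def test_no_signal_no_noise_gives_identical_class_means(self):
        cohort = generate_cohort(noiseless_spec(seed=1, amplitude=0.0))
        y = cohort.label_vector()
        X = np.vstack([cohort.raman_replicates[s].X.mean(axis=0)
                       for s in cohort.subject_ids])
        np.testing.assert_allclose(X[y == 1].mean(axis=0),
                                   X[y == 0].mean(axis=0), atol=1e-12)

    def test_class_effect_amplitude_recovered_at_1125(self):
        """Class mean difference at a marker equals the set amplitude."""
        amp = 0.05
        spec = noiseless_spec(seed=3, amplitude=amp)
        spec = dataclasses.replace(spec, noise_sd=0.02)
        cohort = generate_cohort(spec)
        y = cohort.label_vector()
        j = int(np.argmin(np.abs(spec.raman_grid - 1125.0)))
        vals = np.array([cohort.raman_replicates[s].X[:, j]
                         for s in cohort.subject_ids])  # subjects x reps
        means = vals.mean(axis=1)
        diff = means[y == 1].mean() - means[y == 0].mean()
        n_rep = spec.n_replicates_raman
        se = spec.noise_sd * np.sqrt(2.0 / (18 * n_rep))
        assert abs(diff - amp) < 3 * se

    def test_labels_are_balanced(self):
        cohort = generate_cohort(CohortSpec(n_per_class=4, n_replicates_raman=2,
                                            n_replicates_ftir=2, seed=0))
        labels = list(cohort.labels.values())
        assert labels.count(HEALTHY) == labels.count(DISEASE) == 4
        assert cohort.subject_ids == list(cohort.labels)

    def test_spikes_only_in_raman(self):
        spec = noiseless_spec(seed=2)
        spec = dataclasses.replace(spec, spike_rate=5.0)
        a = generate_cohort(spec)
        b = generate_cohort(dataclasses.replace(spec, spike_rate=0.0))
        sid = a.subject_ids[0]
        assert not np.array_equal(a.raman_replicates[sid].X,
                                  b.raman_replicates[sid].X)
        np.testing.assert_array_equal(a.ftir_replicates[sid].X,
                                      b.ftir_replicates[sid].X)
        # spikes are strictly additive and positive
        delta = a.raman_replicates[sid].X - b.raman_replicates[sid].X
        assert delta.min() >= 0 and delta.max() > 1


class TestValidation:
    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            CohortSpec(noise_sd=-0.1).validate()

    def test_band_outside_grid_rejected(self):
        spec = CohortSpec(effect_bands=[(RAMAN, 5000.0, 10.0, 0.1)])
        with pytest.raises(ValueError, match="outside"):
            spec.validate()

    def test_strict_mode_rejects_empty_effects(self):
        spec = CohortSpec(effect_bands=[])
        generate_cohort(dataclasses.replace(spec, n_per_class=1,
                                            n_replicates_raman=1,
                                            n_replicates_ftir=1))  # allowed
        with pytest.raises(ValueError, match="strict"):
            generate_cohort(spec, strict=True)


class TestPersistence:
    def test_round_trip_identity(self, small_cohort_spec, tmp_path):
        cohort = generate_cohort(small_cohort_spec)
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert back.labels == cohort.labels
        assert back.truth == cohort.truth
        for sid in cohort.subject_ids:
            np.testing.assert_array_equal(back.raman_replicates[sid].X,
                                          cohort.raman_replicates[sid].X)
            np.testing.assert_array_equal(back.ftir_replicates[sid].X,
                                          cohort.ftir_replicates[sid].X)
            np.testing.assert_array_equal(back.ftir_replicates[sid].axis,
                                          cohort.ftir_replicates[sid].axis)

    def test_missing_label_table_is_named(self, small_cohort_spec, tmp_path):
        cohort = generate_cohort(small_cohort_spec)
        write_cohort(cohort, tmp_path)
        (tmp_path / "labels.csv").unlink()
        with pytest.raises(FileNotFoundError, match="labels.csv"):
            read_cohort(tmp_path)

    def test_full_cohort_label_table_has_36_balanced_rows(self, tmp_path):
        spec = CohortSpec(raman_grid=np.linspace(610, 1720, 40),
                          ftir_grid=np.linspace(400, 4000, 50),
                          n_replicates_raman=2, n_replicates_ftir=2, seed=7)
        cohort = generate_cohort(spec)
        write_cohort(cohort, tmp_path)
        import pandas as pd
        labels = pd.read_csv(tmp_path / "labels.csv")
        assert len(labels) == 36
        assert (labels["class"] == "H").sum() == 18
        assert (labels["class"] == "L").sum() == 18

    def test_spec_json_round_trip(self):
        spec = CohortSpec(seed=11)
        back = CohortSpec.from_json(spec.to_json())
        assert back.n_per_class == spec.n_per_class
        np.testing.assert_allclose(back.raman_grid, spec.raman_grid)
        assert back.effect_bands == [tuple(b) for b in spec.effect_bands]
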
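"""Nearest-reference distances, annuli, zones, paired zone comparisons."""

import numpy as np
import pandas as pd
import pytest

from cycifspatial.simulate import generate_paired_zone_cohort
from cycifspatial.spatial import (
    DISTANCE_COLUMN,
    ZoneConfig,
    annulus_counts,
    assign_zone,
    nearest_reference_distance,
    paired_zone_marker_comparison,
)
from conftest import make_cells
from oracles import brute_nearest_distances, wilcoxon_enum


class TestNearestReferenceDistance:
    def test_three_four_five_triangle(self):
        cells = make_cells(np.array([[0.0, 0.0], [3.0, 4.0]]), ["T", "REF"])
        d = nearest_reference_distance(cells, "REF")
        assert d.iloc[0] == 5.0

    def test_coincident_target_and_reference(self):
        cells = make_cells(np.array([[10.0, 10.0], [10.0, 10.0]]), ["T", "REF"])
        d = nearest_reference_distance(cells, "REF")
        assert d.iloc[0] == 0.0

    def test_reference_cells_use_nearest_other_reference(self):
        cells = make_cells(
            np.array([[0.0, 0.0], [6.0, 8.0], [100.0, 0.0]]), ["REF", "REF", "T"]
        )
        d = nearest_reference_distance(cells, "REF")
        assert d.iloc[0] == 10.0 and d.iloc[1] == 10.0

    def test_lone_reference_flagged_undefined(self):
        cells = make_cells(np.array([[0.0, 0.0], [1.0, 0.0]]), ["REF", "T"])
        d = nearest_reference_distance(cells, "REF")
        assert np.isnan(d.iloc[0]) and d.iloc[1] == 1.0

    def test_core_without_references_all_nan(self):
        a = make_cells(np.array([[0.0, 0.0], [1.0, 1.0]]), ["T", "REF"], core_id="A")
        b = make_cells(np.array([[5.0, 5.0]]), ["T"], core_id="B")
        cells = pd.concat([a, b], ignore_index=True)
        d = nearest_reference_distance(cells, "REF")
        assert np.isnan(d.iloc[2])
        assert d.iloc[0] == pytest.approx(np.sqrt(2))

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1000, size=(300, 2))
        labels = np.array(["T"] * 280 + ["REF"] * 20)
        cells = make_cells(pts, labels)
        d = nearest_reference_distance(cells, "REF")
        expected = brute_nearest_distances(pts[:280], pts[280:])
        np.testing.assert_allclose(d.iloc[:280], expected, atol=1e-9)

    def test_invariant_under_translation_and_rotation(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 500, size=(120, 2))
        labels = np.array(["T"] * 110 + ["REF"] * 10)
        d0 = nearest_reference_distance(make_cells(pts, labels), "REF")
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([123.4, -56.7])
        d1 = nearest_reference_distance(make_cells(moved, labels), "REF")
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestAnnulusCounts:
    def _cells_at_distances(self, dists, phenos=None):
        n = len(dists)
        phenos = phenos or ["T"] * n
        xy = np.array([[0.0, 0.0]] + [[d, 0.0] for d in dists])
        return make_cells(xy, ["REF"] + list(phenos))

    def test_forced_half_open_binning(self):
        cells = self._cells_at_distances([10.0, 30.0, 30.0, 80.0])
        profile = annulus_counts(cells, "REF")
        assert list(profile.counts.loc["T", profile.annulus_labels]) == [1, 2, 0, 1]
        assert profile.counts.loc["T", "beyond"] == 0

    def test_empty_neighborhood_all_zero(self):
        cells = self._cells_at_distances([500.0, 600.0])
        profile = annulus_counts(cells, "REF")
        assert profile.counts[profile.annulus_labels].to_numpy().sum() == 0
        assert profile.counts["beyond"].sum() == 2

    def test_boundary_cells_land_in_upper_bin(self):
        cells = self._cells_at_distances([25.0, 100.0])
        profile = annulus_counts(cells, "REF")
        row = profile.counts.loc["T"]
        assert row["[25,50)"] == 1 and row["[0,25)"] == 0
        assert row["beyond"] == 1  # d=100 is outside [75,100)

    def test_conservation_of_totals(self, gated_cohort):
        _, cells, _ = gated_cohort
        profile = annulus_counts(cells, "Tph_like")
        total = profile.counts.to_numpy().sum()
        assert total == profile.n_eligible
        # per-core conservation too
        per_core = profile.per_core_counts
        d = nearest_reference_distance(cells, "Tph_like")
        eligible = (cells["phenotype"] != "Tph_like") & d.notna()
        per_core_expected = cells.loc[eligible].groupby("core_id").size()
        got = per_core.groupby("core_id")[
            [c for c in per_core.columns if c not in ("core_id", "phenotype")]
        ].sum().sum(axis=1)
        pd.testing.assert_series_equal(
            got.sort_index(), per_core_expected.sort_index(), check_names=False
        )

    def test_non_increasing_edges_rejected(self):
        cells = self._cells_at_distances([10.0])
        for bad in ([0, 50, 25], [25, 50], [0], [0, 0, 50]):
            with pytest.raises(ValueError):
                annulus_counts(cells, "REF", bad)


class TestAssignZone:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (0.0, "proximal"),
            (49.999, "proximal"),
            (50.0, "intermediate"),
            (100.0, "intermediate"),
            (150.999, "intermediate"),
            (151.0, "distal"),
            (175.0, "distal"),
            (199.999, "distal"),
            (200.0, "beyond"),
            (1000.0, "beyond"),
        ],
    )
    def test_default_windows(self, d, expected):
        assert assign_zone(d) == expected

    def test_nan_is_undefined(self):
        assert assign_zone(float("nan")) == "undefined"

    def test_vectorized_matches_scalar(self):
        ds = np.array([0.0, 75.0, 151.0, 250.0, np.nan])
        got = assign_zone(ds)
        assert list(got) == [assign_zone(float(d)) if not np.isnan(d) else "undefined" for d in ds]

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            ZoneConfig(proximal_um=(0.0, 200.0), distal_um=(100.0, 150.0))


class TestPairedZoneComparison:
    def test_identical_zones_give_null_result(self):
        # same per-patient values in both zones -> all paired diffs zero
        df = generate_paired_zone_cohort(n_patients=8, seed=1)
        for pid in df["patient_id"].unique():
            mask = (df["patient_id"] == pid) & (df["phenotype"] == "T")
            df.loc[mask, "corr_M1"] = 5.0
            df.loc[mask, "corr_M2"] = 7.0
        out = paired_zone_marker_comparison(df, "REF", ["T"], ["M1", "M2"])
        assert (out["log_fc"].abs() < 1e-12).all()
        assert (out["p_value"] == 1.0).all()

    def test_exact_doubling_gives_log_fc_one(self):
        df = generate_paired_zone_cohort(n_patients=6, seed=2)
        d = np.hypot(df["x_um"] - 500, df["y_um"] - 500)
        is_t = df["phenotype"] == "T"
        df.loc[is_t & (d < 50), "corr_M1"] = 8.0
        df.loc[is_t & (d > 150), "corr_M1"] = 4.0
        out = paired_zone_marker_comparison(df, "REF", ["T"], ["M1"])
        assert out["log_fc"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_only_patients_with_both_zones_contribute(self):
        df = generate_paired_zone_cohort(n_patients=6, seed=3)
        d = np.hypot(df["x_um"] - 500, df["y_um"] - 500)
        # strip patient P000's distal cells entirely
        drop = (df["patient_id"] == "P000") & (df["phenotype"] == "T") & (d > 150)
        df = df[~drop].reset_index(drop=True)
        out = paired_zone_marker_comparison(df, "REF", ["T"], ["M1"])
        assert out["n_patients_paired"].iloc[0] == 5

    def test_below_min_pairs_reports_fc_but_no_test(self):
        df = generate_paired_zone_cohort(n_patients=3, seed=4)
        out = paired_zone_marker_comparison(df, "REF", ["T"], ["M1"], min_pairs=5)
        assert out["n_patients_paired"].iloc[0] == 3
        assert np.isfinite(out["log_fc"].iloc[0])
        assert np.isnan(out["p_value"].iloc[0])
        assert not out["evaluable"].iloc[0]

    def test_no_paired_patients_not_evaluable(self):
        df = generate_paired_zone_cohort(n_patients=4, seed=5)
        d = np.hypot(df["x_um"] - 500, df["y_um"] - 500)
        df = df[~((df["phenotype"] == "T") & (d > 150))].reset_index(drop=True)
        out = paired_zone_marker_comparison(df, "REF", ["T"], ["M1"])
        assert not out["evaluable"].iloc[0]
        assert np.isnan(out["p_value"].iloc[0])

    def test_auto_direction_recorded_and_matches_sign(self):
        df = generate_paired_zone_cohort(
            n_patients=10, shift_sigma=2.0, shifted_marker="M1", seed=6
        )
        out = paired_zone_marker_comparison(df, "REF", ["T"], ["M1"], alternative="auto")
        assert out["direction"].iloc[0] == "greater"
        assert out["log_fc"].iloc[0] > 0

    def test_wilcoxon_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            df = generate_paired_zone_cohort(n_patients=9, seed=int(rng.integers(2**31)))
            out = paired_zone_marker_comparison(df, "REF", ["T"], ["M1"])
            med = (
                df[df["phenotype"] == "T"]
                .assign(zone=assign_zone(
                    nearest_reference_distance(df, "REF").loc[df["phenotype"] == "T"].to_numpy()
                ))
                .groupby(["patient_id", "zone"])["corr_M1"]
                .median()
                .unstack()
            )
            diffs = (med["proximal"] - med["distal"]).to_numpy()
            _, p_ref = wilcoxon_enum(diffs, "greater")
            assert out["p_value"].iloc[0] == pytest.approx(p_ref, abs=1e-10)
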
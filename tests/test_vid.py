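"""VID coefficients, marker selection, and the heatmap matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roastchem.vid import VIDResult, heatmap_matrix, select_discriminant, vid_scores

from .conftest import toy_volatile_table


def roast_meta(n_per: int = 4) -> pd.DataFrame:
    rows = []
    for roast in ("light", "medium", "dark"):
        for r in range(n_per):
            rows.append({"origin": "O1", "roast": roast, "batch": 1, "reading": r + 1})
    return pd.DataFrame(rows)


class TestVIDScores:
    def test_affine_copy_of_membership_scores_one(self):
        rng = np.random.default_rng(0)
        member = rng.normal(size=(12, 1))
        areas = np.column_stack([3.0 * member[:, 0] + 7.0])  # positive affine
        table = toy_volatile_table(areas, meta=roast_meta())
        vid = vid_scores(table, member, classes=["dark"])
        assert vid.coefficients.loc["v1", "dark"] == pytest.approx(1.0, abs=1e-12)

    def test_negated_abundance_negates_vid(self):
        rng = np.random.default_rng(1)
        member = rng.normal(size=(12, 2))
        x = rng.normal(size=12) + 5
        t1 = toy_volatile_table(x[:, None] + 10, meta=roast_meta())
        t2 = toy_volatile_table(-(x[:, None]) + 10, meta=roast_meta())
        v1 = vid_scores(t1, member, classes=["a", "b"])
        v2 = vid_scores(t2, member, classes=["a", "b"])
        assert np.allclose(
            v1.coefficients.to_numpy(), -v2.coefficients.to_numpy(), atol=1e-12
        )

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_direct_pearson(self, seed):
        rng = np.random.default_rng(seed)
        areas = rng.uniform(1, 100, (10, 4))
        member = rng.normal(size=(10, 3))
        table = toy_volatile_table(areas, meta=roast_meta(4).iloc[:10])
        vid = vid_scores(table, member, classes=["l", "m", "d"])
        for j in range(4):
            for k in range(3):
                expected = np.corrcoef(areas[:, j], member[:, k])[0, 1]
                got = vid.coefficients.iloc[j, k]
                assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_compound_flagged_null(self):
        areas = np.column_stack([np.full(12, 5.0), np.arange(12.0) + 1])
        table = toy_volatile_table(areas, meta=roast_meta())
        vid = vid_scores(table, np.random.default_rng(2).normal(size=(12, 1)), classes=["d"])
        assert vid.undefined == ["v1"]
        assert np.isnan(vid.coefficients.loc["v1", "d"])
        assert np.isfinite(vid.coefficients.loc["v2", "d"])

    def test_row_mismatch_rejected(self):
        table = toy_volatile_table(np.ones((4, 1)) * np.arange(4)[:, None])
        with pytest.raises(ValueError, match="rows"):
            vid_scores(table, np.zeros((5, 2)), classes=["a", "b"])

    def test_values_bounded(self):
        rng = np.random.default_rng(3)
        table = toy_volatile_table(rng.uniform(0, 1e6, (12, 6)), meta=roast_meta())
        vid = vid_scores(table, rng.normal(size=(12, 3)), classes=["l", "m", "d"])
        finite = vid.coefficients.to_numpy()
        assert np.all(np.abs(finite[np.isfinite(finite)]) <= 1 + 1e-12)


def make_vid(values: dict[str, dict[str, float]]) -> VIDResult:
    df = pd.DataFrame(values)
    return VIDResult(coefficients=df, threshold=np.nan, signed=True,
                     selected={}, undefined=[])


class TestSelection:
    def test_signed_marker_rule(self):
        vid = make_vid({"dark": {"v1": 0.85, "v2": 0.5}})
        selected = select_discriminant(vid, threshold=0.8, signed=True)
        assert selected["dark"] == ["v1"]

    def test_negative_vid_selected_only_in_magnitude_mode(self):
        vid = make_vid({"light": {"v1": -0.95}})
        assert select_discriminant(vid, 0.9, signed=False)["light"] == ["v1"]
        assert select_discriminant(vid, 0.8, signed=True)["light"] == []

    def test_threshold_one_keeps_only_unit_correlations(self):
        vid = make_vid({"dark": {"v1": 1.0 - 5e-13, "v2": 0.999, "v3": -1.0}})
        signed = select_discriminant(vid, 1.0, signed=True)
        assert signed["dark"] == ["v1"]
        magnitude = select_discriminant(vid, 1.0, signed=False)
        assert set(magnitude["dark"]) == {"v1", "v3"}

    def test_sorted_by_descending_magnitude(self):
        vid = make_vid({"dark": {"v1": 0.85, "v2": 0.99, "v3": 0.91}})
        assert select_discriminant(vid, 0.8)["dark"] == ["v2", "v3", "v1"]


class TestHeatmap:
    def test_noise_free_compound_row(self):
        """Scaled class means of a compound with zero within-class variance
        and means (-1, 0, 1) across light/medium/dark."""
        per = 4
        areas = np.repeat([10.0, 20.0, 30.0], per)[:, None]
        table = toy_volatile_table(areas, meta=roast_meta(per))
        vid = make_vid({"light": {"v1": -0.9}, "medium": {"v1": 0.0},
                        "dark": {"v1": 0.95}})
        select_discriminant(vid, 0.9, signed=False)
        matrix = heatmap_matrix(table, vid, roast_order=["light", "medium", "dark"])
        scaled = matrix.loc["v1"].to_numpy()
        # autoscaled values are symmetric around the medium class
        assert scaled[1] == pytest.approx(0.0, abs=1e-12)
        assert scaled[0] == pytest.approx(-scaled[2], abs=1e-12)
        assert scaled[2] > 0

    def test_recomputation_is_stable(self, fixture_data):
        from roastchem.gcms import abundance_filter, reproducibility_filter
        from roastchem.pls import plsda_fit, predict

        _, volatiles = fixture_data
        sub = volatiles.subset_samples(
            [s for s in volatiles.sample_ids
             if volatiles.sample_meta.loc[s, "origin"] == "Ethiopia"]
        )
        f, _ = abundance_filter(sub)
        f, _ = reproducibility_filter(f)
        areas = f.peak_areas.fillna(0.0)
        model, _ = plsda_fit(areas, f.sample_meta["roast"].tolist(),
                             max_lv=6, n_splits=5, x_scale="autoscale")
        member = pd.DataFrame(predict(model, areas), index=areas.index,
                              columns=model.classes)
        v1 = vid_scores(f, member)
        select_discriminant(v1, 0.9, signed=False)
        m1 = heatmap_matrix(f, v1)
        v2 = vid_scores(f, member)
        select_discriminant(v2, 0.9, signed=False)
        m2 = heatmap_matrix(f, v2)
        assert m1.equals(m2)

    def test_dark_markers_peak_in_dark_column(self, fixture_data, fixture_truth):
        """Planted dark-increasing compounds attain their maximum scaled
        mean at the dark roast."""
        from roastchem.gcms import abundance_filter, reproducibility_filter
        from roastchem.pls import plsda_fit, predict

        _, volatiles = fixture_data
        sub = volatiles.subset_samples(
            [s for s in volatiles.sample_ids
             if volatiles.sample_meta.loc[s, "origin"] == "Ethiopia"]
        )
        f, _ = abundance_filter(sub)
        f, _ = reproducibility_filter(f)
        areas = f.peak_areas.fillna(0.0)
        model, _ = plsda_fit(areas, f.sample_meta["roast"].tolist(),
                             max_lv=6, n_splits=5, x_scale="autoscale")
        member = pd.DataFrame(predict(model, areas), index=areas.index,
                              columns=model.classes)
        vid = vid_scores(f, member)
        select_discriminant(vid, 0.9, signed=False)
        matrix = heatmap_matrix(f, vid, roast_order=["light", "medium", "dark"])
        increasing = fixture_truth.index[
            (fixture_truth["trend"] == "increasing")
            & (fixture_truth["role"] == "discriminant")
        ]
        for comp in increasing:
            if comp in matrix.index:
                assert matrix.columns[matrix.loc[comp].argmax()] == "dark", comp

    def test_empty_selection_rejected(self):
        table = toy_volatile_table(np.arange(12.0)[:, None] + 1, meta=roast_meta())
        vid = make_vid({"dark": {"v1": 0.1}})
        select_discriminant(vid, 0.9)
        with pytest.raises(ValueError, match="empty"):
            heatmap_matrix(table, vid)
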
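import numpy as np
import pandas as pd
import pytest

from mossar import synthetic
from mossar.data_io import (
    PREDICTORS,
    DataLoadError,
    OccurrenceMatrix,
    SubplotScale,
    check_nestedness,
    rarefaction_curve,
    rarefaction_exact_mean,
    read_environment_table,
    read_occurrence_matrix,
    richness_by_scale,
    write_environment_table,
    write_occurrence_matrix,
)


def _occ(matrix, side=1.0, plots=None, species=None):
    matrix = np.asarray(matrix)
    n, s = matrix.shape
    plots = plots or [f"P{i}" for i in range(n)]
    species = species or [f"sp{j}" for j in range(s)]
    df = pd.DataFrame(matrix, index=pd.Index(plots, name="plot_id"), columns=species)
    return OccurrenceMatrix(SubplotScale(side), df)


class TestSubplotScale:
    def test_area_is_side_squared_exactly(self):
        for side, area in zip((0.01, 0.1, 0.5, 1, 5, 10), (0.0001, 0.01, 0.25, 1, 25, 100)):
            assert SubplotScale(side).area == pytest.approx(area, rel=1e-12)

    def test_standard_scales_ordered(self):
        scales = SubplotScale.standard()
        assert list(scales) == sorted(scales)
        assert len(scales) == 6

    def test_from_area_round_trip(self):
        s = SubplotScale.from_area(25.0)
        assert s.side_length == pytest.approx(5.0)

    def test_rejects_nonpositive_side(self):
        with pytest.raises(ValueError):
            SubplotScale(0.0)


class TestEnvironmentTable:
    def test_synthetic_round_trip_identity(self, plots56, tmp_path):
        path = tmp_path / "env.csv"
        write_environment_table(plots56, path)
        back = read_environment_table(path)
        pd.testing.assert_frame_equal(back.data, plots56.data, check_exact=False, rtol=1e-12)

    def test_paper_shape(self, plots56):
        assert plots56.n_plots == 56
        assert list(plots56.covariates().columns) == list(PREDICTORS)
        assert plots56.elevation.between(1960, 3060).all()

    def test_missing_column_names_the_column(self, plots56, tmp_path):
        df = plots56.data.drop(columns=["NDVI"])
        path = tmp_path / "env.csv"
        df.to_csv(path)
        with pytest.raises(DataLoadError, match="NDVI"):
            read_environment_table(path)

    def test_case_insensitive_headers(self, plots56, tmp_path):
        df = plots56.data.rename(columns={"NDVI": "ndvi", "Bio1": "BIO1"})
        path = tmp_path / "env.csv"
        df.to_csv(path)
        back = read_environment_table(path)
        assert "NDVI" in back.data.columns and "Bio1" in back.data.columns

    def test_duplicate_plot_id_rejected(self, plots56, tmp_path):
        df = pd.concat([plots56.data, plots56.data.iloc[[0]]])
        path = tmp_path / "env.csv"
        df.to_csv(path)
        with pytest.raises(DataLoadError, match="duplicate"):
            read_environment_table(path)

    def test_non_numeric_covariate_rejected(self, plots56, tmp_path):
        df = plots56.data.copy()
        df.loc[df.index[3], "NPP"] = "oops"
        path = tmp_path / "env.csv"
        df.to_csv(path)
        with pytest.raises(DataLoadError, match="NPP"):
            read_environment_table(path)


class TestOccurrenceMatrix:
    def test_round_trip(self, community56, plots56, tmp_path):
        scale = min(community56)
        path = tmp_path / "occ.csv"
        write_occurrence_matrix(community56[scale], path)
        back = read_occurrence_matrix(path, scale, plots=plots56)
        pd.testing.assert_frame_equal(back.data, community56[scale].data)

    def test_all_zero_species_column_allowed(self):
        occ = _occ([[1, 0], [1, 0]])
        assert occ.n_species == 2
        assert richness_by_scale(occ).tolist() == [1, 1]

    def test_bad_cell_value_located(self, tmp_path):
        df = pd.DataFrame({"plot_id": ["a", "b"], "sp1": [0, 2]})
        path = tmp_path / "occ.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DataLoadError, match=r"'b'.*'sp1'"):
            read_occurrence_matrix(path, SubplotScale(1.0))

    def test_unknown_plot_rejected_on_align(self, plots56):
        occ = _occ([[1]], plots=["nope"], species=["sp1"])
        with pytest.raises(DataLoadError):
            occ.align_to(plots56)


class TestRichness:
    def test_identity_matrix(self):
        assert richness_by_scale(_occ(np.eye(3, dtype=int))).tolist() == [1, 1, 1]

    def test_all_ones(self):
        assert richness_by_scale(_occ(np.ones((4, 5), dtype=int))).tolist() == [5, 5, 5, 5]

    def test_matches_generator_bookkeeping(self, community56):
        for occ in community56.values():
            np.testing.assert_array_equal(
                richness_by_scale(occ).to_numpy(), occ.presence.sum(axis=1)
            )


class TestNestedness:
    def test_generator_output_nested(self, community56):
        assert check_nestedness(community56) == []

    def test_violation_warns_not_raises(self):
        small = _occ([[1, 1]], side=1.0)
        large = _occ([[1, 0]], side=10.0)
        with pytest.warns(UserWarning, match="nestedness"):
            problems = check_nestedness({small.scale: small, large.scale: large})
        assert len(problems) == 1


class TestRarefaction:
    def test_single_shared_species_flat(self):
        occ = _occ(np.ones((5, 1), dtype=int))
        curve = rarefaction_curve(occ, n_resamples=50, seed=0)
        np.testing.assert_allclose(curve.mean_richness, 1.0)
        np.testing.assert_allclose(curve.ci_high - curve.ci_low, 0.0)

    def test_full_sample_endpoint_exact(self, community56):
        occ = min(community56.items())[1]
        total = int((occ.presence.any(axis=0)).sum())
        curve = rarefaction_curve(occ, n_resamples=20, seed=1)
        assert curve.mean_richness[-1] == pytest.approx(total)
        assert curve.ci_high[-1] - curve.ci_low[-1] == pytest.approx(0.0)

    def test_monotone_nondecreasing_means(self, community56):
        occ = sorted(community56.items())[2][1]
        for seed in (0, 1, 2):
            curve = rarefaction_curve(occ, n_resamples=100, seed=seed)
            assert (np.diff(curve.mean_richness) >= -1e-9).all()

    def test_matches_hypergeometric_oracle(self):
        # independent closed form (Mao Tau): E[S(m)] = sum_s 1 - C(N-n_s, m)/C(N, m)
        rng = np.random.default_rng(5)
        occ = _occ(rng.integers(0, 2, size=(5, 12)))
        n_resamples = 2000
        curve = rarefaction_curve(occ, n_resamples=n_resamples, seed=3)
        exact = rarefaction_exact_mean(occ)
        from math import comb

        pres = occ.presence
        n = pres.shape[0]
        oracle = []
        for m in range(1, n + 1):
            e = sum(
                1 - comb(n - int(pres[:, j].sum()), m) / comb(n, m)
                if n - int(pres[:, j].sum()) >= m
                else 1.0
                for j in range(pres.shape[1])
            )
            oracle.append(e)
        np.testing.assert_allclose(exact, oracle, rtol=1e-10)
        # MC agreement within 3 standard errors
        for m in range(n):
            se = max(curve.mean_richness.std() / np.sqrt(n_resamples), 0.05)
            assert abs(curve.mean_richness[m] - oracle[m]) < 3 * max(se, 0.1)

    def test_rejects_bad_resamples(self, community56):
        with pytest.raises(ValueError):
            rarefaction_curve(min(community56.items())[1], n_resamples=0)
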
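import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import itemscreen as its
from itemscreen.types import ValidationError


def oracle_alpha(frame: pd.DataFrame) -> float:
    """Independent closed form: alpha = k/(k-1) * (1 - tr(S) / 1'S1)."""
    S = np.cov(frame.to_numpy(), rowvar=False, ddof=1)
    k = frame.shape[1]
    return k / (k - 1) * (1 - np.trace(S) / S.sum())


def _scale(ids):
    return its.ScaleDefinition("test", tuple(ids))


class TestCronbachAlpha:
    def test_identical_columns_give_one(self, matrix_factory):
        m = matrix_factory({"a": [1, 2, 3, 4, 2, 3],
                            "b": [1, 2, 3, 4, 2, 3]})
        assert its.cronbach_alpha(m, _scale(["a", "b"])) == pytest.approx(1.0)

    def test_matches_covariance_oracle_on_toy_matrix(self, matrix_factory):
        m = matrix_factory({"a": [1, 2, 3, 4, 2, 3],
                            "b": [2, 2, 4, 3, 1, 3],
                            "c": [1, 3, 3, 4, 2, 2]})
        alpha = its.cronbach_alpha(m, _scale(["a", "b", "c"]))
        assert alpha == pytest.approx(oracle_alpha(m.data), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_matches_covariance_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        k = int(rng.integers(2, 6))
        frame = pd.DataFrame(rng.standard_normal((n, k)),
                             columns=[f"v{j}" for j in range(k)])
        alpha = its.cronbach_alpha(frame, _scale(frame.columns))
        assert alpha == pytest.approx(oracle_alpha(frame), abs=1e-12)

    def test_matches_pingouin(self, matrix_factory):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        frame = pd.DataFrame(rng.integers(1, 5, size=(30, 4)).astype(float),
                             columns=list("abcd"))
        ours = its.cronbach_alpha(frame, _scale("abcd"))
        theirs = pg.cronbach_alpha(data=frame)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_independent_columns_alpha_near_zero(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.standard_normal((10_000, 2)),
                             columns=["a", "b"])
        assert abs(its.cronbach_alpha(frame, _scale(["a", "b"]))) < 0.05

    def test_single_item_scale_rejected(self):
        with pytest.raises(ValidationError):
            its.ScaleDefinition("solo", ("a",))

    def test_unknown_missing_policy_rejected(self, matrix_factory):
        m = matrix_factory({"a": [1, 2, 3], "b": [2, 3, 4]})
        with pytest.raises(ValidationError, match="pairwise"):
            its.cronbach_alpha(m, _scale(["a", "b"]), missing_policy="pairwise")

    def test_zero_total_variance_undefined(self, matrix_factory):
        m = matrix_factory({"a": [2, 2, 2, 2], "b": [3, 3, 3, 3]})
        assert math.isnan(its.cronbach_alpha(m, _scale(["a", "b"])))

    def test_listwise_deletion(self, matrix_factory):
        m = matrix_factory({"a": [1, 2, 3, 4, None],
                            "b": [2, 2, 4, 3, 1],
                            "c": [1, 3, 3, 4, 2]})
        alpha = its.cronbach_alpha(m, _scale(["a", "b", "c"]))
        complete = m.data.dropna()
        assert alpha == pytest.approx(oracle_alpha(complete), abs=1e-12)


class TestAlphaInvariances:
    def test_invariant_under_reverse_then_recode(self, matrix_factory):
        cells = {"a": [1, 2, 3, 4, 2, 3], "b": [2, 2, 4, 3, 1, 3]}
        plain = matrix_factory(cells)
        items = its.build_items([its.ItemMetadata("a"),
                                 its.ItemMetadata("b", reverse_coded=True)])
        flipped = matrix_factory(
            {"a": cells["a"], "b": [5 - v for v in cells["b"]]}, items=items)
        a1 = its.cronbach_alpha(plain, _scale(["a", "b"]))
        a2 = its.cronbach_alpha(its.recode_reverse(flipped), _scale(["a", "b"]))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_invariant_under_adding_a_constant(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        shifted = frame + pd.Series({"a": 10.0, "b": -2.0, "c": 0.5})
        a1 = its.cronbach_alpha(frame, _scale("abc"))
        a2 = its.cronbach_alpha(shifted, _scale("abc"))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestScaleReport:
    def test_disjoint_scales_are_independent_rows(self, matrix_factory):
        m = matrix_factory({"a": [1, 2, 3, 4], "b": [2, 3, 1, 4],
                            "c": [4, 3, 2, 1], "d": [1, 1, 2, 2]})
        rows = its.scale_report(m, [_scale(["a", "b"]),
                                    its.ScaleDefinition("two", ("c", "d"))])
        assert [r.name for r in rows] == ["test", "two"]
        assert rows[0].alpha == pytest.approx(
            its.cronbach_alpha(m, _scale(["a", "b"])))

    def test_fully_missing_scale_reports_undefined(self, matrix_factory):
        m = matrix_factory({"a": [None, None], "b": [None, None]})
        (row,) = its.scale_report(m, [_scale(["a", "b"])])
        assert row.n_complete == 0 and math.isnan(row.alpha)

    def test_latent_loading_recovers_spearman_brown_alpha(self):
        # k = 5 items, loading 0.8 -> population alpha 5r/(1+4r), r = 0.64
        k, lam, n = 5, 0.8, 5_000
        ids = [f"s{j:02d}" for j in range(1, k + 1)]
        cfg = its.CohortConfig(
            n_patients=n,
            scales=[its.ScaleModel(its.ScaleDefinition("latent", tuple(ids)),
                                   loading=lam)],
            default_missingness=0.0,
            seed=11,
        )
        _, _, latent = its.generate_cohort(cfg)
        expected = its.expected_alpha(k, lam)
        assert expected == pytest.approx(0.899, abs=5e-4)
        alpha = its.cronbach_alpha(latent, its.ScaleDefinition("latent", tuple(ids)))
        assert alpha == pytest.approx(expected, abs=0.03)

    def test_alpha_monotone_in_loading(self):
        alphas = []
        for lam in (0.2, 0.5, 0.8):
            ids = tuple(f"s{j}" for j in range(4))
            cfg = its.CohortConfig(
                n_patients=5_000,
                scales=[its.ScaleModel(its.ScaleDefinition("sc", ids),
                                       loading=lam)],
                default_missingness=0.0,
                seed=5,
            )
            _, _, latent = its.generate_cohort(cfg)
            alphas.append(its.cronbach_alpha(
                latent, its.ScaleDefinition("sc", ids)))
        assert alphas[0] < alphas[1] < alphas[2]
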
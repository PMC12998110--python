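"""Quality screening, descriptives, reliability and the sample-size rule."""

import numpy as np
import pandas as pd
import pytest

from profilenet.datasets import SENNC_DIMENSIONS
from profilenet.qc import (
    QCRules,
    apply_quality_filters,
    cronbach_alpha,
    descriptives,
    min_sample_size,
    response_rate,
)

from .conftest import exact_covariance_data, make_survey


@pytest.mark.parametrize(
    "distributed,retained,expected",
    [(530, 510, 96.2), (100, 100, 100.0), (8, 7, 87.5)],
)
def test_response_rate(distributed, retained, expected):
    assert response_rate(distributed, retained) == expected


def test_response_rate_domain_errors():
    with pytest.raises(ValueError):
        response_rate(0, 0)
    with pytest.raises(ValueError):
        response_rate(10, 11)


@pytest.mark.parametrize("P,expected", [(27, 378), (1, 1), (10, 55)])
def test_min_sample_size(P, expected):
    """Thresholds plus pairwise couplings: P + P(P-1)/2."""
    assert min_sample_size(P) == expected
    with pytest.raises(ValueError):
        min_sample_size(0)


class TestQualityFilters:
    def _raw_530(self):
        """530 rows engineered so exactly 9 are too fast, 5 fail a logic
        check and 6 are straight-lined, with no overlaps."""
        rng = np.random.default_rng(42)
        vals = rng.integers(1, 6, size=(530, 27))
        # de-straight-line every row, then straight-line rows 20..25
        vals[:, 0] = np.where(vals[:, 0] == vals[:, 1], vals[:, 1] % 5 + 1, vals[:, 0])
        vals[20:26] = 3
        durations = np.full(530, 400.0)
        durations[:9] = 100.0  # too fast
        flag = np.zeros(530, dtype=int)
        flag[10:15] = 1  # logic violations
        return make_survey(vals, duration_seconds=durations, impossible=flag)

    def test_paper_style_accounting(self):
        raw = self._raw_530()
        rules = QCRules(logic_checks=[lambda row: row["impossible"] == 1])
        retained, report = apply_quality_filters(raw, rules)
        assert (report.too_fast, report.logic_error, report.regularity) == (9, 5, 6)
        assert report.n_retained == retained.n == 510
        assert report.response_rate_percent == 96.2

    def test_counts_reconcile_and_idempotent(self):
        raw = self._raw_530()
        rules = QCRules(logic_checks=[lambda row: row["impossible"] == 1])
        retained, report = apply_quality_filters(raw, rules)
        assert report.n_excluded == raw.n - retained.n
        again, report2 = apply_quality_filters(retained, rules)
        assert again.n == retained.n and report2.n_excluded == 0

    def test_no_rules_identity(self):
        raw = self._raw_530()
        rules = QCRules(min_duration_seconds=None, regularity_run=None, dedupe=False)
        retained, report = apply_quality_filters(raw, rules)
        assert retained.n == raw.n
        assert report.response_rate_percent == 100.0

    def test_constant_row_excluded_as_regularity(self):
        vals = np.tile(np.arange(1, 6), (4, 6))[:, :27].copy()
        vals[2] = 4  # zero-variance responder
        raw = make_survey(vals)
        _, report = apply_quality_filters(
            raw, QCRules(min_duration_seconds=None)
        )
        assert report.regularity == 1

    def test_duplicate_keys_counted_once(self):
        vals = np.tile(np.arange(1, 6), (6, 6))[:, :27]
        raw = make_survey(vals)
        raw.table.loc[3, "respondent_id"] = raw.table.loc[0, "respondent_id"]
        _, report = apply_quality_filters(raw, QCRules(min_duration_seconds=None))
        assert report.duplicate_key == 1

    def test_missing_duration_errors(self):
        vals = np.tile(np.arange(1, 6), (3, 6))[:, :27]
        with pytest.raises(ValueError, match="duration"):
            apply_quality_filters(make_survey(vals), QCRules())


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([x, x, x])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_two_uncorrelated_items(self):
        X = np.array([[1, 1], [2, 1], [1, 2], [2, 2]], dtype=float)
        assert cronbach_alpha(X) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_exchangeable(self):
        # k=3 items, unit variances, all pairwise correlations 0.5:
        # alpha = (3/2)(1 - 3/6) = 0.75
        cov = np.full((3, 3), 0.5)
        np.fill_diagonal(cov, 1.0)
        X = exact_covariance_data(cov, 200, seed=3)
        assert cronbach_alpha(X) == pytest.approx(0.75, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        assert cronbach_alpha(2.5 * X + 7.0) == pytest.approx(
            cronbach_alpha(X), abs=1e-12
        )

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.full((5, 3), 4.0))

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        X = rng.integers(1, 6, size=(80, 6)).astype(float)
        ours = cronbach_alpha(X)
        theirs = pg.cronbach_alpha(pd.DataFrame(X))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestDescriptives:
    def test_constant_responses(self):
        vals = np.full((10, 27), 3)
        rep = descriptives(make_survey(vals), SENNC_DIMENSIONS)
        assert (rep.item_stats["mean"] == 3).all()
        assert (rep.item_stats["sd"] == 0).all()
        assert rep.total_mean == 81.0
        assert np.isnan(rep.cronbach_alpha)  # reliability undefined

    def test_dimension_totals_add_up(self, three_class_data):
        data, _ = three_class_data
        rep = descriptives(data, SENNC_DIMENSIONS)
        assert rep.total_mean == pytest.approx(
            rep.dimension_stats["mean"].sum(), abs=1e-9
        )
        for frame in rep.categorical.values():
            assert frame["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_two_respondent_hand_computation(self):
        vals = np.vstack([np.full(27, 80 / 27.0), np.full(27, 100 / 27.0)])
        from profilenet.datasets import SENNC_ITEMS, ResponseDataset

        table = pd.DataFrame(vals, columns=list(SENNC_ITEMS))
        data = ResponseDataset(table)
        rep = descriptives(data, SENNC_DIMENSIONS)
        assert rep.total_mean == pytest.approx(90.0)
        assert rep.total_sd == pytest.approx(np.sqrt(200.0), abs=1e-9)  # ~14.142

    def test_bad_partition_rejected(self):
        vals = np.full((5, 27), 3)
        bad = {"A": [f"NCK{i}" for i in range(1, 7)]}
        with pytest.raises(ValueError):
            descriptives(make_survey(vals), bad)
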
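import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moxatox.errors import EstimationError, ValidationError
from moxatox.lethality import (
    MortalityTable,
    karber_lc50,
    karber_se,
    max_tolerated_dose,
    spearman_karber_lc50,
)

# frozen oracles for the five-group study design, computed by direct
# evaluation of the closed forms (log10 arithmetic on the dose column)
STUDY_KARBER_LC50 = 403.095
STUDY_SK_LC50 = 426.688
STUDY_I_MEAN = 0.085774
STUDY_SE_LOG10 = 0.023051


def geometric_table(start, ratio, deaths, n=10):
    doses = [start * ratio**j for j in range(len(deaths))]
    return MortalityTable.from_records([(d, n, k) for d, k in zip(doses, deaths)])


class TestKarber:
    def test_symmetric_geometric_design(self, uniform_design):
        """Deaths 0/5/10 on a 10x ladder put the LC50 at the middle dose."""
        est = karber_lc50(uniform_design)
        assert est.lc50 == pytest.approx(100.0, rel=1e-9)
        assert est.i_used == pytest.approx(1.0)
        assert est.warnings == ()

    def test_study_design_estimate_and_warning(self, study_mortality):
        """The five-group table gives ~403.1 g/m3 with mean log spacing
        0.08577; the published 537.65 does not follow from the formula."""
        est = karber_lc50(study_mortality)
        assert est.lc50 == pytest.approx(STUDY_KARBER_LC50, abs=0.05)
        assert est.i_used == pytest.approx(STUDY_I_MEAN, abs=1e-5)
        assert est.se_log10 == pytest.approx(STUDY_SE_LOG10, abs=1e-5)
        assert any("non-uniform" in w for w in est.warnings)
        assert abs(est.lc50 - 537.65) > 100  # the published value is far off

    @given(factor=st.floats(0.1, 100))
    @settings(max_examples=100, derandomize=True)
    def test_scale_equivariance(self, factor):
        t = geometric_table(10, 10, [0, 5, 10])
        base = karber_lc50(t).lc50
        scaled = karber_lc50(t.scaled(factor)).lc50
        assert scaled == pytest.approx(base * factor, rel=1e-9)

    def test_fixed_i_strategy(self, study_mortality):
        est = karber_lc50(study_mortality, i_strategy=0.1)
        assert est.i_used == 0.1

    def test_unbracketed_or_small_designs_rejected(self):
        with pytest.raises(EstimationError, match="not bracketed"):
            karber_lc50(geometric_table(10, 10, [0, 0, 0]))
        with pytest.raises(EstimationError, match="not bracketed"):
            karber_lc50(geometric_table(10, 10, [10, 10, 10]))
        with pytest.raises(ValidationError, match="3 dose groups"):
            karber_lc50(geometric_table(10, 10, [0, 10]))


class TestSpearmanKarber:
    def test_matches_karber_on_uniform_design(self, uniform_design):
        assert spearman_karber_lc50(uniform_design).lc50 == pytest.approx(
            karber_lc50(uniform_design).lc50, rel=1e-12
        )

    def test_study_design_estimate(self, study_mortality):
        est = spearman_karber_lc50(study_mortality)
        assert est.lc50 == pytest.approx(STUDY_SK_LC50, abs=0.05)

    def test_input_order_invariance(self, study_mortality):
        reversed_records = list(
            zip(study_mortality.doses, study_mortality.n, study_mortality.deaths)
        )[::-1]
        est = spearman_karber_lc50(MortalityTable.from_records(reversed_records))
        assert est.lc50 == pytest.approx(STUDY_SK_LC50, abs=0.05)

    @given(
        n_groups=st.integers(3, 8),
        start=st.floats(1, 50),
        ratio=st.floats(1.2, 10),
        data=st.data(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_karber_identity_on_monotone_uniform_ladders(
        self, n_groups, start, ratio, data
    ):
        """On a geometric ladder with monotone 0->1 mortality the two
        estimators coincide algebraically."""
        deaths = sorted(
            data.draw(
                st.lists(
                    st.integers(0, 10), min_size=n_groups, max_size=n_groups
                )
            )
        )
        deaths[0], deaths[-1] = 0, 10
        t = geometric_table(start, ratio, deaths)
        assert spearman_karber_lc50(t).log10_lc50 == pytest.approx(
            karber_lc50(t).log10_lc50, abs=1e-9
        )

    def test_estimate_between_bracketing_doses(self, study_mortality):
        est_k = karber_lc50(study_mortality)
        est_sk = spearman_karber_lc50(study_mortality)
        lo = max(d for d, k in zip(study_mortality.doses, study_mortality.deaths) if k == 0)
        hi = min(
            d
            for d, k, n in zip(
                study_mortality.doses, study_mortality.deaths, study_mortality.n
            )
            if k == n
        )
        for est in (est_k, est_sk):
            assert lo < est.lc50 < hi

    def test_monotonization_rescues_non_monotone_mortality(self):
        t = MortalityTable.from_records(
            [(10, 10, 0), (20, 10, 4), (40, 10, 3), (80, 10, 7), (160, 10, 10)]
        )
        with_pava = spearman_karber_lc50(t, monotonize=True)
        assert any("pooled-adjacent" in w for w in with_pava.warnings)
        plain = spearman_karber_lc50(t)
        assert any("non-monotone" in w for w in plain.warnings)
        # PAVA pools groups 2 and 3 to 3.5/10 each; both estimates stay bracketed
        assert 10 < with_pava.lc50 < 160

    def test_unspanned_mortality_rejected(self):
        with pytest.raises(EstimationError, match="Spearman-Karber requires"):
            spearman_karber_lc50(geometric_table(10, 10, [1, 5, 10]))


class TestSeAndTolerated:
    def test_se_zero_at_extreme_mortality(self):
        t = geometric_table(10, 10, [0, 10, 10])
        assert karber_se(t, 1.0) == 0.0

    def test_study_design_se(self, study_mortality):
        assert karber_se(study_mortality, STUDY_I_MEAN) == pytest.approx(
            STUDY_SE_LOG10, abs=1e-5
        )

    def test_se_linear_in_spacing(self, study_mortality):
        assert karber_se(study_mortality, 0.2) == pytest.approx(
            2 * karber_se(study_mortality, 0.1), rel=1e-12
        )

    def test_se_requires_replication(self):
        t = MortalityTable.from_records([(10, 1, 0), (100, 1, 1), (1000, 1, 1)])
        with pytest.raises(ValidationError, match="n >= 2"):
            karber_se(t, 1.0)

    def test_max_tolerated_dose_study(self, study_mortality):
        assert max_tolerated_dose(study_mortality) == pytest.approx(290.036)

    def test_max_tolerated_dose_all_survive(self):
        t = geometric_table(10, 10, [0, 0, 0])
        assert max_tolerated_dose(t) == pytest.approx(1000.0)

    def test_max_tolerated_dose_none_observed(self):
        t = geometric_table(10, 10, [1, 5, 10])
        with pytest.raises(EstimationError, match="no tolerated dose"):
            max_tolerated_dose(t)


class TestMortalityTable:
    def test_sorted_ascending_regardless_of_input_order(self):
        t = MortalityTable.from_records([(100, 10, 5), (10, 10, 0), (1000, 10, 10)])
        assert t.doses == (10.0, 100.0, 1000.0)
        assert t.deaths == (0, 5, 10)

    def test_duplicate_doses_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            MortalityTable.from_records([(10, 10, 0), (10, 10, 5), (100, 10, 10)])
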
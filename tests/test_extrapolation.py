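"""The rate-ratio extrapolation estimator and its component operations."""

import numpy as np
import pandas as pd
import pytest

import mcod
from mcod.extrapolation import (
    MultipleCauseModel,
    adjust_proportion,
    conditional_mention_proportion,
    death_rate,
    extrapolate,
    stratum_category_deaths,
    total_multiple_deaths,
)
from mcod.simulate import default_cohort_config, simulate_country

from conftest import make_two_category_tables


def _idx(cells):
    return pd.MultiIndex.from_tuples(cells, names=["sex", "age_band", "category"])


class TestConditionalMentionProportion:
    def setup_method(self):
        cells = [
            ("male", "0+", "parkinsons_disease"),
            ("male", "0+", "pneumonia"),
            ("male", "0+", "other"),
        ]
        pop = pd.Series(
            [10_000],
            index=pd.MultiIndex.from_tuples([("male", "0+")], names=["sex", "age_band"]),
        )
        self.uc = mcod.StratifiedCountTable(
            pd.Series([40, 100, 0], index=_idx(cells)), pop
        )
        self.cells = cells

    def test_ratio_forced_unit_and_imputed_zero(self):
        mentions = pd.Series([40, 12, 0], index=_idx(self.cells))
        p = conditional_mention_proportion(mentions, self.uc)
        assert p.value("male", "0+", "pneumonia") == pytest.approx(0.12)
        assert p.value("male", "0+", "parkinsons_disease") == 1.0
        assert p.value("male", "0+", "other") == 0.0
        flags = p.flags
        assert flags.loc[("male", "0+", "parkinsons_disease")] == "forced_unit"
        assert flags.loc[("male", "0+", "other")] == "imputed_zero"
        assert flags.loc[("male", "0+", "pneumonia")] == "observed"

    def test_mentions_exceeding_underlying_rejected(self):
        mentions = pd.Series([40, 101, 0], index=_idx(self.cells))
        with pytest.raises(ValueError, match="exceed"):
            conditional_mention_proportion(mentions, self.uc)


class TestAdjustProportion:
    def test_identity_when_rates_equal(self):
        assert adjust_proportion(0.2, 3.0, 3.0, "other") == (0.2, "adjusted")

    def test_rate_ratio_arithmetic(self):
        v, _ = adjust_proportion(0.2, 2.0, 4.0, "other")
        assert v == pytest.approx(0.1)

    def test_cap_at_one(self):
        assert adjust_proportion(0.8, 4.0, 2.0, "other") == (1.0, "capped")

    def test_pd_category_always_unit(self):
        assert adjust_proportion(0.0, 5.0, 0.0, "parkinsons_disease") == (1.0, "forced_unit")

    def test_zero_target_rate_gives_zero(self):
        assert adjust_proportion(0.3, 0.0, 2.0, "other")[0] == 0.0

    def test_zero_reference_rate_errors_by_default(self):
        with pytest.raises(ZeroDivisionError):
            adjust_proportion(0.3, 1.0, 0.0, "other")

    def test_zero_reference_rate_fallback(self):
        v, flag = adjust_proportion(0.3, 1.0, 0.0, "other", zero_reference_rate="unadjusted")
        assert (v, flag) == (0.3, "observed")


class TestScalarOps:
    @pytest.mark.parametrize("n,p,expect", [(500, 0.04, 20.0), (0, 0.9, 0.0), (1409, 1.0, 1409.0)])
    def test_cell_estimate(self, n, p, expect):
        assert stratum_category_deaths(n, p) == expect

    def test_stratum_total(self):
        assert total_multiple_deaths({"a": 20.0, "b": 5.0, "c": 1409.0}) == 1434.0
        assert total_multiple_deaths({"a": 0.0}) == 0.0

    def test_missing_category_cell_errors(self):
        with pytest.raises(KeyError, match="missing"):
            total_multiple_deaths({"a": 1.0}, categories=["a", "b"])

    def test_death_rate(self):
        assert death_rate(58, 1_000_000) == 5.8
        assert death_rate(0, 123) == 0.0
        with pytest.raises(ValueError):
            death_rate(1, 0)


class TestSelfReferentialExactness:
    @pytest.mark.parametrize("n_deaths", [1_000, 10_000, 100_000])
    def test_reference_equals_target_reproduces_counted_truth(self, n_deaths):
        """With reference = target, the estimator must equal the directly
        counted multiple-cause totals to machine precision."""
        cfg = default_cohort_config(total_deaths=n_deaths)
        country = simulate_country(cfg, seed=n_deaths)
        res = extrapolate(country.uc_table, country.uc_table, country.mention_counts)
        # independent counting oracle straight from the record list
        rec = country.records
        is_mc = (rec["category"] == cfg.pd_category) | rec["pd_mention"]
        truth = (
            rec[is_mc]
            .groupby(["sex", "age_band"])
            .size()
            .reindex(res.m_stratum.index, fill_value=0)
        )
        np.testing.assert_allclose(res.m_stratum.to_numpy(), truth.to_numpy(), rtol=1e-12)


class TestCollapsedClosedForm:
    def test_agrees_with_closed_form_on_random_tables(self):
        """In two-category (PD + other) mode the stratum estimate has the
        closed form M_j = N_pd_t + N_other_t * (mentions_r / N_other_r) *
        (R_t / R_r); agreement to 1e-9 relative tolerance."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            target, reference, mentions = make_two_category_tables(rng)
            res = extrapolate(target, reference, mentions, collapse=True)
            for st in target.population.index:
                sex, band = st
                n_pd_t = target.counts.loc[(sex, band, "parkinsons_disease")]
                n_o_t = target.counts.loc[(sex, band, "other")]
                n_pd_r = reference.counts.loc[(sex, band, "parkinsons_disease")]
                n_o_r = reference.counts.loc[(sex, band, "other")]
                m_r = mentions.loc[(sex, band, "other")]
                ratio = (n_pd_t / target.population.loc[st]) / (
                    n_pd_r / reference.population.loc[st]
                )
                expected = n_pd_t + n_o_t * (m_r / n_o_r) * ratio
                assert res.m_stratum.loc[st] == pytest.approx(expected, rel=1e-9)

    def test_lower_bound_invariant(self):
        """M_j >= target PD underlying count in every stratum."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            target, reference, mentions = make_two_category_tables(rng)
            res = extrapolate(target, reference, mentions)
            n_pd = target.category_counts("parkinsons_disease")
            assert (res.m_stratum >= n_pd.reindex(res.m_stratum.index) - 1e-9).all()


class TestPolicies:
    def test_zero_pd_target_everywhere_gives_zero(self):
        rng = np.random.default_rng(11)
        target, reference, mentions = make_two_category_tables(rng)
        counts = target.counts.copy()
        cat = counts.index.get_level_values("category")
        counts[cat == "parkinsons_disease"] = 0
        target0 = mcod.StratifiedCountTable(counts, target.population)
        res = extrapolate(target0, reference, mentions)
        assert (res.m_stratum == 0).all()

    def test_neutral_ratio_reduces_to_reference_proportions(self):
        rng = np.random.default_rng(5)
        _, reference, mentions = make_two_category_tables(rng)
        res = extrapolate(reference, reference, mentions)
        p_ref = conditional_mention_proportion(mentions, reference)
        np.testing.assert_allclose(
            res.proportions_target.proportions.to_numpy(),
            p_ref.proportions.to_numpy(),
        )
        assert len(res.audit) == 0  # no caps, imputations or fallbacks

    def test_monotone_in_rate_ratio_until_cap(self):
        """Shrinking the target population raises R_t and hence M_j, until
        the proportion caps at 1 and the estimate saturates."""
        rng = np.random.default_rng(3)
        target, reference, mentions = make_two_category_tables(rng, n_strata=1)
        other = mentions.index.get_level_values("category") == "other"
        mentions[other] = np.maximum(mentions[other], 1)
        totals = []
        for pop in [400_000, 200_000, 100_000, 1_000, 100]:
            p = pd.Series(pop, index=target.population.index, dtype="int64")
            t = mcod.StratifiedCountTable(target.counts, p)
            totals.append(extrapolate(t, reference, mentions).total())
        assert all(a <= b + 1e-9 for a, b in zip(totals, totals[1:]))
        capped = extrapolate(
            mcod.StratifiedCountTable(
                target.counts, pd.Series(100, index=target.population.index)
            ),
            reference,
            mentions,
        )
        assert (capped.audit["event"] == "capped").any()
        n = target.counts.groupby(["sex", "age_band"]).sum()
        np.testing.assert_allclose(capped.m_stratum.to_numpy(), n.to_numpy())

    def test_stratum_mismatch_names_missing(self):
        rng = np.random.default_rng(9)
        target, reference, mentions = make_two_category_tables(rng)
        shrunk = mcod.StratifiedCountTable(
            target.counts.drop(index="0-64", level="age_band"),
            target.population.drop(index="0-64", level="age_band"),
        )
        with pytest.raises(ValueError, match="0-64"):
            MultipleCauseModel(shrunk, reference, mentions)

    def test_zero_reference_rate_policy_propagates(self):
        rng = np.random.default_rng(13)
        target, reference, mentions = make_two_category_tables(rng, n_strata=1)
        tcounts = target.counts.copy()
        tcounts[tcounts.index.get_level_values("category") == "parkinsons_disease"] = 50
        target = mcod.StratifiedCountTable(tcounts, target.population)
        counts = reference.counts.copy()
        cat = counts.index.get_level_values("category")
        counts[cat == "parkinsons_disease"] = 0
        mentions = mentions.copy()
        mentions[mentions.index.get_level_values("category") == "parkinsons_disease"] = 0
        ref0 = mcod.StratifiedCountTable(counts, reference.population)
        with pytest.raises(ZeroDivisionError):
            extrapolate(target, ref0, mentions)
        res = extrapolate(target, ref0, mentions, zero_reference_rate="unadjusted")
        assert (res.audit["event"] == "fallback_unadjusted").any()


class TestResultsSurface:
    def test_summary_and_frame(self):
        rng = np.random.default_rng(21)
        target, reference, mentions = make_two_category_tables(rng)
        res = extrapolate(target, reference, mentions)
        s = res.summary()
        assert "estimated multiple-cause PD deaths" in s
        frame = res.to_frame()
        assert list(frame.columns) == ["sex", "age_band", "M", "M_rounded", "rate"]
        assert res.total() == pytest.approx(frame["M"].sum())

    def test_from_csv(self, tmp_path):
        rng = np.random.default_rng(23)
        target, reference, mentions = make_two_category_tables(rng)
        target.counts_frame().to_csv(tmp_path / "tc.csv", index=False)
        target.population_frame().to_csv(tmp_path / "tp.csv", index=False)
        reference.counts_frame().to_csv(tmp_path / "rc.csv", index=False)
        reference.population_frame().to_csv(tmp_path / "rp.csv", index=False)
        mentions.rename("count").reset_index().to_csv(tmp_path / "m.csv", index=False)
        model = MultipleCauseModel.from_csv(
            tmp_path / "tc.csv", tmp_path / "tp.csv",
            tmp_path / "rc.csv", tmp_path / "rp.csv", tmp_path / "m.csv",
        )
        direct = extrapolate(target, reference, mentions)
        np.testing.assert_allclose(
            model.fit().m_stratum.sort_index().to_numpy(),
            direct.m_stratum.sort_index().to_numpy(),
        )
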
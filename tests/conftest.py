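import pandas as pd
import pytest

import mcod


@pytest.fixture(scope="session")
def fixture_certs():
    """The packaged 477-certificate fixture."""
    return mcod.table2_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_tabs(fixture_certs):
    return mcod.tabulate_mentions(fixture_certs)


@pytest.fixture(scope="session")
def small_config():
    """A 2-stratum, 3-category cohort for fast exact checks."""
    strata = [("male", "65-74"), ("female", "75-84")]
    return mcod.CohortConfig(
        deaths={strata[0]: 2000, strata[1]: 3000},
        population={st: 100_000 for st in strata},
        cause_distribution={
            strata[0]: {"parkinsons_disease": 0.05, "pneumonia": 0.30, "other": 0.65},
            strata[1]: {"parkinsons_disease": 0.08, "pneumonia": 0.25, "other": 0.67},
        },
        mention_probability={
            strata[0]: {"pneumonia": 0.10, "other": 0.03},
            strata[1]: {"pneumonia": 0.12, "other": 0.04},
        },
    )


def make_two_category_tables(rng, n_strata=3):
    """Random aligned (target, reference, mentions) tables with two
    categories (PD + other), constructed so no adjustment cap can bind."""
    bands = ["0-64", "65-74", "75-84", "85+"][:n_strata]
    idx = pd.MultiIndex.from_tuples(
        [("male", b) for b in bands], names=["sex", "age_band"]
    )
    rows_t, rows_r, rows_m = [], [], []
    for sex, band in idx:
        n_pd_r = int(rng.integers(50, 200))
        n_pd_t = int(rng.integers(0, 3 * n_pd_r))
        n_other_r = int(rng.integers(500, 5000))
        n_other_t = int(rng.integers(500, 5000))
        mentions = int(rng.integers(0, int(0.2 * n_other_r) + 1))
        rows_t += [(sex, band, "parkinsons_disease", n_pd_t), (sex, band, "other", n_other_t)]
        rows_r += [(sex, band, "parkinsons_disease", n_pd_r), (sex, band, "other", n_other_r)]
        rows_m += [(sex, band, "parkinsons_disease", n_pd_r), (sex, band, "other", mentions)]
    pop = pd.Series(100_000, index=idx, dtype="int64")

    def table(rows):
        s = pd.Series(
            {r[:3]: r[3] for r in rows}, dtype="int64"
        )
        s.index = pd.MultiIndex.from_tuples(s.index, names=["sex", "age_band", "category"])
        return s

    target = mcod.StratifiedCountTable(table(rows_t), pop.copy())
    reference = mcod.StratifiedCountTable(table(rows_r), pop.copy())
    mentions = table(rows_m)
    return target, reference, mentions
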
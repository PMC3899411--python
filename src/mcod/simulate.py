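"""Synthetic two-country death cohorts with known multiple-cause structure.

The real certificate microdata behind national mortality tables are
confidential, so estimator behaviour is studied on simulated cohorts whose
truth is known by construction.  Each simulated death carries an underlying
cause drawn from a per-stratum category distribution and, when the
underlying cause is not PD, an independent binary PD mention with a
configured per-(stratum, category) probability.  Deaths whose underlying
cause is PD always "mention" PD, so the true multiple-cause PD count in a
stratum is the PD-underlying count plus the non-PD deaths with a mention.

Only the PD mention is simulated (not full multi-condition certificates):
the extrapolation uses no further certificate structure.  The fixture
builder in :mod:`mcod.certificates` covers multi-condition needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .certificates import DeathCertificate, PD_LABEL
from .icd import PD_CATEGORY
from .tables import StratifiedCountTable, parse_age_band

__all__ = [
    "CohortConfig",
    "SimulatedCountry",
    "default_cohort_config",
    "simulate_country",
    "make_model_consistent_target",
    "recovery_experiment",
    "RecoveryResult",
]

Stratum = tuple[str, str]  # (sex, age_band)


@dataclass(frozen=True)
class CohortConfig:
    """Study-population configuration for one simulated country.

    ``deaths`` and ``population`` map strata to sizes; ``cause_distribution``
    gives, per stratum, the distribution over underlying-cause categories
    (summing to 1); ``mention_probability`` gives, per stratum, the PD
    mention probability for each non-PD category.  Deaths are fixed counts
    by default; ``poisson_deaths=True`` draws them Poisson with the given
    means.
    """

    deaths: Mapping[Stratum, int]
    population: Mapping[Stratum, int]
    cause_distribution: Mapping[Stratum, Mapping[str, float]]
    mention_probability: Mapping[Stratum, Mapping[str, float]]
    pd_category: str = PD_CATEGORY
    poisson_deaths: bool = False

    def __post_init__(self) -> None:
        strata = set(self.deaths)
        for name, m in (
            ("population", self.population),
            ("cause_distribution", self.cause_distribution),
            ("mention_probability", self.mention_probability),
        ):
            if set(m) != strata:
                raise ValueError(f"{name} strata differ from deaths strata")
        cats = None
        for st in strata:
            sex, band = st
            parse_age_band(band)  # validates the label
            if self.deaths[st] < 0:
                raise ValueError(f"negative deaths in {st}")
            if not self.population[st] > 0:
                raise ValueError(f"non-positive population in {st}")
            if self.deaths[st] > self.population[st]:
                raise ValueError(f"deaths exceed population in {st}")
            dist = self.cause_distribution[st]
            if cats is None:
                cats = set(dist)
            elif set(dist) != cats:
                raise ValueError("category sets differ across strata")
            if self.pd_category not in dist:
                raise ValueError(f"{self.pd_category!r} missing from distribution")
            if any(v < 0 for v in dist.values()) or abs(sum(dist.values()) - 1) > 1e-9:
                raise ValueError(f"cause distribution in {st} is not a distribution")
            probs = self.mention_probability[st]
            if set(probs) != cats - {self.pd_category}:
                raise ValueError(
                    f"mention probabilities in {st} must cover exactly the "
                    "non-PD categories"
                )
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError(f"mention probability outside [0, 1] in {st}")

    @property
    def strata(self) -> list[Stratum]:
        return sorted(self.deaths)

    @property
    def categories(self) -> list[str]:
        return sorted(next(iter(self.cause_distribution.values())))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        """Load from a YAML file with keys ``deaths``, ``population``,
        ``cause_distribution``, ``mention_probability`` (strata written as
        "sex/age_band"), and optional ``pd_category``/``poisson_deaths``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {
            "deaths", "population", "cause_distribution",
            "mention_probability", "pd_category", "poisson_deaths",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def _strat(m, leaf=int):
            return {tuple(k.split("/", 1)): leaf(v) for k, v in m.items()}

        return cls(
            deaths=_strat(raw["deaths"]),
            population=_strat(raw["population"]),
            cause_distribution=_strat(raw["cause_distribution"], dict),
            mention_probability=_strat(raw["mention_probability"], dict),
            pd_category=raw.get("pd_category", PD_CATEGORY),
            poisson_deaths=bool(raw.get("poisson_deaths", False)),
        )


# Default reference-country conditions.  Deaths concentrate in the elderly
# bands where PD deaths occur; the PD underlying-cause share rises with age
# and is scaled up relative to whole-population data so that, at the default
# cohort size of 100 000 deaths, per-stratum PD death counts stay in the
# hundreds-to-thousands range of the real national tables.
_DEFAULT_BANDS = ("55-64", "65-74", "75-84", "85+")
# fraction of all cohort deaths falling in each age band (split evenly by sex)
_DEATH_FRACTION = {"55-64": 0.08, "65-74": 0.24, "75-84": 0.40, "85+": 0.28}
_PD_SHARE = {"55-64": 0.015, "65-74": 0.025, "75-84": 0.035, "85+": 0.040}
_NONPD_MIX = {
    "ischemic_heart_disease": 0.08,
    "malignant_neoplasm": 0.25,
    "cerebrovascular_disease": 0.10,
    "pneumonia": 0.10,
    "other": 0.47,
}
_MENTION_PROB = {
    "ischemic_heart_disease": 0.02,
    "malignant_neoplasm": 0.01,
    "cerebrovascular_disease": 0.025,
    "pneumonia": 0.05,
    "other": 0.03,
}


def default_cohort_config(
    total_deaths: int = 100_000, population_per_stratum: int = 1_000_000
) -> CohortConfig:
    """Reference-country defaults: 2 sexes x 4 elderly age bands, deaths
    split evenly by sex, age-increasing PD share, fixed death counts."""
    deaths, pop, dist, probs = {}, {}, {}, {}
    for sex in ("male", "female"):
        for band in _DEFAULT_BANDS:
            st = (sex, band)
            deaths[st] = int(round(total_deaths * _DEATH_FRACTION[band] / 2))
            pop[st] = population_per_stratum
            s = _PD_SHARE[band]
            scale = (1.0 - s) / sum(_NONPD_MIX.values())
            d = {c: v * scale for c, v in _NONPD_MIX.items()}
            d[PD_CATEGORY] = s
            dist[st] = d
            probs[st] = dict(_MENTION_PROB)
    return CohortConfig(deaths, pop, dist, probs)


@dataclass
class SimulatedCountry:
    """A simulated country's records plus the tables derived from them.

    ``records`` has one row per death: sex, age_band, category, pd_mention.
    ``mention_counts`` counts PD mentions per (sex, age_band, category),
    where PD-underlying deaths count as mentions by definition.  The true
    multiple-cause PD count per stratum is the sum of mention counts over
    categories.
    """

    config: CohortConfig
    records: pd.DataFrame
    uc_table: StratifiedCountTable
    mention_counts: pd.Series

    @property
    def true_multiple_cause(self) -> pd.Series:
        return (
            self.mention_counts.groupby(["sex", "age_band"])
            .sum()
            .reindex(self.uc_table.population.index, fill_value=0)
        )

    def recount(self) -> tuple[pd.Series, pd.Series]:
        """Re-derive (underlying counts, mention counts) from the record
        list; must equal the stored tables exactly."""
        g = self.records.groupby(["sex", "age_band", "category"])
        uc = g.size().reindex(self.uc_table.counts.index, fill_value=0)
        mc = g["pd_mention"].sum().reindex(self.mention_counts.index, fill_value=0)
        return uc.astype("int64"), mc.astype("int64")

    def to_certificates(self) -> list[DeathCertificate]:
        """Render records as minimal certificates: the underlying category on
        Part I line 1, the PD mention (if any) in Part II."""
        certs = []
        pd_cat = self.config.pd_category
        for i, row in enumerate(self.records.itertuples()):
            lo, _ = parse_age_band(row.age_band)
            label = PD_LABEL if row.category == pd_cat else row.category
            part2 = (PD_LABEL,) if (row.pd_mention and row.category != pd_cat) else ()
            certs.append(
                DeathCertificate(
                    id=f"S{i:06d}", sex=row.sex, age_years=lo,
                    part1=(label,), part2=part2,
                )
            )
        return certs


def simulate_country(config: CohortConfig, seed) -> SimulatedCountry:
    """Draw one country's death records under ``config``; reproducible given
    the seed (accepts an int or a ``numpy.random.SeedSequence``)."""
    rng = np.random.default_rng(seed)
    cats = config.categories
    rows = []
    uc_idx, uc_vals, mc_vals = [], [], []
    for st in config.strata:
        sex, band = st
        n = config.deaths[st]
        if config.poisson_deaths:
            n = int(rng.poisson(n))
        p = np.array([config.cause_distribution[st][c] for c in cats])
        counts = rng.multinomial(n, p)
        for c, k in zip(cats, counts):
            if c == config.pd_category:
                mentions = int(k)
            else:
                mentions = int(rng.binomial(k, config.mention_probability[st][c]))
            uc_idx.append((sex, band, c))
            uc_vals.append(int(k))
            mc_vals.append(mentions)
            if k:
                flag = np.zeros(k, dtype=bool)
                flag[:mentions] = True
                rows.append(
                    pd.DataFrame(
                        {
                            "sex": sex,
                            "age_band": band,
                            "category": c,
                            "pd_mention": flag,
                        }
                    )
                )
    index = pd.MultiIndex.from_tuples(uc_idx, names=["sex", "age_band", "category"])
    uc = pd.Series(uc_vals, index=index, dtype="int64")
    mc = pd.Series(mc_vals, index=index, dtype="int64")
    pop = pd.Series(
        {st: config.population[st] for st in config.strata}, dtype="int64"
    )
    pop.index = pd.MultiIndex.from_tuples(pop.index, names=["sex", "age_band"])
    records = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["sex", "age_band", "category", "pd_mention"])
    )
    table = StratifiedCountTable(uc, pop)
    return SimulatedCountry(config, records, table, mc)


def make_model_consistent_target(
    reference: CohortConfig, rate_ratios: float | Mapping[Stratum, float]
) -> CohortConfig:
    """Build a target-country config for which the rate-ratio adjustment is
    exactly correct in expectation: per stratum j with ratio k_j, the target
    PD underlying share is k_j times the reference share (non-PD shares
    rescaled to keep a distribution) and every target mention probability is
    k_j times the reference one."""
    if not isinstance(rate_ratios, Mapping):
        rate_ratios = {st: float(rate_ratios) for st in reference.strata}
    if set(rate_ratios) != set(reference.strata):
        raise ValueError("rate_ratios must cover exactly the reference strata")
    dist, probs = {}, {}
    for st in reference.strata:
        k = rate_ratios[st]
        if k < 0:
            raise ValueError(f"negative rate ratio in {st}")
        s_ref = reference.cause_distribution[st][reference.pd_category]
        s_tgt = k * s_ref
        if s_tgt > 1:
            raise ValueError(f"implied PD share {s_tgt:.3f} > 1 in {st}")
        rest_ref = 1.0 - s_ref
        scale = (1.0 - s_tgt) / rest_ref if rest_ref > 0 else 0.0
        d = {
            c: (s_tgt if c == reference.pd_category else v * scale)
            for c, v in reference.cause_distribution[st].items()
        }
        dist[st] = d
        pr = {}
        for c, p in reference.mention_probability[st].items():
            pt = k * p
            if pt > 1:
                raise ValueError(
                    f"implied mention probability {pt:.3f} > 1 for {c} in {st}"
                )
            pr[c] = pt
        probs[st] = pr
    return replace(
        reference,
        cause_distribution=dist,
        mention_probability=probs,
    )


@dataclass
class RecoveryResult:
    """Per-seed recovery errors plus their summary moments."""

    per_seed: pd.DataFrame  # seed, estimate, truth, rel_error

    @property
    def mean_rel_error(self) -> float:
        return float(self.per_seed["rel_error"].mean())

    @property
    def mean_abs_rel_error(self) -> float:
        return float(self.per_seed["rel_error"].abs().mean())

    @property
    def sd_rel_error(self) -> float:
        return float(self.per_seed["rel_error"].std(ddof=1))


def recovery_experiment(
    reference_config: CohortConfig | None = None,
    rate_ratios: float | Mapping[Stratum, float] = 0.7,
    n_seeds: int = 20,
    base_seed: int = 0,
    mention_scale: float = 1.0,
) -> RecoveryResult:
    """Estimate recovery error over repeated two-country simulations.

    Per seed: simulate the reference country and a model-consistent target,
    run the extrapolation using only the target's underlying-cause table plus
    the reference tables, and compare the estimated total multiple-cause
    count with the target's true count.  ``mention_scale`` != 1 deliberately
    misspecifies the target (its true mention probabilities deviate from the
    model-implied ones by that factor) to study estimator bias.
    """
    from .extrapolation import extrapolate  # local import avoids a cycle

    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if reference_config is None:
        reference_config = default_cohort_config()
    target_config = make_model_consistent_target(reference_config, rate_ratios)
    if mention_scale != 1.0:
        probs = {
            st: {c: min(1.0, mention_scale * p) for c, p in m.items()}
            for st, m in target_config.mention_probability.items()
        }
        target_config = replace(target_config, mention_probability=probs)

    rows = []
    root = np.random.SeedSequence(base_seed)
    for i, child in enumerate(root.spawn(n_seeds)):
        ref_ss, tgt_ss = child.spawn(2)
        ref = simulate_country(reference_config, ref_ss)
        tgt = simulate_country(target_config, tgt_ss)
        res = extrapolate(tgt.uc_table, ref.uc_table, ref.mention_counts)
        est = res.total()
        truth = float(tgt.true_multiple_cause.sum())
        rows.append(
            {
                "seed": i,
                "estimate": est,
                "truth": truth,
                "rel_error": (est - truth) / truth if truth else 0.0,
            }
        )
    return RecoveryResult(pd.DataFrame(rows))
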
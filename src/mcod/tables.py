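"""Stratified count, rate and proportion tables.

Strata are sex x age-band cells.  The default age partition is the nine
bands used in the published Japan/US mortality tables (0-14 ... 75-84, 85+);
any partition of [0, inf) into contiguous bands may be configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "SEXES",
    "DEFAULT_AGE_BANDS",
    "parse_age_band",
    "validate_age_partition",
    "age_to_band",
    "StratifiedCountTable",
    "RateTable",
    "MentionProportionTable",
    "PROPORTION_FLAGS",
]

SEXES = ("male", "female")

DEFAULT_AGE_BANDS = (
    "0-14", "15-24", "25-34", "35-44", "45-54",
    "55-64", "65-74", "75-84", "85+",
)

PROPORTION_FLAGS = ("observed", "adjusted", "forced_unit", "imputed_zero", "capped")


def parse_age_band(label: str) -> tuple[int, int | None]:
    """``"15-24"`` -> (15, 24); ``"85+"`` -> (85, None)."""
    s = label.strip()
    if s.endswith("+"):
        return int(s[:-1]), None
    lo, _, hi = s.partition("-")
    try:
        return int(lo), int(hi)
    except ValueError as exc:
        raise ValueError(f"malformed age band {label!r}") from exc


def validate_age_partition(bands: Sequence[str]) -> tuple[str, ...]:
    """Check the bands tile [0, inf) contiguously, in order, with a single
    open-ended final band."""
    if not bands:
        raise ValueError("empty age partition")
    parsed = [parse_age_band(b) for b in bands]
    if parsed[0][0] != 0:
        raise ValueError("age partition must start at 0")
    for (lo, hi), (nlo, _) in zip(parsed, parsed[1:]):
        if hi is None:
            raise ValueError("open-ended band must be last")
        if nlo != hi + 1:
            raise ValueError(f"age partition gap/overlap at {hi}..{nlo}")
    if parsed[-1][1] is not None:
        raise ValueError("last age band must be open-ended (e.g. '85+')")
    return tuple(bands)


def age_to_band(age: int, bands: Sequence[str] = DEFAULT_AGE_BANDS) -> str:
    if age < 0:
        raise ValueError("negative age")
    for b in bands:
        lo, hi = parse_age_band(b)
        if age >= lo and (hi is None or age <= hi):
            return b
    raise ValueError(f"age {age} not covered by partition")


def _stratum_index(rows: Iterable[tuple[str, str]]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(rows, names=["sex", "age_band"])


@dataclass
class StratifiedCountTable:
    """Underlying-cause death counts by (sex, age band, cause category),
    with population denominators per stratum.

    ``counts`` has MultiIndex (sex, age_band, category); ``population`` has
    MultiIndex (sex, age_band).
    """

    counts: pd.Series
    population: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype("int64")
        self.counts.index = self.counts.index.set_names(
            ["sex", "age_band", "category"]
        )
        self.population.index = self.population.index.set_names(["sex", "age_band"])
        if (self.counts < 0).any():
            raise ValueError("negative death counts")
        stratum_deaths = self.counts.groupby(["sex", "age_band"]).sum()
        pop = self.population.reindex(stratum_deaths.index)
        bad = stratum_deaths[(stratum_deaths > 0) & ~(pop > 0)]
        if len(bad):
            raise ValueError(
                f"strata with deaths but no positive population: {list(bad.index)}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def strata(self) -> pd.MultiIndex:
        return _stratum_index(
            sorted({(s, a) for s, a, _ in self.counts.index})
        )

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.counts.index.get_level_values("category").unique()))

    def category_counts(self, category: str) -> pd.Series:
        """Per-stratum counts for one category, indexed (sex, age_band)."""
        out = self.counts.xs(category, level="category")
        return out.reindex(self.population.index, fill_value=0)

    def stratum_totals(self) -> pd.Series:
        return (
            self.counts.groupby(["sex", "age_band"])
            .sum()
            .reindex(self.population.index, fill_value=0)
        )

    def rate_table(self, category: str, per: float = 100_000.0) -> "RateTable":
        """Death rates for one underlying-cause category."""
        return RateTable(self.category_counts(category), self.population, per=per)

    def collapse(self, keep_category: str, other: str = "other") -> "StratifiedCountTable":
        """Merge every category except ``keep_category`` into ``other``."""
        cat = self.counts.index.get_level_values("category")
        grouping = np.where(cat == keep_category, keep_category, other)
        collapsed = self.counts.groupby(
            [
                self.counts.index.get_level_values("sex"),
                self.counts.index.get_level_values("age_band"),
                pd.Index(grouping, name="category"),
            ]
        ).sum()
        collapsed.index = collapsed.index.set_names(["sex", "age_band", "category"])
        # ensure both categories exist in every stratum
        full = pd.MultiIndex.from_tuples(
            [(s, a, c) for s, a in self.population.index for c in (keep_category, other)],
            names=["sex", "age_band", "category"],
        )
        collapsed = collapsed.reindex(full, fill_value=0)
        return StratifiedCountTable(collapsed, self.population.copy())

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_frames(
        cls, counts: pd.DataFrame, population: pd.DataFrame
    ) -> "StratifiedCountTable":
        """Build from tidy frames: counts(sex, age_band, category, count) and
        population(sex, age_band, population)."""
        c = counts.set_index(["sex", "age_band", "category"])["count"]
        p = population.set_index(["sex", "age_band"])["population"]
        return cls(c, p)

    @classmethod
    def from_csv(cls, counts_path: str | Path, population_path: str | Path):
        return cls.from_frames(pd.read_csv(counts_path), pd.read_csv(population_path))

    def counts_frame(self) -> pd.DataFrame:
        return self.counts.rename("count").reset_index()

    def population_frame(self) -> pd.DataFrame:
        return self.population.rename("population").reset_index()


@dataclass
class RateTable:
    """Per-stratum death rates (per 100 000 by default) plus sex-specific and
    overall totals derived from the same counts and denominators.

    Unrounded values are kept internally; :meth:`rounded` applies the
    publication convention (half-up, one decimal).
    """

    counts: pd.Series
    population: pd.Series
    per: float = 100_000.0

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(self.population.index, fill_value=0)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        zero_pop = self.population[(self.counts > 0) & ~(self.population > 0)]
        if len(zero_pop):
            raise ValueError(f"deaths in zero-population strata: {list(zero_pop.index)}")

    @property
    def rates(self) -> pd.Series:
        """Unrounded per-stratum rates; 0 where the population is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.per * self.counts / self.population
        return r.fillna(0.0).replace([np.inf, -np.inf], 0.0)

    def rounded(self) -> pd.Series:
        return self.rates.map(lambda x: round_half_up(x, 1))

    def total(self, sex: str | None = None, rounded: bool = True) -> float:
        """Crude total rate, overall or for one sex."""
        c, p = self.counts, self.population
        if sex is not None:
            c = c.xs(sex, level="sex")
            p = p.xs(sex, level="sex")
        rate = self.per * c.sum() / p.sum()
        return round_half_up(rate, 1) if rounded else float(rate)


@dataclass
class MentionProportionTable:
    """Conditional mention proportions P(PD mentioned | underlying category)
    per stratum, each carrying a provenance flag.

    ``table`` has MultiIndex (sex, age_band, category) and columns
    ``proportion`` (in [0, 1]) and ``flag`` (one of :data:`PROPORTION_FLAGS`).
    The Parkinson's-disease category is identically 1 (``forced_unit``): a
    certificate with PD as underlying cause necessarily mentions PD.
    """

    table: pd.DataFrame
    pd_category: str = "parkinsons_disease"

    def __post_init__(self) -> None:
        p = self.table["proportion"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("proportions outside [0, 1]")
        bad_flags = set(self.table["flag"]) - set(PROPORTION_FLAGS)
        if bad_flags:
            raise ValueError(f"unknown provenance flags: {sorted(bad_flags)}")
        cat = self.table.index.get_level_values("category")
        pd_rows = self.table.loc[cat == self.pd_category, "proportion"]
        if len(pd_rows) and not (pd_rows == 1.0).all():
            raise ValueError(f"{self.pd_category} proportions must all equal 1")

    @property
    def proportions(self) -> pd.Series:
        return self.table["proportion"]

    @property
    def flags(self) -> pd.Series:
        return self.table["flag"]

    def value(self, sex: str, age_band: str, category: str) -> float:
        return float(self.table.loc[(sex, age_band, category), "proportion"])
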
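"""Cross-national extrapolation of multiple-cause Parkinson's-disease deaths.

Countries without multiple-cause coding publish only underlying-cause death
counts N_ij (stratum j = sex x age band, underlying-cause category i).  A
reference country with multiple-cause coding yields, per stratum and
category, the conditional probability that PD is mentioned on a certificate
given the underlying cause,

    P_ref,j(PD | D_i) = mentions_ij / N_ref,ij .

The target country's probabilities are taken proportional to the reference
ones, rescaled by the ratio of the two countries' stratum-specific
PD-underlying death rates to absorb differences in disease structure:

    P_tgt,j(PD | D_i) = P_ref,j(PD | D_i) * R_tgt,j / R_ref,j ,

with P(PD | PD) = 1 identically.  Estimated multiple-cause deaths are then

    M_ij = N_tgt,ij * P_tgt,j(PD | D_i),     M_j = sum_i M_ij ,

and rates follow by dividing M_j by the target population.  The estimator is
exact when reference and target are the same population, and is a lower
bound M_j >= N_tgt,(PD)j always.

:class:`MultipleCauseModel` bundles the three input tables and policy knobs;
``fit()`` returns a :class:`MultipleCauseResults` with the estimates, the
adjusted proportion table, rates, and an audit log of every cap, imputation
or fallback applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up
from .icd import PD_CATEGORY
from .tables import MentionProportionTable, RateTable, StratifiedCountTable

__all__ = [
    "conditional_mention_proportion",
    "adjust_proportion",
    "stratum_category_deaths",
    "total_multiple_deaths",
    "death_rate",
    "MultipleCauseModel",
    "MultipleCauseResults",
    "extrapolate",
]


def conditional_mention_proportion(
    reference_mentions: pd.Series,
    reference_uc: StratifiedCountTable,
    pd_category: str = PD_CATEGORY,
) -> MentionProportionTable:
    """Observed P(PD mentioned | underlying D_i) per stratum and category.

    ``reference_mentions`` counts certificates mentioning PD, indexed like
    the underlying-cause counts (sex, age_band, category).  PD cells are
    forced to 1; cells with zero underlying deaths get 0 (``imputed_zero``).
    Mentions exceeding the underlying count are a data-consistency error.
    """
    uc = reference_uc.counts
    mentions = reference_mentions.reindex(uc.index, fill_value=0).astype("int64")
    extra = set(reference_mentions.index) - set(uc.index)
    if extra:
        raise ValueError(f"mention cells absent from underlying table: {sorted(extra)[:5]}")
    over = mentions[mentions > uc]
    if len(over):
        raise ValueError(
            f"mentions exceed underlying deaths in cells: {list(over.index)[:5]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = (mentions / uc).to_numpy(dtype=float)
    flags = np.where(uc.to_numpy() > 0, "observed", "imputed_zero")
    prop = np.where(uc.to_numpy() > 0, prop, 0.0)
    is_pd = uc.index.get_level_values("category") == pd_category
    prop = np.where(is_pd, 1.0, prop)
    flags = np.where(is_pd, "forced_unit", flags)
    table = pd.DataFrame({"proportion": prop, "flag": flags}, index=uc.index)
    return MentionProportionTable(table, pd_category=pd_category)


def adjust_proportion(
    p_ref: float,
    r_target: float,
    r_ref: float,
    category: str,
    pd_category: str = PD_CATEGORY,
    zero_reference_rate: str = "error",
) -> tuple[float, str]:
    """Rescale a reference mention proportion by the stratum rate ratio.

    Returns ``(value, flag)``.  Rules: the PD category is 1 regardless of
    rates; a zero target rate gives 0; a zero reference rate with a positive
    target rate is undefined — error by default, or fall back to the
    unadjusted reference proportion when ``zero_reference_rate='unadjusted'``;
    values above 1 are capped (flag ``capped``) since the result must remain
    a probability.
    """
    if not 0.0 <= p_ref <= 1.0:
        raise ValueError(f"reference proportion {p_ref} outside [0, 1]")
    if r_target < 0 or r_ref < 0:
        raise ValueError("negative death rate")
    if category == pd_category:
        return 1.0, "forced_unit"
    if r_target == r_ref:
        # neutral ratio (including the 0/0 limit): the reference proportion
        # carries over unchanged, keeping the estimator exact when reference
        # and target are the same population
        return p_ref, "adjusted"
    if r_target == 0.0:
        return 0.0, "adjusted"
    if r_ref == 0.0:
        if zero_reference_rate == "unadjusted":
            return p_ref, "observed"
        raise ZeroDivisionError(
            "reference PD rate is 0 while target rate is positive; "
            "set zero_reference_rate='unadjusted' to fall back"
        )
    v = p_ref * r_target / r_ref
    if v > 1.0:
        return 1.0, "capped"
    return v, "adjusted"


def stratum_category_deaths(n: float, p: float) -> float:
    """Estimated multiple-cause deaths in one (stratum, category) cell:
    N_ij * P_j(PD | D_i), unrounded."""
    if n < 0:
        raise ValueError("negative count")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion {p} outside [0, 1]")
    return float(n) * float(p)


def total_multiple_deaths(
    m_cells: Mapping[str, float] | pd.Series | Iterable[float],
    categories: Iterable[str] | None = None,
) -> float:
    """Sum the per-category estimates M_ij into the stratum total M_j.

    When ``categories`` is given, every listed category must be present."""
    if isinstance(m_cells, pd.Series):
        cells = m_cells.to_dict()
    elif isinstance(m_cells, Mapping):
        cells = dict(m_cells)
    else:
        cells = {i: v for i, v in enumerate(m_cells)}
        if categories is not None:
            raise ValueError("category check requires labelled cells")
    if categories is not None:
        missing = set(categories) - set(cells)
        if missing:
            raise KeyError(f"missing category cells: {sorted(missing)}")
    return float(sum(cells.values()))


def death_rate(
    count: float, population: float, per: float = 100_000.0, rounded: bool = True
) -> float:
    """Death rate ``per * count / population``; reported half-up to one
    decimal unless ``rounded=False``."""
    if population <= 0:
        raise ValueError("population must be positive")
    r = per * count / population
    return round_half_up(r, 1) if rounded else float(r)


# ---------------------------------------------------------------------------


class MultipleCauseModel:
    """Estimator of a target country's multiple-cause PD deaths from its
    underlying-cause table plus a reference country's mention data.

    Parameters
    ----------
    target_uc : StratifiedCountTable
        Target-country underlying-cause counts and population.
    reference_uc : StratifiedCountTable
        Reference-country underlying-cause counts and population.
    reference_mentions : pd.Series
        Certificates mentioning PD per (sex, age_band, category) in the
        reference country.
    pd_category : str
        Name of the PD category (whose rates drive the adjustment).
    collapse : bool
        Merge all non-PD categories into ``other`` before fitting; use when
        the reference data are only available as aggregate totals.
    zero_reference_rate : {'error', 'unadjusted'}
        Policy when a stratum has target PD deaths but no reference PD
        deaths.
    per : float
        Rate scale (default per 100 000 population).
    """

    def __init__(
        self,
        target_uc: StratifiedCountTable,
        reference_uc: StratifiedCountTable,
        reference_mentions: pd.Series,
        *,
        pd_category: str = PD_CATEGORY,
        collapse: bool = False,
        zero_reference_rate: str = "error",
        per: float = 100_000.0,
    ):
        if zero_reference_rate not in ("error", "unadjusted"):
            raise ValueError(f"unknown zero_reference_rate policy {zero_reference_rate!r}")
        if collapse:
            target_uc = target_uc.collapse(pd_category)
            reference_uc = reference_uc.collapse(pd_category)
            reference_mentions = _collapse_mentions(reference_mentions, pd_category)
        self.target_uc = target_uc
        self.reference_uc = reference_uc
        self.reference_mentions = reference_mentions
        self.pd_category = pd_category
        self.zero_reference_rate = zero_reference_rate
        self.per = per
        self._validate_alignment()

    @classmethod
    def from_csv(
        cls,
        target_counts: str,
        target_population: str,
        reference_counts: str,
        reference_population: str,
        reference_mentions: str,
        **kwargs,
    ) -> "MultipleCauseModel":
        """Build from the CSV dialects: counts(sex, age_band, category,
        count), population(sex, age_band, population); mentions share the
        counts layout."""
        t = StratifiedCountTable.from_csv(target_counts, target_population)
        r = StratifiedCountTable.from_csv(reference_counts, reference_population)
        m = pd.read_csv(reference_mentions).set_index(["sex", "age_band", "category"])[
            "count"
        ]
        return cls(t, r, m, **kwargs)

    def _validate_alignment(self) -> None:
        t_strata = set(map(tuple, self.target_uc.population.index))
        r_strata = set(map(tuple, self.reference_uc.population.index))
        if t_strata != r_strata:
            missing = sorted(t_strata ^ r_strata)
            raise ValueError(f"stratum partitions differ; unmatched strata: {missing}")
        if set(self.target_uc.categories) != set(self.reference_uc.categories):
            raise ValueError(
                "category sets differ between target and reference tables"
            )
        if self.pd_category not in self.target_uc.categories:
            raise ValueError(f"PD category {self.pd_category!r} absent from tables")

    def fit(self) -> "MultipleCauseResults":
        """Run the full estimation pipeline and return the results."""
        p_ref = conditional_mention_proportion(
            self.reference_mentions, self.reference_uc, self.pd_category
        )
        r_tgt = self.target_uc.rate_table(self.pd_category, per=self.per)
        r_ref = self.reference_uc.rate_table(self.pd_category, per=self.per)
        rt, rr = r_tgt.rates, r_ref.rates

        idx = p_ref.table.index
        values = np.empty(len(idx))
        flags = np.empty(len(idx), dtype=object)
        audit: list[dict] = []
        for k, (sex, band, cat) in enumerate(idx):
            v, f = adjust_proportion(
                float(p_ref.table["proportion"].iloc[k]),
                float(rt.loc[(sex, band)]),
                float(rr.loc[(sex, band)]),
                cat,
                pd_category=self.pd_category,
                zero_reference_rate=self.zero_reference_rate,
            )
            values[k] = v
            flags[k] = f
            src = p_ref.table["flag"].iloc[k]
            if src == "imputed_zero" and f == "adjusted":
                flags[k] = "imputed_zero"
            if flags[k] in ("capped", "imputed_zero") or f == "observed":
                audit.append(
                    {
                        "sex": sex,
                        "age_band": band,
                        "category": cat,
                        "event": "fallback_unadjusted" if f == "observed" else flags[k],
                        "proportion": values[k],
                    }
                )
        p_tgt = MentionProportionTable(
            pd.DataFrame({"proportion": values, "flag": flags}, index=idx),
            pd_category=self.pd_category,
        )

        n_tgt = self.target_uc.counts.reindex(idx, fill_value=0)
        m_cells = (n_tgt * p_tgt.proportions).rename("m")
        m_stratum = (
            m_cells.groupby(["sex", "age_band"])
            .sum()
            .reindex(self.target_uc.population.index, fill_value=0.0)
        )
        rate_table = RateTable(m_stratum, self.target_uc.population, per=self.per)
        return MultipleCauseResults(
            model=self,
            proportions_reference=p_ref,
            proportions_target=p_tgt,
            m_cells=m_cells,
            m_stratum=m_stratum,
            rate_table=rate_table,
            audit=pd.DataFrame(
                audit, columns=["sex", "age_band", "category", "event", "proportion"]
            ),
        )


def _collapse_mentions(mentions: pd.Series, pd_category: str) -> pd.Series:
    cat = mentions.index.get_level_values("category")
    grouping = np.where(cat == pd_category, pd_category, "other")
    out = mentions.groupby(
        [
            mentions.index.get_level_values("sex"),
            mentions.index.get_level_values("age_band"),
            pd.Index(grouping, name="category"),
        ]
    ).sum()
    out.index = out.index.set_names(["sex", "age_band", "category"])
    return out


@dataclass
class MultipleCauseResults:
    """Fitted estimates: M_ij cells, stratum totals M_j, rates, the adjusted
    proportion table and the audit log."""

    model: MultipleCauseModel
    proportions_reference: MentionProportionTable
    proportions_target: MentionProportionTable
    m_cells: pd.Series
    m_stratum: pd.Series
    rate_table: RateTable
    audit: pd.DataFrame

    @property
    def m_rounded(self) -> pd.Series:
        """Stratum totals rounded half-up to integers (publication form)."""
        return self.m_stratum.map(lambda x: int(round_half_up(x, 0))).astype("int64")

    def total(self, sex: str | None = None, rounded: bool = False) -> float:
        m = self.m_stratum
        if sex is not None:
            m = m.xs(sex, level="sex")
        t = float(m.sum())
        return float(int(round_half_up(t, 0))) if rounded else t

    def to_frame(self) -> pd.DataFrame:
        """Tidy result table: sex, age_band, M (unrounded), M_rounded, rate."""
        out = pd.DataFrame(
            {
                "M": self.m_stratum,
                "M_rounded": self.m_rounded,
                "rate": self.rate_table.rounded(),
            }
        )
        return out.reset_index()

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        lines = [
            "Multiple-cause death extrapolation",
            "=" * 50,
            f"strata: {len(self.model.target_uc.population)}"
            f"  categories: {len(self.model.target_uc.categories)}",
            f"target underlying PD deaths: "
            f"{int(self.model.target_uc.category_counts(self.model.pd_category).sum())}",
            f"estimated multiple-cause PD deaths: {self.total(rounded=True):.0f}",
            *(
                f"  {sex}: {self.total(sex, rounded=True):.0f}"
                for sex in self.m_stratum.index.get_level_values("sex").unique()
            ),
            f"overall rate per {self.rate_table.per:,.0f}: {self.rate_table.total()}",
            f"audit events (caps/imputations/fallbacks): {len(self.audit)}",
            "",
            self.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)


def extrapolate(
    target_uc: StratifiedCountTable,
    reference_uc: StratifiedCountTable,
    reference_mentions: pd.Series,
    **kwargs,
) -> MultipleCauseResults:
    """Functional one-shot wrapper around
    ``MultipleCauseModel(...).fit()``."""
    return MultipleCauseModel(
        target_uc, reference_uc, reference_mentions, **kwargs
    ).fit()
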
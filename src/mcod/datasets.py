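"""Packaged transcriptions of the published summary tables.

These are hand-transcribed aggregates from the public record (Japan 2008 and
US 2006 national vital statistics, plus the sampled-decedent demographics).
They ship with the package so that every analysis and test runs offline.
The certificate-level microdata behind them are confidential and are NOT
included; synthetic stand-ins come from :mod:`mcod.certificates` and
:mod:`mcod.simulate`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ._util import round_half_up

__all__ = [
    "load_table1_demographics",
    "load_japan_2008_rates",
    "load_us_2006_rates",
    "overall_rate_ratio",
    "sex_total_underlying_deaths",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("mcod.data") / name
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_table1_demographics() -> pd.DataFrame:
    """Demographics of all 4589 PD-underlying decedents vs the 477 sampled
    (Japan 2008)."""
    return _load("table1_demographics.csv")


def load_japan_2008_rates() -> pd.DataFrame:
    """Japan 2008 PD deaths by sex and age band: underlying-cause counts and
    rates, and the published multiple-cause estimates (per 100 000).

    Columns: sex (male/female/total), age_band (nine bands plus 'total'),
    uc_deaths, uc_rate, mc_deaths, mc_rate.
    """
    return _load("table3_japan_2008.csv")


def load_us_2006_rates() -> pd.DataFrame:
    """US 2006 PD deaths by sex and age band, underlying vs multiple cause
    (same layout as :func:`load_japan_2008_rates`)."""
    return _load("table4_us_2006.csv")


def overall_rate_ratio(rates: pd.DataFrame, ndigits: int = 1) -> float:
    """Ratio of the overall multiple-cause rate to the overall
    underlying-cause rate, from a published rate table (half-up rounded)."""
    row = rates[(rates["sex"] == "total") & (rates["age_band"] == "total")]
    if len(row) != 1:
        raise ValueError("rate table lacks a unique overall-total row")
    ratio = float(row["mc_rate"].iloc[0]) / float(row["uc_rate"].iloc[0])
    return round_half_up(ratio, ndigits)


def sex_total_underlying_deaths(rates: pd.DataFrame) -> int:
    """Sum of the sex-specific all-ages underlying-cause death counts."""
    rows = rates[(rates["sex"].isin(["male", "female"])) & (rates["age_band"] == "total")]
    if len(rows) != 2:
        raise ValueError("rate table lacks the two sex-total rows")
    return int(rows["uc_deaths"].sum())
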
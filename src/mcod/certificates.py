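"""Death-certificate data model, cause-role tabulation and fixture building.

A death certificate carries an ordered causal chain in Part I (line 1 is the
immediate cause; later lines are intermediate causes down to the underlying
cause) and, in Part II, contributory conditions outside that chain.  Given
certificate-level records this module classifies every mention into one of
the three roles, ranks mention frequencies per role, and computes any-role
mention prevalences.

Because certificate microdata are confidential, :func:`build_fixture_from_counts`
constructs a synthetic certificate set whose role tabulation reproduces a
published count table exactly; the packaged specification transcribes the
comorbidity table for the 477 sampled Japanese decedents whose underlying
cause was Parkinson's disease (2008).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "ROLES",
    "PD_LABEL",
    "DeathCertificate",
    "RoleTabulation",
    "assign_cause_roles",
    "tabulate_mentions",
    "mention_prevalence",
    "build_fixture_from_counts",
    "load_count_spec",
    "table2_count_spec",
    "table2_fixture",
    "read_certificates_csv",
    "write_certificates_csv",
    "tabulations_to_frame",
]

ROLES = ("immediate", "intermediate", "contributory")

#: label excluded from tabulations by default — every certificate in the
#: study population carries it as the underlying cause
PD_LABEL = "Parkinson's disease"

# Table-1 marginals of the sampled decedents: 208 men / 269 women, with
# sex-specific mean (SD) ages 80.1 (7.2) and 82.7 (6.9)
_SEX_MARGINALS = {"male": 208, "female": 269}
_AGE_MOMENTS = {"male": (80.1, 7.2), "female": (82.7, 6.9)}


@dataclass(frozen=True)
class DeathCertificate:
    """One decedent's cause mentions plus demographics.

    ``part1`` is ordered: line 1 first (the immediate cause).  ``part2`` is
    unordered.  A label may appear at most once per role.
    """

    id: str
    sex: str
    age_years: int
    part1: tuple[str, ...]
    part2: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.part1:
            raise ValueError(f"certificate {self.id}: Part I must be non-empty")
        if self.sex not in ("male", "female"):
            raise ValueError(f"certificate {self.id}: unknown sex {self.sex!r}")
        if self.age_years < 0:
            raise ValueError(f"certificate {self.id}: negative age")
        # a label may appear at most once per role: once on Part I line 1
        # (immediate), once among later Part I lines (intermediate), once in
        # Part II (contributory)
        for role, labels in (
            ("intermediate", self.part1[1:]),
            ("contributory", self.part2),
        ):
            if len(set(labels)) != len(labels):
                raise ValueError(
                    f"certificate {self.id}: duplicate {role} label"
                )


@dataclass(frozen=True)
class RoleTabulation:
    """Ranked mention counts for one cause role.

    ``rows`` are ``(label, count, percent)`` sorted by count descending, ties
    broken alphabetically; ``percent`` uses the number of certificates as the
    denominator, rounded half-up to one decimal.
    """

    role: str
    n_certificates: int
    rows: tuple[tuple[str, int, float], ...]

    def as_dict(self) -> dict[str, tuple[int, float]]:
        return {lab: (cnt, pct) for lab, cnt, pct in self.rows}

    def count(self, label: str) -> int:
        return self.as_dict()[label][0]

    def percent(self, label: str) -> float:
        return self.as_dict()[label][1]


def assign_cause_roles(cert: DeathCertificate) -> list[tuple[str, str]]:
    """Classify each mention: Part I line 1 -> immediate, later Part I lines
    -> intermediate, Part II -> contributory.  Order is preserved."""
    out = [(cert.part1[0], "immediate")]
    out += [(lab, "intermediate") for lab in cert.part1[1:]]
    out += [(lab, "contributory") for lab in cert.part2]
    return out


def tabulate_mentions(
    certs: Sequence[DeathCertificate], exclude: str | None = PD_LABEL
) -> dict[str, RoleTabulation]:
    """Count, per role, the certificates mentioning each label (``exclude``
    dropped), and rank in descending order of frequency."""
    if not certs:
        raise ValueError("no certificates to tabulate")
    n = len(certs)
    counts: dict[str, dict[str, int]] = {r: {} for r in ROLES}
    for cert in certs:
        for label, role in assign_cause_roles(cert):
            if label == exclude:
                continue
            counts[role][label] = counts[role].get(label, 0) + 1
    out = {}
    for role in ROLES:
        ranked = sorted(counts[role].items(), key=lambda kv: (-kv[1], kv[0]))
        rows = tuple(
            (lab, cnt, round_half_up(100.0 * cnt / n, 1)) for lab, cnt in ranked
        )
        out[role] = RoleTabulation(role, n, rows)
    return out


def mention_prevalence(
    certs: Sequence[DeathCertificate],
    label: str,
    roles: Iterable[str] = ROLES,
    vocabulary: Iterable[str] | None = None,
) -> float:
    """Percentage of certificates mentioning ``label`` in any of ``roles``
    (one decimal, half-up); a certificate counts once even if the label
    appears in several roles.

    ``vocabulary`` guards against typos: the label must occur in it, or in
    the certificates themselves.  By default the vocabulary is the set of
    labels observed anywhere in ``certs``.
    """
    roles = set(roles)
    unknown_roles = roles - set(ROLES)
    if unknown_roles:
        raise ValueError(f"unknown roles: {sorted(unknown_roles)}")
    observed = {lab for c in certs for lab, _ in assign_cause_roles(c)}
    vocab = set(vocabulary) if vocabulary is not None else observed
    if label not in vocab | observed:
        raise KeyError(f"label {label!r} not in mention vocabulary")
    hit = sum(
        any(lab == label and role in roles for lab, role in assign_cause_roles(c))
        for c in certs
    )
    return round_half_up(100.0 * hit / len(certs), 1)


# ---------------------------------------------------------------------------
# fixture construction from a published count table


def load_count_spec(path: str | Path) -> pd.DataFrame:
    """Read a role/label/count CSV into a tidy spec frame."""
    spec = pd.read_csv(path)
    missing = {"role", "label", "count"} - set(spec.columns)
    if missing:
        raise ValueError(f"count spec missing columns: {sorted(missing)}")
    return spec


def table2_count_spec() -> pd.DataFrame:
    """The packaged transcription of the published role-stratified mention
    counts for the 477 sampled certificates."""
    ref = resources.files("mcod.data") / "table2_mention_counts.csv"
    with resources.as_file(ref) as p:
        return load_count_spec(p)


def build_fixture_from_counts(
    spec: pd.DataFrame | Mapping[tuple[str, str], int],
    n: int,
    seed: int = 0,
    fill_immediate: str = PD_LABEL,
) -> list[DeathCertificate]:
    """Construct ``n`` certificates whose role tabulation reproduces ``spec``.

    Labels are dealt to certificates round-robin so each label lands on
    distinct certificates across all roles (hence any-role prevalence equals
    the summed role counts).  Certificates left without an immediate cause
    receive ``fill_immediate`` on Part I line 1, which the default tabulation
    excludes.  Sex and age are drawn from the sampled-decedent marginals
    (208 men / 269 women, sex-specific age moments); only these draws use
    ``seed`` — the mention layout is deterministic.
    """
    if isinstance(spec, pd.DataFrame):
        items = [
            (str(r.role), str(r.label), int(r.count)) for r in spec.itertuples()
        ]
    else:
        items = [(role, lab, int(c)) for (role, lab), c in spec.items()]

    for role, lab, c in items:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        if c < 0 or c > n:
            raise ValueError(f"count {c} for ({role}, {lab!r}) infeasible with n={n}")
    seen_rl = set()
    for role, lab, _ in items:
        if (role, lab) in seen_rl:
            raise ValueError(f"duplicate spec entry ({role}, {lab!r})")
        seen_rl.add((role, lab))
    imm_total = sum(c for role, _, c in items if role == "immediate")
    if imm_total > n:
        raise ValueError(f"immediate counts sum to {imm_total} > n={n}")
    label_totals: dict[str, int] = {}
    for _, lab, c in items:
        label_totals[lab] = label_totals.get(lab, 0) + c
    for lab, tot in label_totals.items():
        if tot > n:
            raise ValueError(f"label {lab!r} assigned {tot} > n={n} certificates")

    part1: list[list[str]] = [[] for _ in range(n)]
    part2: list[list[str]] = [[] for _ in range(n)]
    holders: dict[str, set[int]] = {}

    # immediate causes fill the front block contiguously
    cursor = 0
    for role, lab, c in items:
        if role != "immediate":
            continue
        for i in range(cursor, cursor + c):
            part1[i].append(lab)
            holders.setdefault(lab, set()).add(i)
        cursor += c
    for i in range(cursor, n):
        part1[i].append(fill_immediate)

    # intermediate / contributory dealt round-robin, skipping certificates
    # that already hold the label in another role
    for target_role, target in (("intermediate", part1), ("contributory", part2)):
        cur = 0
        for role, lab, c in items:
            if role != target_role:
                continue
            taken = holders.setdefault(lab, set())
            placed = 0
            scanned = 0
            while placed < c:
                if scanned > n:  # full lap without progress: infeasible
                    raise ValueError(
                        f"cannot place {c} mentions of {lab!r} as {role}"
                    )
                i = cur % n
                cur += 1
                scanned += 1
                if i in taken:
                    continue
                target[i].append(lab)
                taken.add(i)
                placed += 1
                scanned = 0

    rng = np.random.default_rng(seed)
    n_male = int(round(n * _SEX_MARGINALS["male"] / sum(_SEX_MARGINALS.values())))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    certs = []
    for i in range(n):
        mu, sd = _AGE_MOMENTS[str(sexes[i])]
        age = int(np.clip(round(rng.normal(mu, sd)), 0, 110))
        certs.append(
            DeathCertificate(
                id=f"C{i:05d}",
                sex=str(sexes[i]),
                age_years=age,
                part1=tuple(part1[i]),
                part2=tuple(part2[i]),
            )
        )
    return certs


def table2_fixture(seed: int = 0) -> list[DeathCertificate]:
    """The packaged 477-certificate fixture reproducing the published
    role-stratified mention counts."""
    return build_fixture_from_counts(table2_count_spec(), n=477, seed=seed)


# ---------------------------------------------------------------------------
# CSV dialect: id, sex, age, part1 ("|"-joined, line 1 first), part2


def write_certificates_csv(certs: Sequence[DeathCertificate], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sex", "age", "part1", "part2"])
        for c in certs:
            w.writerow([c.id, c.sex, c.age_years, "|".join(c.part1), "|".join(c.part2)])


def read_certificates_csv(path: str | Path) -> list[DeathCertificate]:
    certs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "sex", "age", "part1", "part2"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                certs.append(
                    DeathCertificate(
                        id=row["id"],
                        sex=row["sex"],
                        age_years=int(row["age"]),
                        part1=tuple(x for x in row["part1"].split("|") if x),
                        part2=tuple(x for x in (row["part2"] or "").split("|") if x),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not certs:
        raise ValueError(f"{path}: no certificate rows")
    return certs


def tabulations_to_frame(tabs: Mapping[str, RoleTabulation]) -> pd.DataFrame:
    """Flatten role tabulations into a tidy frame (role, rank, label, count,
    percent) mirroring the three-block published layout."""
    rows = []
    for role in ROLES:
        for rank, (lab, cnt, pct) in enumerate(tabs[role].rows, start=1):
            rows.append((role, rank, lab, cnt, pct))
    return pd.DataFrame(rows, columns=["role", "rank", "label", "count", "percent"])
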
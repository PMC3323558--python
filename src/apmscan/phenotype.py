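"""Excess-longevity phenotypes and affected-status selection.

Excess longevity (EL) is observed lifespan minus the expected lifespan for
an individual's sex and birth cohort; familial excess longevity (FEL) is a
kinship-weighted average of EL over an individual's relatives.  Affected
status combines top-quartile EL and FEL (or, for sensitivity analyses, an
attained-age cutoff applied regardless of sex or family history).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree

__all__ = [
    "ExpectedLifespanTable",
    "PhenotypeRecord",
    "SelectionRule",
    "excess_longevity",
    "familial_excess_longevity",
    "compute_phenotypes",
    "select_affected",
    "quartile_thresholds",
]


class CohortError(KeyError):
    """Raised when a (sex, birth cohort) query is not covered by the table."""


class ExpectedLifespanTable:
    """Expected lifespan by sex and birth-cohort band.

    Backed by a DataFrame with columns ``sex``, ``cohort_start``,
    ``cohort_end`` (inclusive years) and ``expected_lifespan``.  A birth year
    inside a band returns that band's value; a year falling in a gap between
    two bands of the same sex is linearly interpolated between band
    midpoints; a year outside the covered range raises :class:`CohortError`.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "cohort_start", "cohort_end", "expected_lifespan"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"expected-lifespan table missing columns {sorted(missing)}")
        if (table["expected_lifespan"] <= 0).any():
            raise ValueError("expected lifespan must be positive")
        self._bands: dict[str, pd.DataFrame] = {}
        for sex, grp in table.groupby("sex"):
            grp = grp.sort_values("cohort_start").reset_index(drop=True)
            if (grp["cohort_end"] < grp["cohort_start"]).any():
                raise ValueError("cohort_end must be >= cohort_start")
            self._bands[str(sex)] = grp

    @classmethod
    def constant(cls, by_sex: Mapping[str, float],
                 cohort_start: int = 1700, cohort_end: int = 2100) -> "ExpectedLifespanTable":
        """A single all-cohort band per sex (useful for simulated data)."""
        rows = [
            {"sex": s, "cohort_start": cohort_start, "cohort_end": cohort_end,
             "expected_lifespan": v}
            for s, v in by_sex.items()
        ]
        return cls(pd.DataFrame(rows))

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(self._bands.values(), ignore_index=True)

    def expected(self, sex: str, birth_year: int) -> float:
        if sex not in self._bands:
            raise CohortError(f"no expected-lifespan entries for sex {sex!r}")
        grp = self._bands[sex]
        hit = grp[(grp["cohort_start"] <= birth_year) & (birth_year <= grp["cohort_end"])]
        if len(hit):
            return float(hit["expected_lifespan"].iloc[0])
        # interpolate between neighbouring band midpoints
        mid = (grp["cohort_start"] + grp["cohort_end"]).to_numpy() / 2.0
        vals = grp["expected_lifespan"].to_numpy(dtype=float)
        if birth_year < grp["cohort_start"].iloc[0] or birth_year > grp["cohort_end"].iloc[-1]:
            raise CohortError(
                f"birth year {birth_year} outside covered cohorts for sex {sex!r}"
            )
        return float(np.interp(birth_year, mid, vals))


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-individual phenotype: EL, FEL (None if no scorable relatives),
    affected status."""

    id: str
    EL: Optional[float]
    FEL: Optional[float]
    affected: bool = False

    def __post_init__(self) -> None:
        if self.affected and (self.EL is None or self.FEL is None):
            raise ValueError("affected individuals must have defined EL and FEL")


@dataclass(frozen=True)
class SelectionRule:
    """Affected-status rule.

    ``mode="el_fel_thresholds"``: affected iff EL >= el_min and FEL >= fel_min
    (closed thresholds).  ``mode="attained_age"``: affected iff attained age
    >= age_min, regardless of sex or family history.
    """

    mode: str = "el_fel_thresholds"
    el_min: float = 3.0
    fel_min: float = 1.75
    age_min: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("el_fel_thresholds", "attained_age"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        for v in (self.el_min, self.fel_min, self.age_min):
            if not np.isfinite(v):
                raise ValueError("selection thresholds must be finite")


def excess_longevity(ind: Individual, table: ExpectedLifespanTable) -> float:
    """EL = observed lifespan - expected lifespan for (sex, birth cohort)."""
    lifespan = ind.lifespan()
    if lifespan is None:
        raise ValueError(f"individual {ind.id!r} has no attained age or lifespan")
    if ind.sex == "unknown":
        raise ValueError(f"individual {ind.id!r} has unknown sex; EL is sex-adjusted")
    if ind.birth_year is None:
        raise ValueError(f"individual {ind.id!r} has no birth year")
    return lifespan - table.expected(ind.sex, ind.birth_year)


def familial_excess_longevity(
    ped: Pedigree, el_by_id: Mapping[str, float], i: str
) -> Optional[float]:
    """Kinship-weighted average EL over i's relatives.

    FEL_i = sum_j w_ij EL_j / sum_j w_ij over j != i with w_ij = 2 phi(i, j)
    > 0 and defined EL_j.  Returns None when no relative contributes.
    """
    num = 0.0
    den = 0.0
    for j, el in el_by_id.items():
        if j == i or el is None or j not in ped:
            continue
        w = 2.0 * ped.kinship(i, j)
        if w > 0.0:
            num += w * el
            den += w
    if den == 0.0:
        return None
    return num / den


def compute_phenotypes(
    ped: Pedigree,
    table: ExpectedLifespanTable,
    ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """EL and FEL for every individual with a scorable lifespan.

    Returns a DataFrame indexed by id with columns ``EL`` and ``FEL``
    (NaN where undefined).  ``ids`` restricts which individuals get rows;
    all scorable individuals always contribute to their relatives' FEL.
    """
    el_by_id: dict[str, float] = {}
    for ind in ped.members:
        try:
            el_by_id[ind.id] = excess_longevity(ind, table)
        except (ValueError, KeyError):
            continue
    wanted = list(ids) if ids is not None else ped.ids
    # kinship is zero across connected components, so FEL only needs the
    # EL values within an individual's own component
    comp_of: dict[str, int] = {}
    comps = ped.components()
    for k, comp in enumerate(comps):
        for iid in comp:
            comp_of[iid] = k
    el_by_comp: list[dict[str, float]] = [
        {j: el_by_id[j] for j in comp if j in el_by_id} for comp in comps
    ]
    rows = []
    for iid in wanted:
        el = el_by_id.get(iid)
        fel = familial_excess_longevity(ped, el_by_comp[comp_of[iid]], iid)
        rows.append({"id": iid, "EL": el, "FEL": fel})
    return pd.DataFrame(rows).set_index("id")


def select_affected(
    records: pd.DataFrame | Iterable[PhenotypeRecord],
    rule: SelectionRule,
    attained_age: Optional[Mapping[str, float]] = None,
) -> set[str]:
    """Apply a :class:`SelectionRule` and return the affected id set.

    ``records`` is the DataFrame from :func:`compute_phenotypes` (or an
    iterable of :class:`PhenotypeRecord`).  For attained-age mode the ages
    mapping must be supplied (or present as an ``attained_age`` column).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [{"id": r.id, "EL": r.EL, "FEL": r.FEL} for r in records]
        ).set_index("id")
    if len(records) == 0:
        raise ValueError("no phenotype records to select from")
    if rule.mode == "el_fel_thresholds":
        mask = (records["EL"] >= rule.el_min) & (records["FEL"] >= rule.fel_min)
        return set(records.index[mask.fillna(False)])
    ages = (
        records["attained_age"]
        if attained_age is None and "attained_age" in records.columns
        else pd.Series(dict(attained_age or {}))
    )
    if ages is None or len(ages) == 0:
        raise ValueError("attained-age selection requires attained ages")
    return set(ages.index[ages >= rule.age_min]) & set(records.index)


def quartile_thresholds(values: Iterable[float]) -> float:
    """75th-percentile cutoff (linear-interpolation quantile).

    Used to derive data-driven top-quartile EL/FEL thresholds for
    :func:`select_affected`.
    """
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 values to define a quartile threshold")
    return float(np.quantile(arr, 0.75, method="linear"))
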
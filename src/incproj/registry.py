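"""Registry-style incidence/population tables and Lexis-grid indexing.

A registry table pairs two equally shaped matrices: observed incidence
counts ``Y`` and person-years at risk ``N``, with calendar years in rows
(ascending) and age groups in columns (increasing, constant width of 1 or
5 years).  All projection models consume this structure; the Lexis
specification records the grid geometry (number of age groups ``I``,
periods ``J``, grid factor ``M``) needed for cohort indexing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RegistryTable",
    "LexisSpec",
    "RegistryValidationError",
    "read_registry_csv",
    "write_registry_csv",
    "filter_age_range",
    "cohort_index",
    "rates",
]


class RegistryValidationError(ValueError):
    """Raised when a registry table violates its structural invariants."""


@dataclass(frozen=True)
class LexisSpec:
    """Geometry of an age x period Lexis grid.

    Parameters
    ----------
    I : int
        Number of age groups.
    J : int
        Number of periods (years).
    M : int
        Grid factor: age-group width divided by period width.  For 5-year
        age groups with yearly data, ``M`` is 5; for single ages, 1.
    """

    I: int
    J: int
    M: int

    def __post_init__(self) -> None:
        if self.I < 1 or self.J < 1 or self.M < 1:
            raise ValueError("I, J and M must be positive integers")

    @property
    def K(self) -> int:
        """Number of distinct cohorts, ``M * (I - 1) + J``."""
        return self.M * (self.I - 1) + self.J


def cohort_index(spec: LexisSpec, i: int, j: int) -> int:
    """Cohort index ``k = j + M * (I - i)`` for 1-based age ``i``, period ``j``.

    The oldest age group (``i = I``) in period ``j`` belongs to cohort
    ``j``; younger groups at the same period were born later, so their
    cohort index is larger by ``M`` per age group.
    """
    if not (1 <= i <= spec.I):
        raise IndexError(f"age index i={i} outside 1..{spec.I}")
    if not (1 <= j <= spec.J):
        raise IndexError(f"period index j={j} outside 1..{spec.J}")
    return j + spec.M * (spec.I - i)


@dataclass(frozen=True)
class RegistryTable:
    """Paired incidence/population matrices on a year x age-group grid.

    Attributes
    ----------
    years : ndarray of int
        Calendar years, strictly ascending with step 1.
    age_lower : ndarray of int
        Lower bound (in years of age) of each age group, strictly
        ascending with constant spacing equal to ``age_width``.
    age_width : int
        Width of every (closed) age group in years: 1 or 5.
    incidence : ndarray of int, shape (len(years), len(age_lower))
        Observed counts ``Y``.
    population : ndarray of float, same shape
        Person-years at risk ``N`` (strictly positive).
    open_top : bool
        Whether the last age group is open-ended ("85+").  Open groups
        are carried through I/O but never retained by the default age
        filter.
    meta : dict
        Optional metadata (entity, sex, registry name) carried into
        metric records.
    """

    years: np.ndarray
    age_lower: np.ndarray
    age_width: int
    incidence: np.ndarray
    population: np.ndarray
    open_top: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        age_lower = np.asarray(self.age_lower, dtype=int)
        Y = np.asarray(self.incidence)
        N = np.asarray(self.population, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "age_lower", age_lower)
        object.__setattr__(self, "incidence", Y)
        object.__setattr__(self, "population", N)
        self._validate()

    def _validate(self) -> None:
        years, age_lower = self.years, self.age_lower
        Y, N = self.incidence, self.population
        if Y.shape != (len(years), len(age_lower)):
            raise RegistryValidationError(
                f"incidence shape {Y.shape} does not match "
                f"({len(years)}, {len(age_lower)})"
            )
        if N.shape != Y.shape:
            raise RegistryValidationError(
                f"population shape {N.shape} != incidence shape {Y.shape}"
            )
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise RegistryValidationError("years must ascend with step 1")
        if self.age_width not in (1, 5):
            raise RegistryValidationError("age-group width must be 1 or 5")
        if len(age_lower) > 1:
            steps = np.diff(age_lower)
            if not np.all(steps == self.age_width):
                raise RegistryValidationError(
                    "age-group lower bounds must ascend with constant width "
                    f"{self.age_width}; got spacings {sorted(set(steps))}"
                )
        if not np.issubdtype(Y.dtype, np.integer):
            if not np.all(Y == np.round(Y)):
                raise RegistryValidationError("incidence must be integer")
            object.__setattr__(self, "incidence", Y.astype(int))
        if np.any(self.incidence < 0):
            r, c = np.argwhere(self.incidence < 0)[0]
            raise RegistryValidationError(
                f"negative incidence at year {years[r]}, "
                f"age group {self.age_labels[c]}"
            )
        if np.any(~(N > 0)):
            r, c = np.argwhere(~(N > 0))[0]
            raise RegistryValidationError(
                f"non-positive population at year {years[r]}, "
                f"age group {self.age_labels[c]}"
            )

    # -- derived views ------------------------------------------------

    @property
    def age_labels(self) -> list[str]:
        labels = []
        for pos, lo in enumerate(self.age_lower):
            last = pos == len(self.age_lower) - 1
            if last and self.open_top:
                labels.append(f"{lo}+")
            elif self.age_width == 1:
                labels.append(str(lo))
            else:
                labels.append(f"{lo}-{lo + self.age_width - 1}")
        return labels

    @property
    def age_mid(self) -> np.ndarray:
        """Midpoint of each (closed) age group."""
        return self.age_lower + (self.age_width - 1) / 2.0

    @property
    def lexis(self) -> LexisSpec:
        return LexisSpec(I=len(self.age_lower), J=len(self.years), M=self.age_width)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_ages(self) -> int:
        return len(self.age_lower)

    def slice_years(self, first: int, last: int) -> "RegistryTable":
        """Sub-table for calendar years ``first..last`` inclusive."""
        mask = (self.years >= first) & (self.years <= last)
        if not mask.any():
            raise RegistryValidationError(f"no years in [{first}, {last}]")
        return replace(
            self,
            years=self.years[mask],
            incidence=self.incidence[mask],
            population=self.population[mask],
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(self.years, name="year")
        cols = self.age_labels
        return (
            pd.DataFrame(self.incidence, index=idx, columns=cols),
            pd.DataFrame(self.population, index=idx, columns=cols),
        )


_AGE_LABEL_RE = re.compile(r"^\s*(\d+)")


def _parse_age_label(label: str) -> tuple[int, bool]:
    """Leading integer of an age-group label; flag open-ended '85+' style."""
    m = _AGE_LABEL_RE.match(str(label))
    if m is None:
        raise RegistryValidationError(f"cannot parse age-group label {label!r}")
    return int(m.group(1)), str(label).strip().endswith("+")


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    try:
        df.index = df.index.astype(int)
    except (TypeError, ValueError) as err:
        raise RegistryValidationError(f"{path}: year column is not integer") from err
    bad = df.columns[df.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
    if len(bad):
        raise RegistryValidationError(f"{path}: non-numeric cells in column {bad[0]!r}")
    return df.sort_index().astype(float)


def read_registry_csv(incidence_path, population_path, meta: dict | None = None) -> RegistryTable:
    """Read a registry table from two CSV files (incidence, population).

    Both files are rectangular: first column the calendar year, one
    column per age group, header cells being either bare lower bounds
    ("20") or range labels ("20-24", "85+").  Row order in the files is
    arbitrary; years are normalized to ascending order.
    """
    inc = _read_matrix(incidence_path)
    pop = _read_matrix(population_path)
    if inc.shape != pop.shape:
        raise RegistryValidationError(
            f"shape mismatch: incidence {inc.shape} vs population {pop.shape}"
        )
    if list(inc.index) != list(pop.index):
        raise RegistryValidationError("incidence and population years differ")
    parsed = [_parse_age_label(c) for c in inc.columns]
    lowers = np.array([p[0] for p in parsed])
    open_top = parsed[-1][1]
    if any(flag for flag, _ in [(p[1], p[0]) for p in parsed[:-1]]):
        raise RegistryValidationError("open-ended age group must be last")
    if len(lowers) > 1:
        widths = np.unique(np.diff(lowers))
        if len(widths) != 1:
            raise RegistryValidationError(
                f"mixed age-group widths {widths.tolist()} are not supported"
            )
        width = int(widths[0])
    else:
        width = 1
    return RegistryTable(
        years=inc.index.to_numpy(),
        age_lower=lowers,
        age_width=width,
        incidence=inc.to_numpy(),
        population=pop.to_numpy(),
        open_top=open_top,
        meta=dict(meta or {}),
    )


def write_registry_csv(t: RegistryTable, incidence_path, population_path) -> None:
    """Write the table back to the two-file CSV dialect (round-trip safe)."""
    inc, pop = t.to_frames()
    inc.to_csv(incidence_path)
    pop.to_csv(population_path)


def filter_age_range(
    t: RegistryTable, min_age: int = 20, max_age: float = 84
) -> RegistryTable:
    """Keep age groups whose full closed interval lies within [min_age, max_age].

    The defaults reproduce the conventional registry analysis range of
    ages 20-84: childhood tumours are excluded below 20 and the
    open-ended 85+ aggregate above 84 (a fixed group width is required
    by the cohort-indexed models).  Open-ended top groups are retained
    only when ``max_age`` is infinite.
    """
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    upper = t.age_lower + t.age_width - 1.0
    if t.open_top and len(t.age_lower):
        upper = upper.astype(float)
        upper[-1] = np.inf
    keep = (t.age_lower >= min_age) & (upper <= max_age)
    if not keep.any():
        raise RegistryValidationError(
            f"no age group fully inside [{min_age}, {max_age}]"
        )
    open_top = bool(t.open_top and keep[-1])
    return replace(
        t,
        age_lower=t.age_lower[keep],
        incidence=t.incidence[:, keep],
        population=t.population[:, keep],
        open_top=open_top,
    )


def rates(t: RegistryTable) -> np.ndarray:
    """Elementwise incidence rates ``Y / N``."""
    return t.incidence / t.population
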
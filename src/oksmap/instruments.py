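"""Oxford Knee Score (OKS) and EQ-5D-5L instrument machinery.

The OKS is a 12-item knee-specific patient-reported outcome.  Each item
is coded 0 (severe) to 4 (very mild); the total ranges 0-48 with 48 the
best health, and is banded into severity categories.

The EQ-5D-5L describes health on five domains — mobility (MO),
self-care (SC), usual activities (UA), pain/discomfort (PD) and
anxiety/depression (AD) — each at five levels, 1 (no problems) to 5
(extreme problems / unable to).  A health state is the 5-digit code
concatenating the domain levels, giving 5**5 = 3,125 states from 11111
(full health) to 55555 (worst health).  A country value set (tariff)
converts a state into a utility index anchored at 1 for full health,
with states worse than dead below 0.

Two value-set dialects are supported:

* ``additive`` — a full-health constant plus per-domain, per-level
  decrements (main-effects tariffs), as delimited text with columns
  ``domain, level, decrement`` and one ``constant`` row;
* ``lookup`` — a complete 3,125-row ``profile_code, utility`` table
  (used for crosswalk tariffs or tariffs with interaction terms).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "OKS_N_ITEMS",
    "SEVERITY_BANDS",
    "EQProfile",
    "ValueSet",
    "total_oks",
    "classify_severity",
    "enumerate_profiles",
    "utility",
    "read_value_set",
    "bundled_value_set_path",
    "bundled_value_sets",
]

#: EQ-5D-5L domain order, fixed everywhere in this package.
DOMAINS = ("MO", "SC", "UA", "PD", "AD")

OKS_N_ITEMS = 12

#: OKS severity bands: inclusive total-score ranges partitioning 0-48.
SEVERITY_BANDS = {
    "severe": (0, 19),
    "moderate": (20, 29),
    "mild": (30, 39),
    "very_mild": (40, 48),
}


def _validate_items(items: Sequence[int]) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (OKS_N_ITEMS,):
        raise ValueError(f"an OKS response has exactly {OKS_N_ITEMS} items, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("OKS items must be integers")
        arr = arr.astype(int)
    if arr.min() < 0 or arr.max() > 4:
        raise ValueError("every OKS item must lie in {0,...,4}")
    return arr


def total_oks(items: Sequence[int]) -> int:
    """Total OKS score: the sum of the 12 item responses (0-48)."""
    return int(_validate_items(items).sum())


def classify_severity(score: int) -> str:
    """Band a total OKS score: severe 0-19, moderate 20-29, mild 30-39, very_mild 40-48."""
    if not 0 <= score <= 48:
        raise ValueError(f"OKS total must lie in [0, 48], got {score}")
    for name, (lo, hi) in SEVERITY_BANDS.items():
        if lo <= score <= hi:
            return name
    raise AssertionError("unreachable: bands partition 0-48")


@dataclass(frozen=True)
class EQProfile:
    """One EQ-5D-5L health state: five domain levels in MO/SC/UA/PD/AD order."""

    levels: tuple[int, int, int, int, int]

    def __post_init__(self):
        if len(self.levels) != 5:
            raise ValueError("an EQ-5D-5L profile has exactly five domain levels")
        if any(not 1 <= l <= 5 for l in self.levels):
            raise ValueError(f"domain levels must lie in 1..5, got {self.levels}")
        object.__setattr__(self, "levels", tuple(int(l) for l in self.levels))

    @property
    def code(self) -> str:
        """The 5-digit profile code, e.g. '11111' for full health."""
        return "".join(str(l) for l in self.levels)

    @classmethod
    def from_code(cls, code: str) -> "EQProfile":
        code = str(code)
        if len(code) != 5 or not code.isdigit():
            raise ValueError(f"a profile code is five digits, got {code!r}")
        return cls(tuple(int(c) for c in code))


def enumerate_profiles() -> list[EQProfile]:
    """All 3,125 EQ-5D-5L states in lexicographic code order, 11111 first."""
    return [EQProfile(levels) for levels in itertools.product(range(1, 6), repeat=5)]


@dataclass
class ValueSet:
    """A country tariff mapping EQ-5D-5L profiles to utilities.

    ``dialect`` is ``additive`` (constant + per-domain decrements) or
    ``lookup`` (complete profile -> utility table).  ``tariff_type`` is
    ``VT`` (direct valuation) or ``CW`` (crosswalk).
    """

    country: str
    tariff_type: str = "VT"
    dialect: str = "additive"
    constant: float = 1.0
    # decrements[domain][level] for levels 2..5; level 1 decrement is 0.
    decrements: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    table: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.dialect not in ("additive", "lookup"):
            raise ValueError(f"unknown value-set dialect {self.dialect!r}")
        if self.tariff_type not in ("VT", "CW"):
            raise ValueError(f"tariff_type must be 'VT' or 'CW', got {self.tariff_type!r}")
        if self.dialect == "additive":
            missing = [d for d in DOMAINS if d not in self.decrements]
            if missing:
                raise ValueError(f"additive value set missing domains: {missing}")
            for d in DOMAINS:
                levels = set(self.decrements[d])
                if levels != {2, 3, 4, 5}:
                    raise ValueError(f"domain {d} must give decrements for levels 2..5, got {sorted(levels)}")
        else:
            if len(self.table) != 5**5:
                missing = self._missing_codes()
                raise ValueError(
                    f"lookup value set must cover all 3125 profiles exactly once; "
                    f"{len(self.table)} rows given"
                    + (f"; first missing code {missing[0]}" if missing else "")
                )

    def _missing_codes(self) -> list[str]:
        return [p.code for p in enumerate_profiles() if p.code not in self.table]

    def to_lookup(self) -> "ValueSet":
        """Materialize an additive tariff as a full 3,125-row lookup table."""
        if self.dialect == "lookup":
            return self
        table = {p.code: utility(p, self) for p in enumerate_profiles()}
        return ValueSet(
            country=self.country, tariff_type=self.tariff_type, dialect="lookup", table=table
        )


def utility(profile: EQProfile, vs: ValueSet) -> float:
    """Utility index of ``profile`` under value set ``vs``.

    Additive dialect: full-health constant minus the sum of level
    decrements for each domain at level > 1.  Lookup dialect: table
    retrieval; a missing code is an error.
    """
    if vs.dialect == "lookup":
        try:
            return float(vs.table[profile.code])
        except KeyError:
            raise KeyError(f"profile {profile.code} missing from lookup value set {vs.country!r}")
    u = vs.constant
    for domain, level in zip(DOMAINS, profile.levels):
        if level > 1:
            u -= vs.decrements[domain][level]
    return float(u)


def utilities(profiles: Iterable[EQProfile], vs: ValueSet) -> np.ndarray:
    """Vectorized :func:`utility` over an iterable of profiles."""
    return np.array([utility(p, vs) for p in profiles], dtype=float)


# ---------------------------------------------------------------------------
# value-set I/O


def read_value_set(path, dialect: str, country: str | None = None, tariff_type: str = "VT") -> ValueSet:
    """Read a value set from delimited text.

    ``additive`` schema: columns ``domain, level, decrement``; domains
    MO/SC/UA/PD/AD with levels 2-5, plus one row with domain
    ``constant`` giving the full-health value (level column ignored).

    ``lookup`` schema: columns ``profile_code, utility`` covering all
    3,125 profiles exactly once.
    """
    path = Path(path)
    if dialect == "additive":
        df = pd.read_csv(path, dtype={"domain": str})
        required = {"domain", "level", "decrement"}
        if not required.issubset(df.columns):
            raise ValueError(f"additive value set {path} must have columns {sorted(required)}")
        if not np.issubdtype(np.asarray(df["decrement"]).dtype, np.number):
            raise ValueError(f"non-numeric decrement values in {path}")
        const_rows = df[df["domain"].str.lower() == "constant"]
        if len(const_rows) != 1:
            raise ValueError(f"additive value set {path} needs exactly one 'constant' row")
        constant = float(const_rows["decrement"].iloc[0])
        body = df[df["domain"].str.lower() != "constant"]
        decrements: dict[str, dict[int, float]] = {d: {} for d in DOMAINS}
        for _, row in body.iterrows():
            d = str(row["domain"]).upper()
            if d not in DOMAINS:
                raise ValueError(f"unknown domain {row['domain']!r} in {path}")
            level = int(row["level"])
            if not 2 <= level <= 5:
                raise ValueError(f"additive decrements are for levels 2..5, got {level} in {path}")
            if level in decrements[d]:
                raise ValueError(f"duplicate decrement for {d} level {level} in {path}")
            decrements[d][level] = float(row["decrement"])
        return ValueSet(
            country=country or path.stem,
            tariff_type=tariff_type,
            dialect="additive",
            constant=constant,
            decrements=decrements,
        )
    if dialect == "lookup":
        df = pd.read_csv(path, dtype={"profile_code": str})
        required = {"profile_code", "utility"}
        if not required.issubset(df.columns):
            raise ValueError(f"lookup value set {path} must have columns {sorted(required)}")
        codes = df["profile_code"].astype(str).str.zfill(5)
        dupes = codes[codes.duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate profile rows in {path}: {sorted(dupes.unique())[:5]}")
        if not np.issubdtype(np.asarray(df["utility"]).dtype, np.number):
            raise ValueError(f"non-numeric utilities in {path}")
        table = dict(zip(codes, df["utility"].astype(float)))
        if len(table) != 5**5:
            missing = [p.code for p in enumerate_profiles() if p.code not in table]
            raise ValueError(
                f"lookup value set {path} has {len(table)} profiles, expected 3125; "
                f"missing codes start with {missing[:3]}"
            )
        return ValueSet(
            country=country or path.stem, tariff_type=tariff_type, dialect="lookup", table=table
        )
    raise ValueError(f"unknown dialect {dialect!r}; expected 'additive' or 'lookup'")


def write_value_set(vs: ValueSet, path) -> None:
    """Write a value set back to delimited text in its own dialect."""
    path = Path(path)
    if vs.dialect == "additive":
        rows = [{"domain": "constant", "level": 0, "decrement": vs.constant}]
        for d in DOMAINS:
            for level in (2, 3, 4, 5):
                rows.append({"domain": d, "level": level, "decrement": vs.decrements[d][level]})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        pd.DataFrame(
            {"profile_code": list(vs.table), "utility": list(vs.table.values())}
        ).to_csv(path, index=False)


def bundled_value_set_path(name: str) -> Path:
    """Path to a bundled toy value-set file (``toy_additive``, ``toy_lookup``,
    or ``synthetic_egypt_vt``)."""
    ref = resources.files("oksmap") / "data" / f"{name}.csv"
    return Path(str(ref))


def bundled_value_sets() -> list[ValueSet]:
    """The two bundled toy value sets (one per dialect).

    These are illustrative tariffs for tests and examples only — they are
    not any country's published weights.  Real tariffs load through
    :func:`read_value_set` with the same schemas.
    """
    return [
        read_value_set(bundled_value_set_path("toy_additive"), "additive", country="ToyLand", tariff_type="VT"),
        read_value_set(bundled_value_set_path("toy_lookup"), "lookup", country="ToyLookupia", tariff_type="CW"),
    ]
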
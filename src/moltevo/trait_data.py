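"""Species trait tables: molt scoring, dichotomization and separation checks.

The data model mirrors a comparative study design for European passerines:
one row per species carrying a molt record (presence of a winter--spring
molt, the calendar months in which it occurs, its extent, and the feather
tracts replaced) together with ecological and sexual-selection predictors
(migration 1-5, habitat 1-6, aerial foraging 0-2, winter gregariousness
1-4, log body mass, a dichromatism score and a sexual-selection index).

Two timing conventions for scoring the winter--spring ("pre-alternate")
molt are supported: an *inclusive* rule in which any November-through-spring
molt counts, and a *strict* rule in which a molt confined to November and
December is reassigned to the post-breeding (pre-basic) molt.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Month",
    "MoltObservation",
    "SpeciesRecord",
    "SpeciesTable",
    "DichotomizationScheme",
    "BinaryTraitPair",
    "classify_prealternate",
    "classify_extent",
    "classify_tracts",
    "dichotomize",
    "enumerate_schemes",
    "detect_separation",
    "normalize_species_name",
    "read_species_table",
    "write_species_table",
]

FLIGHT_TRACTS = frozenset({"primaries", "secondaries", "tertials", "rectrices"})
NONFLIGHT_TRACTS = frozenset({"wing-coverts", "head", "body"})
ALL_TRACTS = FLIGHT_TRACTS | NONFLIGHT_TRACTS

ORDINAL_RANGES = {
    "migration": (1, 5),
    "habitat": (1, 6),
    "aerial_foraging": (0, 2),
    "gregariousness": (1, 4),
}


class Month(enum.Enum):
    """Calendar months, stored by name to avoid 0/1-based index ambiguity."""

    JANUARY = "January"
    FEBRUARY = "February"
    MARCH = "March"
    APRIL = "April"
    MAY = "May"
    JUNE = "June"
    JULY = "July"
    AUGUST = "August"
    SEPTEMBER = "September"
    OCTOBER = "October"
    NOVEMBER = "November"
    DECEMBER = "December"

    @classmethod
    def parse(cls, token: str) -> "Month":
        token = token.strip()
        for m in cls:
            if m.value.lower() == token.lower():
                return m
        raise ValueError(f"unknown month name: {token!r}")


EARLY_WINTER = frozenset({Month.NOVEMBER, Month.DECEMBER})


class TraitDataError(ValueError):
    """Raised on invalid trait records or degenerate transformations."""


@dataclass(frozen=True)
class MoltObservation:
    """One species' winter--spring molt record.

    ``extent`` is 'none', 'partial' or 'complete'.  The invariants couple
    the three fields: a species without the molt has no months, no tracts
    and extent 'none'; a species with it has at least one month and tract.
    """

    has_winter_spring_molt: bool
    molt_months: frozenset = frozenset()
    extent: str = "none"
    tracts: frozenset = frozenset()

    def __post_init__(self):
        months = frozenset(
            Month.parse(m) if isinstance(m, str) else m for m in self.molt_months
        )
        object.__setattr__(self, "molt_months", months)
        tracts = frozenset(t.strip().lower() for t in self.tracts)
        object.__setattr__(self, "tracts", tracts)
        self.validate()

    def validate(self) -> None:
        if self.extent not in ("none", "partial", "complete"):
            raise TraitDataError(f"invalid extent {self.extent!r}")
        if not self.tracts <= ALL_TRACTS:
            raise TraitDataError(
                f"unknown feather tracts: {sorted(self.tracts - ALL_TRACTS)}"
            )
        if self.has_winter_spring_molt:
            if self.extent == "none":
                raise TraitDataError("molting species must have partial/complete extent")
            if not self.molt_months:
                raise TraitDataError("molting species must record at least one month")
            if not self.tracts:
                raise TraitDataError("molting species must record at least one tract")
        else:
            if self.extent != "none" or self.molt_months or self.tracts:
                raise TraitDataError(
                    "species without winter-spring molt must have extent 'none', "
                    "no months and no tracts"
                )


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    body_mass: float
    dichromatism: float
    sexual_selection: float
    migration: int
    habitat: int
    aerial_foraging: int
    gregariousness: int
    molt: MoltObservation
    # Optional per-species override for sexually dimorphic molt patterns
    # (e.g. Oriolus oriolus: complete in males, partial in females).
    molt_override_female: MoltObservation | None = None

    def __post_init__(self):
        if self.body_mass <= 0:
            raise TraitDataError(f"{self.species}: body mass must be > 0")
        if self.dichromatism < 0:
            raise TraitDataError(f"{self.species}: dichromatism must be >= 0")
        for name in ORDINAL_RANGES:
            lo, hi = ORDINAL_RANGES[name]
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and lo <= v <= hi):
                raise TraitDataError(
                    f"{self.species}: {name}={v!r} outside ordinal range {lo}..{hi}"
                )

    @property
    def log_body_mass(self) -> float:
        return float(np.log10(self.body_mass))


def normalize_species_name(name: str) -> str:
    """Trim, collapse internal whitespace and join with underscores.

    Produces labels comparable with Newick tip labels, where spaces are
    conventionally replaced by underscores.
    """
    return "_".join(name.split())


# ---------------------------------------------------------------------------
# molt classification


def classify_prealternate(molt: MoltObservation, timing_rule: str = "inclusive") -> int:
    """Score the presence of a pre-alternate (winter--spring) molt as 0/1.

    ``timing_rule='inclusive'``: any recorded winter--spring molt scores 1.
    ``timing_rule='strict'``: a molt occurring *only* in November and/or
    December is treated as part of the pre-basic molt and scores 0.
    """
    molt.validate()
    if timing_rule not in ("inclusive", "strict"):
        raise ValueError(f"unknown timing rule {timing_rule!r}")
    if not molt.has_winter_spring_molt:
        return 0
    if timing_rule == "inclusive":
        return 1
    return int(bool(molt.molt_months - EARLY_WINTER))


def classify_extent(molt: MoltObservation) -> str:
    """Return 'partial' or 'complete'; errors on species without the molt."""
    molt.validate()
    if not molt.has_winter_spring_molt:
        raise TraitDataError("extent undefined for species without pre-alternate molt")
    return molt.extent


def classify_tracts(molt: MoltObservation) -> str:
    """Classify the molted tracts as 'nonflight_only' or 'includes_flight'.

    Flight feathers are primaries, secondaries, tertials and rectrices;
    nonflight tracts are wing coverts, head and body feathers.
    """
    molt.validate()
    if not molt.tracts:
        raise TraitDataError("no tracts recorded")
    return "nonflight_only" if molt.tracts <= NONFLIGHT_TRACTS else "includes_flight"


# ---------------------------------------------------------------------------
# dichotomization


@dataclass(frozen=True)
class DichotomizationScheme:
    """A rule turning an ordinal or continuous predictor into two states.

    ``kind='ordinal-cut'``: ``cut`` is a level; values strictly above it
    score 1.  ``kind='continuous-stat'``: ``stat`` is one of mean, median,
    q25, q75 computed on the supplied values; values at or above the cut
    score 1 (ties go to state 1).  ``kind='identity'`` passes a binary
    variable through unchanged.
    """

    variable: str
    kind: str
    cut: float | None = None
    stat: str | None = None

    def __post_init__(self):
        if self.kind not in ("ordinal-cut", "continuous-stat", "identity"):
            raise TraitDataError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "ordinal-cut" and self.cut is None:
            raise TraitDataError("ordinal-cut scheme requires a cut level")
        if self.kind == "continuous-stat" and self.stat not in (
            "mean",
            "median",
            "q25",
            "q75",
        ):
            raise TraitDataError(f"unknown continuous statistic {self.stat!r}")

    def describe(self) -> str:
        if self.kind == "ordinal-cut":
            return f"{self.variable}: >{self.cut:g} -> 1"
        if self.kind == "continuous-stat":
            return f"{self.variable}: >= {self.stat} -> 1"
        return f"{self.variable}: identity"


_STATS = {
    "mean": np.mean,
    "median": np.median,
    "q25": lambda v: np.quantile(v, 0.25),  # linear-interpolation (type-7)
    "q75": lambda v: np.quantile(v, 0.75),
}


def dichotomize(values: Sequence[float], scheme: DichotomizationScheme) -> np.ndarray:
    """Apply a dichotomization scheme; both output states must be present."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise TraitDataError("empty input")
    if np.unique(v).size < 2 and scheme.kind != "identity":
        raise TraitDataError("constant input: dichotomization is degenerate")
    if scheme.kind == "identity":
        if not set(np.unique(v)) <= {0.0, 1.0}:
            raise TraitDataError("identity scheme requires a 0/1 variable")
        out = v.astype(int)
    elif scheme.kind == "ordinal-cut":
        out = (v > scheme.cut).astype(int)
    else:
        cut = float(_STATS[scheme.stat](v))
        out = (v >= cut).astype(int)  # tie at the cut scores 1
    if scheme.kind != "identity" and np.unique(out).size < 2:
        raise TraitDataError(
            f"scheme {scheme.describe()} is degenerate on these data "
            "(only one output state)"
        )
    return out


def enumerate_schemes(
    variable: str,
    values: Sequence[float],
    kind: str = "auto",
) -> list[DichotomizationScheme]:
    """All admissible dichotomization schemes for one predictor.

    An ordinal variable with K observed levels yields K-1 cut points (one
    between every adjacent pair of observed levels); a continuous variable
    yields the four summary-statistic cuts (mean, median, lower and upper
    quartile); a binary variable yields the single identity scheme.
    """
    v = np.asarray(values, dtype=float)
    levels = np.unique(v)
    if levels.size < 2:
        raise TraitDataError(f"{variable}: constant variable")
    if kind == "auto":
        if set(levels) <= {0.0, 1.0}:
            kind = "binary"
        elif np.allclose(levels, np.round(levels)) and levels.size <= 10:
            kind = "ordinal"
        else:
            kind = "continuous"
    if kind == "binary":
        return [DichotomizationScheme(variable, "identity")]
    if kind == "ordinal":
        return [
            DichotomizationScheme(variable, "ordinal-cut", cut=float(levels[i]))
            for i in range(levels.size - 1)
        ]
    if kind == "continuous":
        return [
            DichotomizationScheme(variable, "continuous-stat", stat=s)
            for s in ("mean", "median", "q25", "q75")
        ]
    raise TraitDataError(f"unknown variable kind {kind!r}")


@dataclass(frozen=True)
class BinaryTraitPair:
    """Two aligned 0/1 trait vectors over an ordered taxon list.

    ``inverted_orientation`` marks pairs in which state 0 of one trait is
    biologically associated with state 1 of the other; the temporal-order
    comparisons of the directional test battery swap accordingly.
    """

    taxa: tuple
    trait_x: np.ndarray
    trait_y: np.ndarray
    inverted_orientation: bool = False

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(self.taxa))
        x = np.asarray(self.trait_x, dtype=int)
        y = np.asarray(self.trait_y, dtype=int)
        if not (len(self.taxa) == x.size == y.size):
            raise TraitDataError("taxa and trait vectors must have equal lengths")
        for name, v in (("trait_x", x), ("trait_y", y)):
            if not set(np.unique(v)) <= {0, 1}:
                raise TraitDataError(f"{name} must be 0/1")
        object.__setattr__(self, "trait_x", x)
        object.__setattr__(self, "trait_y", y)

    def joint_states(self) -> np.ndarray:
        """Joint state index per taxon: 0=(0,0), 1=(0,1), 2=(1,0), 3=(1,1)."""
        return 2 * self.trait_x + self.trait_y


# ---------------------------------------------------------------------------
# separation


def detect_separation(
    outcome: Sequence[int], predictors: pd.DataFrame
) -> tuple[bool, list[str]]:
    """Flag (quasi-)separation: a predictor stratum perfectly predicting y.

    A discrete predictor is flagged when some observed level co-occurs with
    only one outcome value; a continuous predictor when the sign of its
    centered values does.  This is deliberately conservative — sparse levels
    trigger the flag — because the downstream remedy (a proper zero-mean
    normal prior on the fixed effects) is harmless when applied needlessly.
    """
    y = np.asarray(outcome, dtype=int)
    if y.size == 0 or len(predictors) == 0:
        raise TraitDataError("empty input")
    if len(predictors) != y.size:
        raise TraitDataError("outcome and predictors have different lengths")
    offenders: list[str] = []
    if np.unique(y).size < 2:
        return True, ["<constant outcome>"]
    for col in predictors.columns:
        x = np.asarray(predictors[col], dtype=float)
        levels = np.unique(x)
        if levels.size <= 10 and np.allclose(levels, np.round(levels)):
            strata = x
        else:
            strata = np.sign(x - x.mean())
        for s in np.unique(strata):
            if np.unique(y[strata == s]).size == 1:
                offenders.append(col)
                break
    return bool(offenders), offenders


# ---------------------------------------------------------------------------
# table container and IO


#: canonical column order of the on-disk TSV layout
TABLE_COLUMNS = [
    "species",
    "body_mass",
    "dichromatism",
    "sexual_selection",
    "migration",
    "habitat",
    "aerial_foraging",
    "gregariousness",
    "has_winter_spring_molt",
    "molt_months",
    "extent",
    "tracts",
]


@dataclass
class SpeciesTable:
    """Validated collection of species records with derived binary variables."""

    records: list[SpeciesRecord]

    def __post_init__(self):
        names = [r.species for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TraitDataError(f"duplicate species labels: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def molt_presence(self, timing_rule: str = "inclusive") -> np.ndarray:
        return np.array(
            [classify_prealternate(r.molt, timing_rule) for r in self.records]
        )

    def molt_extent_binary(self, timing_rule: str = "inclusive") -> pd.Series:
        """Extent scored complete=1 / partial=0, for molting species only."""
        keep = self.molt_presence(timing_rule).astype(bool)
        vals = {}
        for r, k in zip(self.records, keep):
            if k:
                vals[r.species] = int(classify_extent(r.molt) == "complete")
        return pd.Series(vals, name="extent")

    def predictor_frame(self, predictors: Iterable[str]) -> pd.DataFrame:
        cols = {}
        for p in predictors:
            if p == "log_body_mass":
                cols[p] = [r.log_body_mass for r in self.records]
            else:
                cols[p] = [getattr(r, p) for r in self.records]
        return pd.DataFrame(cols, index=self.species, dtype=float)

    def subset(self, species: Iterable[str]) -> "SpeciesTable":
        wanted = set(species)
        missing = wanted - set(self.species)
        if missing:
            raise TraitDataError(f"unknown species: {sorted(missing)}")
        return SpeciesTable([r for r in self.records if r.species in wanted])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "species": r.species,
                    "body_mass": r.body_mass,
                    "dichromatism": r.dichromatism,
                    "sexual_selection": r.sexual_selection,
                    "migration": r.migration,
                    "habitat": r.habitat,
                    "aerial_foraging": r.aerial_foraging,
                    "gregariousness": r.gregariousness,
                    "has_winter_spring_molt": int(r.molt.has_winter_spring_molt),
                    "molt_months": ",".join(
                        sorted((m.value for m in r.molt.molt_months))
                    ),
                    "extent": r.molt.extent,
                    "tracts": ";".join(sorted(r.molt.tracts)),
                }
            )
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _record_from_row(row: Mapping) -> SpeciesRecord:
    months = [t for t in str(row["molt_months"]).split(",") if t.strip()]
    tracts = [t for t in str(row["tracts"]).split(";") if t.strip()]
    molt = MoltObservation(
        has_winter_spring_molt=bool(int(row["has_winter_spring_molt"])),
        molt_months=frozenset(months),
        extent=str(row["extent"]),
        tracts=frozenset(tracts),
    )
    return SpeciesRecord(
        species=normalize_species_name(str(row["species"])),
        body_mass=float(row["body_mass"]),
        dichromatism=float(row["dichromatism"]),
        sexual_selection=float(row["sexual_selection"]),
        migration=int(row["migration"]),
        habitat=int(row["habitat"]),
        aerial_foraging=int(row["aerial_foraging"]),
        gregariousness=int(row["gregariousness"]),
        molt=molt,
    )


def read_species_table(
    path, column_map: Mapping[str, str] | None = None, sep: str = "\t"
) -> SpeciesTable:
    """Read a species trait TSV.

    ``column_map`` maps canonical column names to the file's header names,
    so externally archived layouts can be ingested without editing the file.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TraitDataError(f"missing required columns: {missing}")
    return SpeciesTable([_record_from_row(row) for _, row in df.iterrows()])


def write_species_table(table: SpeciesTable, path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)
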
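"""Survey data model: belt-transect fish records, seagrass cover, aggregation.

The sampling unit is a 25 x 4 m belt transect (100 m^2) surveyed by
underwater visual census inside a seagrass bed.  Every fish seen on the
transect is recorded with its species, family, functional group and a body
length visually estimated to the nearest 5 cm; seagrass bottom cover is
estimated to the nearest 10% in six 0.25 m^2 quadrats per transect.  Sites
are either inside a marine protected area (``MPA``) or fished
(``open``), and each site is revisited in three monsoon seasons: short
rains (``SR``), long rains (``LR``) and the dry season (``D``).

This module defines the record types, validation, CSV round-trip I/O,
age-class staging by fractional maximum length, and the aggregation of raw
records into species x sample density tables used by every downstream
analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

SEASONS: tuple[str, ...] = ("SR", "LR", "D")
MANAGEMENT_LEVELS: tuple[str, ...] = ("MPA", "open")
AGE_CLASSES: tuple[str, ...] = ("juvenile", "subadult", "adult")

#: Default transect footprint in m^2 (25 x 4 m belt).
DEFAULT_TRANSECT_AREA = 100.0

#: Densities are reported per this many m^2, so on the default transect the
#: density equals the raw count.
DENSITY_UNIT_AREA = 100.0


@dataclass(frozen=True)
class FishObservation:
    """A single fish seen on a transect."""

    species: str
    family: str = ""
    functional_group: str = ""
    length_cm: float = 5.0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label must be nonempty")
        if self.length_cm <= 0:
            raise ValueError(f"length_cm must be positive, got {self.length_cm}")
        if self.length_cm % 5 != 0:
            raise ValueError(
                f"length_cm={self.length_cm} is not a multiple of 5 cm "
                "(lengths are recorded to the nearest 5 cm)"
            )


@dataclass
class TransectRecord:
    """One surveyed transect: site context, fish list and quadrat covers."""

    site: str
    management: str
    season: str
    transect_id: str
    fish: list[FishObservation] = field(default_factory=list)
    quadrat_cover_pct: list[float] = field(default_factory=list)
    area_m2: float = DEFAULT_TRANSECT_AREA

    @property
    def sample_id(self) -> str:
        return f"{self.site}:{self.season}:{self.transect_id}"


@dataclass
class SurveyDesign:
    """Study layout: sites with management level and transect replication.

    The default emulates the field design: four sites (two protected, two
    fished), 10 transects each except one protected site with 7, revisited
    in all three seasons — (10 + 10 + 10 + 7) x 3 = 111 transect records.
    """

    sites: list[tuple[str, str, int]]
    seasons: tuple[str, ...] = SEASONS

    @classmethod
    def default(cls) -> "SurveyDesign":
        return cls(
            sites=[
                ("mpa1", "MPA", 10),
                ("mpa2", "MPA", 7),
                ("open1", "open", 10),
                ("open2", "open", 10),
            ]
        )

    @property
    def n_transect_records(self) -> int:
        return sum(n for _, _, n in self.sites) * len(self.seasons)

    def site_management(self) -> dict[str, str]:
        return {s: m for s, m, _ in self.sites}


@dataclass
class AgeClassRule:
    """Length cut-points mapping body length to juvenile/subadult/adult.

    Staging uses half-open intervals [0, c1) -> juvenile, [c1, c2) ->
    subadult, [c2, inf) -> adult, so a length exactly on a cut-point goes to
    the upper class.  Cut-points may be given per species; otherwise they
    default to one third and two thirds of the species' maximum length, a
    standard fraction-of-Lmax staging when published stage tables are
    unavailable.
    """

    cuts: dict[str, tuple[float, float]] = field(default_factory=dict)
    default: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for sp, (c1, c2) in self.cuts.items():
            _check_cuts(c1, c2, sp)
        if self.default is not None:
            _check_cuts(*self.default, "<default>")

    @classmethod
    def from_lmax(cls, lmax_cm: dict[str, float],
                  overrides: dict[str, tuple[float, float]] | None = None,
                  default: tuple[float, float] | None = None) -> "AgeClassRule":
        cuts = {sp: (lm / 3.0, 2.0 * lm / 3.0) for sp, lm in lmax_cm.items()}
        if overrides:
            cuts.update(overrides)
        return cls(cuts=cuts, default=default)

    def cut_points(self, species: str) -> tuple[float, float]:
        if species in self.cuts:
            return self.cuts[species]
        if self.default is not None:
            return self.default
        raise KeyError(
            f"no age-class cut-points for species {species!r} and no default rule"
        )


def _check_cuts(c1: float, c2: float, label: str) -> None:
    if not (0 < c1 < c2):
        raise ValueError(f"cut-points for {label} must satisfy 0 < c1 < c2, got ({c1}, {c2})")


def assign_age_class(obs: FishObservation, rule: AgeClassRule) -> str:
    """Stage one fish as juvenile, subadult or adult by its length."""
    c1, c2 = rule.cut_points(obs.species)
    if obs.length_cm < c1:
        return "juvenile"
    if obs.length_cm < c2:
        return "subadult"
    return "adult"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str]
    transect_counts: pd.DataFrame  # index site, columns season, values counts
    n_records: int

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_survey(records: Sequence[TransectRecord],
                    design: SurveyDesign | None = None) -> ValidationReport:
    """Check schema conformance and tally transects per site and season.

    Collects (rather than raises) violations: unknown season or management
    labels, covers outside [0, 100], non-positive areas, bad fish lengths,
    and duplicate transect ids within a site x season cell.  If a design is
    given, per-cell transect counts are compared against it.
    """
    violations: list[str] = []
    seen: set[tuple[str, str, str]] = set()
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.site, rec.season, rec.transect_id)
        if key in seen:
            violations.append(
                f"duplicate transect_id {rec.transect_id!r} in {rec.site}/{rec.season}"
            )
        seen.add(key)
        counts[(rec.site, rec.season)] = counts.get((rec.site, rec.season), 0) + 1
        if rec.season not in SEASONS:
            violations.append(f"{rec.sample_id}: unknown season {rec.season!r}")
        if rec.management not in MANAGEMENT_LEVELS:
            violations.append(f"{rec.sample_id}: unknown management {rec.management!r}")
        if rec.area_m2 <= 0:
            violations.append(f"{rec.sample_id}: non-positive area {rec.area_m2}")
        for c in rec.quadrat_cover_pct:
            if not (0 <= c <= 100):
                violations.append(f"{rec.sample_id}: cover {c}% outside [0, 100]")
    if design is not None:
        want = {(s, season): n for s, _, n in design.sites for season in design.seasons}
        for cell, n_expected in want.items():
            n_got = counts.get(cell, 0)
            if n_got != n_expected:
                violations.append(
                    f"site {cell[0]} season {cell[1]}: {n_got} transects, design says {n_expected}"
                )
    sites = sorted({s for s, _ in counts})
    seasons = [s for s in SEASONS if any(k[1] == s for k in counts)] or list(SEASONS)
    tab = pd.DataFrame(0, index=sites, columns=seasons, dtype=int)
    for (site, season), n in counts.items():
        if season in tab.columns:
            tab.loc[site, season] = n
    return ValidationReport(violations=violations, transect_counts=tab,
                            n_records=len(records))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class DensityTable:
    """Species x sample density matrix with sample grouping labels.

    ``values`` is a samples x species DataFrame; ``sample_info`` is aligned
    row-wise and carries site, management, season and (at transect level)
    transect id.  The species set is the union over the whole survey so
    tables stay conformable across seasons, sites and age-class filters.
    """

    values: pd.DataFrame
    sample_info: pd.DataFrame
    level: Literal["transect", "site"]
    aggregation: Literal["sum", "mean"]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("density values must be nonnegative")
        if not self.values.index.equals(self.sample_info.index):
            raise ValueError("values and sample_info indices must align")
        if not self.values.index.is_unique:
            raise ValueError("sample labels must be unique")

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def subset(self, mask: pd.Series) -> "DensityTable":
        return DensityTable(self.values.loc[mask], self.sample_info.loc[mask],
                            self.level, self.aggregation)

    def to_frame(self) -> pd.DataFrame:
        """Grouping columns and species densities in one tidy frame."""
        return pd.concat([self.sample_info, self.values], axis=1)


def mean_cover(record: TransectRecord) -> float:
    """Average quadrat cover of one transect, in percent."""
    if not record.quadrat_cover_pct:
        raise ValueError(f"{record.sample_id}: no quadrat cover values")
    return float(np.mean(record.quadrat_cover_pct))


def aggregate_density(records: Sequence[TransectRecord],
                      level: Literal["transect", "site"] = "transect",
                      aggregation: Literal["sum", "mean"] = "sum",
                      age_filter: str | None = None,
                      rule: AgeClassRule | None = None) -> DensityTable:
    """Turn raw transect records into a species x sample density table.

    At transect level each row is one transect with per-species counts
    scaled to individuals per 100 m^2 (equal to the raw count on the default
    transect).  At site level transect rows within each site x season are
    combined by ``aggregation`` (``sum`` matches pooled site-level community
    data; ``mean`` gives mean density per species, site and season).
    ``age_filter`` restricts counts to one age class while keeping the full
    species set, so filtered tables stay conformable.
    """
    if not records:
        raise ValueError("no transect records to aggregate")
    if age_filter is not None:
        if age_filter not in AGE_CLASSES:
            raise ValueError(f"unknown age class {age_filter!r}; expected one of {AGE_CLASSES}")
        if rule is None:
            raise ValueError("age_filter requires an AgeClassRule")

    species = sorted({obs.species for rec in records for obs in rec.fish})
    sp_index = {sp: j for j, sp in enumerate(species)}
    rows = np.zeros((len(records), len(species)))
    info_rows = []
    ids = []
    for i, rec in enumerate(records):
        for obs in rec.fish:
            if age_filter is not None and assign_age_class(obs, rule) != age_filter:
                continue
            rows[i, sp_index[obs.species]] += 1
        rows[i] *= DENSITY_UNIT_AREA / rec.area_m2
        ids.append(rec.sample_id)
        info_rows.append({"site": rec.site, "management": rec.management,
                          "season": rec.season, "transect": rec.transect_id})
    values = pd.DataFrame(rows, index=ids, columns=species)
    info = pd.DataFrame(info_rows, index=ids)
    if level == "transect":
        return DensityTable(values, info, "transect", aggregation)
    if level != "site":
        raise ValueError(f"unknown level {level!r}")

    group = info.groupby(["site", "season"], sort=True)
    agg = group.apply(lambda g: getattr(values.loc[g.index], aggregation)(axis=0),
                      include_groups=False)
    site_ids = [f"{site}:{season}" for site, season in agg.index]
    site_values = pd.DataFrame(agg.values, index=site_ids, columns=species)
    site_info = pd.DataFrame(
        {"site": [s for s, _ in agg.index], "season": [se for _, se in agg.index]},
        index=site_ids)
    mgmt = info.drop_duplicates("site").set_index("site")["management"]
    site_info["management"] = site_info["site"].map(mgmt)
    return DensityTable(site_values, site_info[["site", "management", "season"]],
                        "site", aggregation)


def cover_table(records: Sequence[TransectRecord],
                level: Literal["transect", "site"] = "transect") -> pd.DataFrame:
    """Mean seagrass cover per transect (or averaged per site x season)."""
    rows = [{"sample": r.sample_id, "site": r.site, "management": r.management,
             "season": r.season, "transect": r.transect_id,
             "cover_pct": mean_cover(r)} for r in records]
    df = pd.DataFrame(rows).set_index("sample")
    if level == "transect":
        return df
    out = (df.groupby(["site", "management", "season"], sort=True)["cover_pct"]
             .mean().reset_index())
    out.index = out["site"] + ":" + out["season"]
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

FISH_COLUMNS = ["site", "management", "season", "transect", "species", "family",
                "functional_group", "length_cm"]
COVER_COLUMNS = ["site", "management", "season", "transect", "quadrat", "cover_pct"]
SPECIES_COLUMNS = ["species", "family", "functional_group", "lmax_cm"]


def _open_write(path_or_file):
    if hasattr(path_or_file, "write"):
        import contextlib
        return contextlib.nullcontext(path_or_file)
    return open(path_or_file, "w", newline="", encoding="utf-8")


def write_survey_csv(records: Sequence[TransectRecord], fish_path, cover_path) -> None:
    """Serialize records to the two long-format survey CSVs (UTF-8)."""
    with _open_write(fish_path) as fh:
        w = csv.writer(fh)
        w.writerow(FISH_COLUMNS)
        for rec in records:
            for obs in rec.fish:
                w.writerow([rec.site, rec.management, rec.season, rec.transect_id,
                            obs.species, obs.family, obs.functional_group,
                            _fmt(obs.length_cm)])
    with _open_write(cover_path) as fh:
        w = csv.writer(fh)
        w.writerow(COVER_COLUMNS)
        for rec in records:
            for q, c in enumerate(rec.quadrat_cover_pct, start=1):
                w.writerow([rec.site, rec.management, rec.season, rec.transect_id,
                            q, _fmt(c)])


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_survey_csv(fish_path, cover_path) -> list[TransectRecord]:
    """Read the fish and cover CSVs back into transect records.

    A transect appearing in the cover file but holding no fish yields a
    record with an empty fish list, so empty transects survive a round trip.
    """
    fish = pd.read_csv(fish_path, dtype={"site": str, "transect": str, "species": str})
    cover = pd.read_csv(cover_path, dtype={"site": str, "transect": str})
    for df, cols, path in ((fish, FISH_COLUMNS, fish_path), (cover, COVER_COLUMNS, cover_path)):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")

    keys: list[tuple] = []
    meta: dict[tuple, tuple] = {}
    for df in (cover, fish):
        for row in df.itertuples(index=False):
            k = (row.site, row.season, row.transect)
            if k not in meta:
                keys.append(k)
                meta[k] = (row.management,)
    records = {}
    for k in keys:
        site, season, transect = k
        records[k] = TransectRecord(site=site, management=meta[k][0], season=season,
                                    transect_id=str(transect))
    for row in cover.itertuples(index=False):
        records[(row.site, row.season, row.transect)].quadrat_cover_pct.append(
            float(row.cover_pct))
    for row in fish.itertuples(index=False):
        records[(row.site, row.season, row.transect)].fish.append(
            FishObservation(species=row.species, family=str(row.family),
                            functional_group=str(row.functional_group),
                            length_cm=float(row.length_cm)))
    return [records[k] for k in keys]


def write_species_table(species_info: pd.DataFrame, path) -> None:
    species_info.to_csv(path, index=False)


def read_species_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def rule_from_species_table(df: pd.DataFrame) -> AgeClassRule:
    """Build an age-class rule from a species table.

    Explicit ``cut1_cm``/``cut2_cm`` columns override the Lmax/3, 2Lmax/3
    default staging.
    """
    lmax = dict(zip(df["species"], df["lmax_cm"]))
    overrides = {}
    if "cut1_cm" in df.columns and "cut2_cm" in df.columns:
        for row in df.itertuples(index=False):
            c1, c2 = getattr(row, "cut1_cm"), getattr(row, "cut2_cm")
            if pd.notna(c1) and pd.notna(c2):
                overrides[row.species] = (float(c1), float(c2))
    return AgeClassRule.from_lmax(lmax, overrides=overrides)
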
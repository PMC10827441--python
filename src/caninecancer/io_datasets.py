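"""Breed-table ingestion and dataset assembly.

Reads and writes delimited per-breed mortality tables, builds consensus
adult weights from heterogeneous weight sources, removes accidental
(trauma) deaths from cause-of-death proportions, merges breed forms
(e.g. miniature and standard Dachshund) into single records, and places
independently collected datasets on a common mortality scale using their
shared breeds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INBREEDING_MEASURES",
    "BreedRecord",
    "DatasetTable",
    "WeightSources",
    "BreedTableError",
    "read_breed_table",
    "write_breed_table",
    "exclude_trauma",
    "consensus_weight",
    "hierarchical_mean",
    "merge_breed_forms",
    "normalize_shared",
    "combine_means",
    "load_default_breed_forms",
    "load_default_clades",
]

#: Inbreeding proxies the association stage understands. Values are consumed
#: as published numbers; nothing here estimates them from genotypes.
INBREEDING_MEASURES = ("SNP", "WGS", "ROH", "HOM", "MHC")


class BreedTableError(ValueError):
    """Raised for malformed or invariant-violating breed tables."""


def _canon(name: str) -> str:
    """Case-insensitive, whitespace-trimmed breed-name key."""
    return " ".join(str(name).split()).casefold()


@dataclass
class BreedRecord:
    """One breed: the unit of analysis.

    ``weight_kg`` is the consensus adult body weight W and
    ``cancer_mortality`` the proportion of deaths (at any age) due to
    cancer, optionally already corrected for trauma deaths.
    """

    breed_name: str
    weight_kg: float
    cancer_mortality: float
    n_deaths: int | None = None
    trauma_fraction: float | None = None
    clade: str | None = None
    observed_lifespan_years: float | None = None
    inbreeding: dict[str, float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.breed_name or not str(self.breed_name).strip():
            problems.append("empty breed name")
        if not (self.weight_kg > 0):
            problems.append(f"weight_kg must be positive, got {self.weight_kg!r}")
        if not (0.0 <= self.cancer_mortality <= 1.0):
            problems.append(
                f"cancer_mortality must be in [0, 1], got {self.cancer_mortality!r}"
            )
        if self.n_deaths is not None and self.n_deaths < 0:
            problems.append(f"n_deaths must be nonnegative, got {self.n_deaths!r}")
        if self.trauma_fraction is not None:
            if not (0.0 <= self.trauma_fraction <= 1.0):
                problems.append(
                    f"trauma_fraction must be in [0, 1], got {self.trauma_fraction!r}"
                )
            elif self.trauma_fraction + self.cancer_mortality > 1.0 + 1e-12:
                problems.append(
                    "trauma_fraction + cancer_mortality exceeds 1 "
                    f"({self.trauma_fraction} + {self.cancer_mortality})"
                )
        return problems


@dataclass
class DatasetTable:
    """A named collection of breed records (one source, e.g. US/UK/FINN)."""

    source_id: str
    records: list[BreedRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise BreedTableError(f"dataset {self.source_id!r} has no records")
        seen: set[str] = set()
        for rec in self.records:
            key = _canon(rec.breed_name)
            if key in seen:
                raise BreedTableError(
                    f"duplicate breed {rec.breed_name!r} in dataset {self.source_id!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def breed_names(self) -> list[str]:
        return [r.breed_name for r in self.records]

    def get(self, breed_name: str) -> BreedRecord | None:
        key = _canon(breed_name)
        for rec in self.records:
            if _canon(rec.breed_name) == key:
                return rec
        return None

    def weights(self) -> np.ndarray:
        return np.array([r.weight_kg for r in self.records], dtype=float)

    def mortalities(self) -> np.ndarray:
        return np.array([r.cancer_mortality for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "breed": r.breed_name,
                "weight": r.weight_kg,
                "cancer_mortality": r.cancer_mortality,
                "n_deaths": r.n_deaths,
                "trauma_fraction": r.trauma_fraction,
                "clade": r.clade,
                "observed_lifespan": r.observed_lifespan_years,
            }
            for m in INBREEDING_MEASURES:
                row[m] = r.inbreeding.get(m)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class WeightSources:
    """Per-source, per-sex adult weight ranges for one breed.

    ``per_source`` maps source name -> sex label -> (low, high) in kg,
    either bound optional (``None``). ``reference_source`` anchors the
    outlier screen and is never itself removed.
    """

    per_source: dict[str, dict[str, tuple[float | None, float | None]]]
    reference_source: str | None = None

    def __post_init__(self) -> None:
        if not self.per_source:
            raise ValueError("at least one weight source is required")
        for src, sexes in self.per_source.items():
            for sex, (lo, hi) in sexes.items():
                if lo is not None and hi is not None and lo > hi:
                    raise ValueError(
                        f"source {src!r} sex {sex!r}: low {lo} exceeds high {hi}"
                    )


# ---------------------------------------------------------------------------
# Reading / writing


_REQUIRED = ("breed", "weight", "cancer_mortality")
_OPTIONAL = ("n_deaths", "trauma_fraction", "clade", "observed_lifespan")


def read_breed_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    source_id: str | None = None,
    sep: str | None = None,
) -> DatasetTable:
    """Read a delimited breed table into a validated :class:`DatasetTable`.

    ``dialect`` maps canonical field names (``breed``, ``weight``,
    ``cancer_mortality``, the optional fields, and the inbreeding measure
    names SNP/WGS/ROH/HOM/MHC) to the file's column names. Unmapped
    canonical names fall back to identically named columns. Column names
    are never guessed beyond this explicit map. The delimiter is taken
    from the extension (``.tsv`` -> tab, otherwise comma) unless ``sep``
    is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)

    dialect = dict(dialect or {})
    colmap: dict[str, str] = {}
    for canonical in (*_REQUIRED, *_OPTIONAL, *INBREEDING_MEASURES):
        col = dialect.get(canonical, canonical)
        if col in df.columns:
            colmap[canonical] = col
    missing = [c for c in _REQUIRED if c not in colmap]
    if missing:
        raise BreedTableError(
            f"{path}: required column(s) {missing} not resolvable "
            f"(columns present: {list(df.columns)})"
        )

    records: list[BreedRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            weight = float(row[colmap["weight"]])
            mortality = float(row[colmap["cancer_mortality"]])
        except (TypeError, ValueError):
            errors.append(f"row {i}: non-numeric weight or cancer_mortality")
            continue

        def _opt(name: str, cast=float):
            col = colmap.get(name)
            if col is None:
                return None
            val = row[col]
            if pd.isna(val) or val == "":
                return None
            return cast(val)

        inbreeding = {}
        for m in INBREEDING_MEASURES:
            v = _opt(m)
            if v is not None:
                inbreeding[m] = v
        rec = BreedRecord(
            breed_name=str(row[colmap["breed"]]).strip(),
            weight_kg=weight,
            cancer_mortality=mortality,
            n_deaths=_opt("n_deaths", lambda v: int(round(float(v)))),
            trauma_fraction=_opt("trauma_fraction"),
            clade=_opt("clade", str),
            observed_lifespan_years=_opt("observed_lifespan"),
            inbreeding=inbreeding,
        )
        problems = rec.validate()
        if problems:
            errors.append(f"row {i} ({rec.breed_name!r}): " + "; ".join(problems))
        else:
            records.append(rec)
    if errors:
        raise BreedTableError(f"{path}: invalid rows:\n  " + "\n  ".join(errors))
    return DatasetTable(source_id=source_id or path.stem, records=records)


def write_breed_table(table: DatasetTable, path: str | Path, sep: str | None = None) -> Path:
    """Write a dataset back to a delimited file (inverse of reading)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = table.to_frame()
    # Drop all-empty optional columns so round trips stay tidy.
    keep = [c for c in df.columns if c in ("breed", "weight", "cancer_mortality") or df[c].notna().any()]
    df[keep].to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# Trauma exclusion


def exclude_trauma(record: BreedRecord) -> BreedRecord:
    """Remove accidental (trauma) deaths from the cause-of-death proportion.

    Mortality proportions are renormalised to the non-trauma denominator:
    p' = p / (1 - trauma_fraction). Death counts shrink by the same factor.
    """
    if record.trauma_fraction is None:
        raise ValueError(f"{record.breed_name!r}: trauma_fraction not available")
    t = record.trauma_fraction
    if t >= 1.0:
        raise ZeroDivisionError(
            f"{record.breed_name!r}: trauma_fraction = 1 leaves no non-trauma deaths"
        )
    new_p = record.cancer_mortality / (1.0 - t)
    new_n = record.n_deaths
    if new_n is not None:
        new_n = int(round(new_n * (1.0 - t)))
    return replace(
        record, cancer_mortality=new_p, n_deaths=new_n, trauma_fraction=None
    )


# ---------------------------------------------------------------------------
# Consensus weights


def hierarchical_mean(ranges: Mapping[str, tuple[float | None, float | None]]) -> float:
    """Mean of per-sex (low, high) ranges: within sex first, then between.

    A missing bound contributes nothing; a sex with no bounds is skipped.
    """
    sex_means = []
    for bounds in ranges.values():
        vals = [b for b in bounds if b is not None]
        if vals:
            sex_means.append(float(np.mean(vals)))
    if not sex_means:
        raise ValueError("no numeric bounds in any sex")
    return float(np.mean(sex_means))


def consensus_weight(sources: WeightSources) -> float:
    """Consensus adult weight across heterogeneous sources.

    Each source is reduced to a single value hierarchically (within sex,
    then between sexes); sources are then screened iteratively: a value is
    dropped when it deviates from the mean of the remaining values by more
    than 3 standard errors of those remaining values. The reference
    (anchor) source is never removable. The consensus is the mean of the
    surviving values. A single source is returned unscreened; with two
    sources screening is impossible and both are kept.
    """
    per_source: dict[str, float] = {}
    for src, sexes in sources.per_source.items():
        try:
            per_source[src] = hierarchical_mean(sexes)
        except ValueError:
            continue
    if not per_source:
        raise ValueError("no weight source provides a numeric bound")
    if len(per_source) == 1:
        return next(iter(per_source.values()))

    surviving = dict(per_source)
    ref = sources.reference_source
    while len(surviving) >= 3:
        worst_src, worst_excess = None, 0.0
        for src, value in surviving.items():
            if src == ref:
                continue
            rest = [v for s, v in surviving.items() if s != src]
            se = float(np.std(rest, ddof=1)) / math.sqrt(len(rest))
            dev = abs(value - float(np.mean(rest)))
            if se > 0 and dev > 3.0 * se and dev / se > worst_excess:
                worst_src, worst_excess = src, dev / se
        if worst_src is None:
            break
        del surviving[worst_src]
    return float(np.mean(list(surviving.values())))


# ---------------------------------------------------------------------------
# Breed-form merging

FormSpec = Sequence  # nested lists of form names


def _resolve_forms(spec, lookup) -> float | None:
    """Hierarchical mean over a nested form spec; None if nothing resolves."""
    if isinstance(spec, str):
        return lookup(spec)
    vals = [v for v in (_resolve_forms(s, lookup) for s in spec) if v is not None]
    if not vals:
        return None
    return float(np.mean(vals))


def merge_breed_forms(
    table: DatasetTable, form_map: Mapping[str, FormSpec]
) -> DatasetTable:
    """Collapse breed forms into single canonical records.

    ``form_map`` maps a canonical breed name to a nested list of form
    names; inner lists are averaged first (e.g. the two miniature
    Dachshunds are averaged, then that value is averaged with the
    standard form). Forms absent from the table are ignored; numeric
    fields are hierarchical means over the present forms.
    """
    if not form_map:
        return table

    def _flatten(spec) -> list[str]:
        if isinstance(spec, str):
            return [spec]
        out: list[str] = []
        for s in spec:
            out.extend(_flatten(s))
        return out

    consumed: set[str] = set()
    merged: list[BreedRecord] = []
    for canonical, spec in form_map.items():
        form_names = _flatten(spec)
        form_keys = {_canon(f) for f in form_names}
        present = [f for f in form_names if table.get(f) is not None]
        if not present:
            continue
        existing = table.get(canonical)
        if existing is not None and _canon(canonical) not in form_keys:
            raise BreedTableError(
                f"canonical name {canonical!r} collides with an existing breed"
            )
        consumed |= {k for k in form_keys if any(_canon(r.breed_name) == k for r in table)}

        def _field(attr):
            def lookup(name: str):
                rec = table.get(name)
                if rec is None:
                    return None
                return getattr(rec, attr)

            return _resolve_forms(spec, lookup)

        first = table.get(present[0])
        clades = {table.get(f).clade for f in present if table.get(f).clade}
        n_deaths = _field("n_deaths")
        inbreeding: dict[str, float] = {}
        for m in INBREEDING_MEASURES:
            v = _resolve_forms(spec, lambda n: (table.get(n) or BreedRecord("", 1, 0)).inbreeding.get(m))
            if v is not None:
                inbreeding[m] = v
        merged.append(
            BreedRecord(
                breed_name=canonical,
                weight_kg=_field("weight_kg"),
                cancer_mortality=_field("cancer_mortality"),
                n_deaths=None if n_deaths is None else int(round(n_deaths)),
                trauma_fraction=_field("trauma_fraction"),
                clade=clades.pop() if len(clades) == 1 else first.clade,
                observed_lifespan_years=_field("observed_lifespan_years"),
                inbreeding=inbreeding,
            )
        )

    kept = [r for r in table if _canon(r.breed_name) not in consumed]
    return DatasetTable(source_id=table.source_id, records=kept + merged)


# ---------------------------------------------------------------------------
# Cross-dataset normalisation


def _shared_stats(table: DatasetTable, shared: Sequence[str]) -> tuple[float, float]:
    vals = []
    for name in shared:
        rec = table.get(name)
        if rec is None:
            raise BreedTableError(
                f"shared breed {name!r} missing from dataset {table.source_id!r}"
            )
        vals.append(rec.cancer_mortality)
    arr = np.asarray(vals, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def normalize_shared(
    tables: Sequence[DatasetTable], shared_breeds: Sequence[str]
) -> list[DatasetTable]:
    """Place datasets on a common mortality scale via their shared breeds.

    Each table's cancer mortalities are affinely rescaled so that its
    shared-breed subset acquires the across-table average mean and
    (sample) standard deviation of those subsets. The map is applied to
    every record of the table, not only the shared breeds.
    """
    if len(tables) < 2:
        raise ValueError("normalisation needs at least two tables")
    if len(shared_breeds) < 3:
        raise ValueError("normalisation needs at least three shared breeds")
    stats = [_shared_stats(t, shared_breeds) for t in tables]
    for (m, s), t in zip(stats, tables):
        if s <= 1e-12 * max(abs(m), 1.0):
            raise ZeroDivisionError(
                f"dataset {t.source_id!r} has zero variance over the shared breeds"
            )
    m_star = float(np.mean([m for m, _ in stats]))
    s_star = float(np.mean([s for _, s in stats]))
    out = []
    for (m_d, s_d), t in zip(stats, tables):
        scale = s_star / s_d
        recs = [
            replace(r, cancer_mortality=m_star + (r.cancer_mortality - m_d) * scale)
            for r in t
        ]
        out.append(DatasetTable(source_id=t.source_id, records=recs))
    return out


def load_default_breed_forms() -> dict[str, list]:
    """The shipped, editable breed-form mapping (miniature/standard forms)."""
    import importlib.resources

    import yaml

    text = (
        importlib.resources.files("caninecancer") / "data" / "breed_forms.yaml"
    ).read_text()
    return yaml.safe_load(text)


def load_default_clades() -> dict[str, str]:
    """The shipped, editable breed -> clade mapping (partial; extend freely)."""
    import importlib.resources

    import yaml

    text = (
        importlib.resources.files("caninecancer") / "data" / "clades.yaml"
    ).read_text()
    return yaml.safe_load(text)


def combine_means(
    tables: Sequence[DatasetTable], min_sources: int = 2, source_id: str = "combined"
) -> DatasetTable:
    """Per-breed unweighted means across (normalised) datasets.

    Keeps every breed appearing in at least ``min_sources`` tables;
    cancer mortality and weight are plain means of the per-table values,
    death counts are summed when available in every contributing table.
    """
    if min_sources > len(tables):
        raise ValueError(
            f"min_sources={min_sources} exceeds the number of tables ({len(tables)})"
        )
    by_breed: dict[str, list[BreedRecord]] = {}
    display: dict[str, str] = {}
    for t in tables:
        for r in t:
            key = _canon(r.breed_name)
            by_breed.setdefault(key, []).append(r)
            display.setdefault(key, r.breed_name)
    records = []
    for key, recs in by_breed.items():
        if len(recs) < min_sources:
            continue
        n_deaths = None
        if all(r.n_deaths is not None for r in recs):
            n_deaths = int(sum(r.n_deaths for r in recs))
        lifespans = [
            r.observed_lifespan_years for r in recs if r.observed_lifespan_years is not None
        ]
        inbreeding: dict[str, float] = {}
        for m in INBREEDING_MEASURES:
            vals = [r.inbreeding[m] for r in recs if m in r.inbreeding]
            if vals:
                inbreeding[m] = float(np.mean(vals))
        clades = [r.clade for r in recs if r.clade]
        records.append(
            BreedRecord(
                breed_name=display[key],
                weight_kg=float(np.mean([r.weight_kg for r in recs])),
                cancer_mortality=float(np.mean([r.cancer_mortality for r in recs])),
                n_deaths=n_deaths,
                clade=clades[0] if clades else None,
                observed_lifespan_years=float(np.mean(lifespans)) if lifespans else None,
                inbreeding=inbreeding,
            )
        )
    if not records:
        raise BreedTableError("no breed meets the min_sources requirement")
    return DatasetTable(source_id=source_id, records=records)
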
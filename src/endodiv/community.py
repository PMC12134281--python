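"""Data model and IO for culture-based endophyte isolate inventories.

The unit of observation is a *morphospecies record*: one morphologically
distinguished fungal taxon recovered from one tissue of one host plant,
with a colony count. A :class:`CommunityTable` bundles the records of a
study together with per-tissue segment tallies (how many surface-sterilised
tissue segments were plated, and how many yielded at least one endophyte),
which is the raw input for colonization-frequency percentages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

TISSUES = ("flower", "leaf", "stem", "root")
LOCATIONS = ("PAWD", "NCAH")

UNCLASSIFIED = "unclassified"

ISOLATE_COLUMNS = ("plant", "location", "tissue", "morphospecies", "genus", "colony_count")
TALLY_COLUMNS = ("plant", "tissue", "segments_examined", "segments_colonized")

_DATA_DIR = Path(__file__).parent / "data"


class SchemaError(ValueError):
    """Input file does not have the expected columns."""


class ValidationError(ValueError):
    """Input rows violate a community-table invariant."""


@dataclass(frozen=True)
class TaxonRecord:
    """A morphospecies with its (possibly partial) taxonomic placement."""

    morphospecies_id: str
    genus: str
    phylum: str = "unknown"
    class_name: str = "unknown"

    @property
    def classified(self) -> bool:
        return self.genus != UNCLASSIFIED


@dataclass(frozen=True)
class IsolateRecord:
    """One morphospecies observed in one plant tissue."""

    plant: str
    location: str
    tissue: str
    taxon: TaxonRecord
    colony_count: int

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValidationError(
                f"unknown location {self.location!r}; expected one of {LOCATIONS}"
            )
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r}; expected one of {TISSUES}"
            )
        if self.colony_count < 0:
            raise ValidationError(
                f"negative colony_count {self.colony_count} for "
                f"({self.plant}, {self.tissue}, {self.taxon.morphospecies_id})"
            )


@dataclass(frozen=True)
class SegmentTally:
    """Segments examined vs colonized for one plant tissue."""

    plant: str
    tissue: str
    segments_examined: int
    segments_colonized: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.segments_examined <= 0:
            raise ValidationError("segments_examined must be positive")
        if not 0 <= self.segments_colonized <= self.segments_examined:
            raise ValidationError(
                f"segments_colonized={self.segments_colonized} outside "
                f"[0, {self.segments_examined}] for ({self.plant}, {self.tissue})"
            )


@dataclass
class CommunityTable:
    """Validated isolate records plus segment tallies for one study."""

    isolates: list[IsolateRecord] = field(default_factory=list)
    tallies: list[SegmentTally] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.isolates:
            key = (rec.plant, rec.tissue, rec.taxon.morphospecies_id)
            if key in seen:
                raise ValidationError(f"duplicate isolate record for {key}")
            seen.add(key)
        seen_t: set[tuple[str, str]] = set()
        for tal in self.tallies:
            key_t = (tal.plant, tal.tissue)
            if key_t in seen_t:
                raise ValidationError(f"duplicate segment tally for {key_t}")
            seen_t.add(key_t)

    # -- views ------------------------------------------------------------

    @property
    def plants(self) -> list[str]:
        return sorted({r.plant for r in self.isolates})

    def records_for(self, plant: str) -> list[IsolateRecord]:
        return [r for r in self.isolates if r.plant == plant]

    def abundance_vector(self, plant: str) -> list[int]:
        """Per-morphospecies colony counts for one plant (zeros dropped)."""
        counts: dict[str, int] = {}
        for r in self.records_for(plant):
            counts[r.taxon.morphospecies_id] = (
                counts.get(r.taxon.morphospecies_id, 0) + r.colony_count
            )
        return sorted((n for n in counts.values() if n > 0), reverse=True)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plant": r.plant,
                "location": r.location,
                "tissue": r.tissue,
                "morphospecies": r.taxon.morphospecies_id,
                "genus": r.taxon.genus,
                "colony_count": r.colony_count,
            }
            for r in self.isolates
        ]
        return pd.DataFrame(rows, columns=list(ISOLATE_COLUMNS))

    def tallies_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plant": t.plant,
                "tissue": t.tissue,
                "segments_examined": t.segments_examined,
                "segments_colonized": t.segments_colonized,
            }
            for t in self.tallies
        ]
        return pd.DataFrame(rows, columns=list(TALLY_COLUMNS))


def _normalize(s: str) -> str:
    return " ".join(str(s).split())


def _frame_to_table(df: pd.DataFrame, tallies: pd.DataFrame | None, provenance: str) -> CommunityTable:
    missing = [c for c in ISOLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {provenance or 'input'}")
    records = []
    for _, row in df.iterrows():
        count = row["colony_count"]
        try:
            count = int(count)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer colony_count {count!r}") from exc
        taxon = TaxonRecord(
            morphospecies_id=_normalize(row["morphospecies"]),
            genus=_normalize(row["genus"]),
            phylum=_normalize(row["phylum"]) if "phylum" in df.columns else "unknown",
            class_name=_normalize(row["class_name"]) if "class_name" in df.columns else "unknown",
        )
        records.append(
            IsolateRecord(
                plant=_normalize(row["plant"]),
                location=_normalize(row["location"]),
                tissue=_normalize(row["tissue"]),
                taxon=taxon,
                colony_count=count,
            )
        )
    tally_records = []
    if tallies is not None:
        missing_t = [c for c in TALLY_COLUMNS if c not in tallies.columns]
        if missing_t:
            raise SchemaError(f"missing tally column(s) {missing_t}")
        for _, row in tallies.iterrows():
            tally_records.append(
                SegmentTally(
                    plant=_normalize(row["plant"]),
                    tissue=_normalize(row["tissue"]),
                    segments_examined=int(row["segments_examined"]),
                    segments_colonized=int(row["segments_colonized"]),
                )
            )
    return CommunityTable(isolates=records, tallies=tally_records, provenance=provenance)


def read_community(
    path: str | Path | io.IOBase,
    format: str = "csv",
    tallies_path: str | Path | None = None,
) -> CommunityTable:
    """Read an isolate inventory (and optional segment tallies) into a table.

    Parameters
    ----------
    path
        CSV/TSV file with columns plant, location, tissue, morphospecies,
        genus, colony_count (phylum / class_name optional).
    format
        ``"csv"`` or ``"tsv"``.
    tallies_path
        Optional sibling file with columns plant, tissue,
        segments_examined, segments_colonized.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"format must be 'csv' or 'tsv', got {format!r}")
    df = pd.read_csv(path, sep=sep, dtype=str).dropna(how="all")
    tal = None
    if tallies_path is not None:
        tal = pd.read_csv(tallies_path, sep=sep).dropna(how="all")
    name = getattr(path, "name", str(path))
    return _frame_to_table(df, tal, provenance=str(name))


def write_community(
    table: CommunityTable,
    path: str | Path,
    format: str = "csv",
    tallies_path: str | Path | None = None,
) -> None:
    """Write a table back to CSV/TSV so that ``read_community`` round-trips."""
    sep = {"csv": ",", "tsv": "\t"}[format]
    table.to_frame().to_csv(path, sep=sep, index=False)
    if tallies_path is not None:
        table.tallies_frame().to_csv(tallies_path, sep=sep, index=False)


def load_fixture(name: str) -> CommunityTable:
    """Load a packaged fixture ('table1_isolates' or 'reconstructed_abundances')."""
    path = _DATA_DIR / f"{name}.csv"
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return read_community(path)


def load_fixture_frame(name: str) -> pd.DataFrame:
    """Load a packaged reference CSV ('table2_cf' or 'table3_indices') as a frame."""
    path = _DATA_DIR / f"{name}.csv"
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return pd.read_csv(path)


def genus_tally(table: CommunityTable, include_unclassified: bool = True) -> dict[str, int]:
    """Count morphospecies records per genus.

    With ``include_unclassified=False``, records whose genus is the
    'unclassified' marker (sterile mycelia that never sporulated) are
    dropped from the mapping entirely.
    """
    out: dict[str, int] = {}
    for rec in table.isolates:
        if not include_unclassified and not rec.taxon.classified:
            continue
        out[rec.taxon.genus] = out.get(rec.taxon.genus, 0) + 1
    return out


def location_tally(table: CommunityTable) -> dict[str, int]:
    """Count morphospecies records per sampling area."""
    out: dict[str, int] = {}
    for rec in table.isolates:
        out[rec.location] = out.get(rec.location, 0) + 1
    return out


def merge_tables(*tables: CommunityTable) -> CommunityTable:
    """Concatenate studies; the merged table is re-validated."""
    isolates: list[IsolateRecord] = []
    tallies: list[SegmentTally] = []
    for t in tables:
        isolates.extend(t.isolates)
        tallies.extend(t.tallies)
    return CommunityTable(
        isolates=isolates,
        tallies=tallies,
        provenance="+".join(t.provenance for t in tables),
    )
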
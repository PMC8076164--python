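"""The collection catalogue: 378 vouchered Greenland *Hebeloma* collections.

The packaged fixture (``data/catalogue.csv``) is a transcription of the
survey's voucher table merged with the per-species collection paragraphs:
database reference, fungarium voucher, collector number, species, ITS GenBank
accession(s) with partial-ITS flags (ITS1-only / ITS2-only), decimal
coordinates (west longitudes negative), elevation, date, collector, hosts and
locality.  Records lacking coordinates would carry nulls and be excluded from
biogeographic derivations (the shipped fixture localizes all 378).
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

ACCESSION_RE = re.compile(r"[A-Z]{2}\d{6}")
PARTIAL_FLAGS = {"", "its1_only", "its2_only"}

_COLUMNS = ["db_ref", "voucher", "other_number", "species", "its_accession",
            "its_partial", "region", "latitude", "longitude", "elevation_m",
            "date", "collector", "hosts", "locality"]


class CatalogueError(ValueError):
    """Raised with a row number for malformed catalogue input."""


@dataclass(frozen=True)
class CollectionRecord:
    db_ref: str
    voucher: str
    species: str                      # "Hebeloma <epithet>"
    other_number: str = ""
    its_accession: tuple = ()
    its_partial: str = ""             # "", "its1_only" or "its2_only"
    region: Optional[str] = None      # S/W/N/E override, if transcribed
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    elevation_m: Optional[float] = None
    date: Optional[str] = None        # ISO date
    collector: str = ""
    hosts: tuple = ()
    locality: str = ""

    @property
    def epithet(self) -> str:
        return self.species.split()[-1]


def default_catalogue_path() -> Path:
    return Path(str(resources.files("hebkeys").joinpath("data", "catalogue.csv")))


def load_catalogue(path=None, known_species=None) -> list[CollectionRecord]:
    """Read and validate a catalogue CSV.

    Checks: unique db_ref, accessions matching two letters + six digits,
    valid partial-ITS flags, parseable coordinates, and — when
    ``known_species`` is given — species membership.  Errors name the row.
    """
    path = Path(path) if path is not None else default_catalogue_path()
    records, seen = [], set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            db_ref = (row.get("db_ref") or "").strip()
            if not db_ref:
                raise CatalogueError(f"row {i}: missing db_ref")
            if db_ref in seen:
                raise CatalogueError(f"row {i}: duplicate db_ref {db_ref}")
            seen.add(db_ref)
            species = (row.get("species") or "").strip()
            if known_species is not None and species.split()[-1] not in known_species:
                raise CatalogueError(f"row {i}: unknown species {species!r}")
            accs = tuple(a for a in (row.get("its_accession") or "").split(";") if a)
            for a in accs:
                if not ACCESSION_RE.fullmatch(a):
                    raise CatalogueError(f"row {i}: malformed accession {a!r}")
            partial = (row.get("its_partial") or "").strip()
            if partial not in PARTIAL_FLAGS:
                raise CatalogueError(f"row {i}: bad its_partial {partial!r}")

            def num(key):
                v = (row.get(key) or "").strip()
                if not v:
                    return None
                try:
                    return float(v)
                except ValueError:
                    raise CatalogueError(f"row {i}: bad number {key}={v!r}")

            date = (row.get("date") or "").strip() or None
            if date and not re.fullmatch(r"\d{4}-\d{2}-\d{2}", date):
                raise CatalogueError(f"row {i}: bad date {date!r}")
            hosts = tuple(h.strip() for h in (row.get("hosts") or "").split(";")
                          if h.strip())
            records.append(CollectionRecord(
                db_ref=db_ref, voucher=(row.get("voucher") or "").strip(),
                other_number=(row.get("other_number") or "").strip(),
                species=species, its_accession=accs, its_partial=partial,
                region=(row.get("region") or "").strip() or None,
                latitude=num("latitude"), longitude=num("longitude"),
                elevation_m=num("elevation_m"), date=date,
                collector=(row.get("collector") or "").strip(),
                hosts=hosts, locality=(row.get("locality") or "").strip()))
    return records


def dump_catalogue(records, path) -> None:
    """Write records back to CSV; load → dump → load is the identity."""
    with Path(path).open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_COLUMNS)
        w.writeheader()
        for r in records:
            d = asdict(r)
            d["its_accession"] = ";".join(r.its_accession)
            d["hosts"] = "; ".join(r.hosts)
            for k in ("latitude", "longitude", "elevation_m"):
                if d[k] is None:
                    d[k] = ""
                elif float(d[k]).is_integer():
                    d[k] = str(int(d[k]))
                else:
                    d[k] = repr(d[k])
            for k in ("region", "date"):
                d[k] = d[k] or ""
            w.writerow(d)


def count_by_species(records) -> dict[str, int]:
    """Collection counts per species; values sum to the catalogue size."""
    out: dict[str, int] = {}
    for r in records:
        out[r.species] = out.get(r.species, 0) + 1
    return out


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import Decimal, ROUND_HALF_UP
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def species_share(records, species: str) -> float:
    """Percentage of collections belonging to ``species`` (full name or
    epithet), rounded half-up to one decimal."""
    if not records:
        raise CatalogueError("empty catalogue")
    n = sum(1 for r in records
            if r.species == species or r.epithet == species)
    return _round_half_up(100.0 * n / len(records), 1)


def partial_its_count(records) -> int:
    """Number of collections that yielded only ITS1 or only ITS2."""
    return sum(1 for r in records if r.its_partial)
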
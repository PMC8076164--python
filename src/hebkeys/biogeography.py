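"""Greenland regions, bioclimatic zones and species distribution groups.

Greenland is divided into four regions: South (south of 62.20°N), West
(62.20–74°N on the west side), North (north of 74°N) and East (62.20–74°N on
the east side).  The island spans two bioclimatic zones — a tiny Subarctic
zone at the heads of some southern fjords, and the Arctic zone, split into Low
Arctic and High Arctic approximately along 70°N.

Species are grouped by the regions their collections come from:

1. South Greenland only;
2. South & West;
3. South, West & East but never North;
4. all of Greenland (South and North both present);
5. never collected in South Greenland.

The east/west divide of the ice sheet is not a printed meridian; the default
44°W separates every listed west-coast site (48–56°W) from every east-coast
site (17–37°W) in the 62.2–74°N band and is configurable.  A per-record region
override (e.g. transcribed from a catalogue's own S-/W-/N-/E- headings) takes
precedence over the coordinate rule.  The Subarctic zone is botanically
defined; it is only assigned via an explicit site flag or the 61.25°N analysis
cutoff, never inferred.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

LAT_SOUTH = 62.20        #: south of this: South Greenland
LAT_NORTH = 74.0         #: north of this: North Greenland
LAT_HIGH_ARCTIC = 70.0   #: Low/High Arctic boundary (approximation)
LON_DIVIDE = -44.0       #: default east/west divide meridian (44°W)
SUBARCTIC_LAT = 61.25    #: analysis cutoff for the Subarctic zone

# sanity bounding box for Greenland coordinates
_LAT_BOX = (59.0, 84.0)
_LON_BOX = (-75.0, -10.0)

REGIONS = ("South", "West", "North", "East")
_REGION_LETTER = {"South": "S", "West": "W", "North": "N", "East": "E"}
_LETTER_REGION = {v: k for k, v in _REGION_LETTER.items()}


class CoordinateError(ValueError):
    """Raised for coordinates outside Greenland's bounding box."""


@dataclass(frozen=True)
class RegionAssignment:
    region: str
    zone: str
    basis: tuple

    @property
    def letter(self) -> str:
        return _REGION_LETTER[self.region]


def assign_region(lat: float, lon: float, *, divide_lon: float = LON_DIVIDE,
                  high_arctic_lat: float = LAT_HIGH_ARCTIC,
                  subarctic_site: bool = False) -> RegionAssignment:
    """Assign a coordinate to a region and bioclimatic zone.

    Latitudes exactly on the 62.20/74°N boundaries belong to the northern
    side.  ``subarctic_site=True`` marks a site in the botanically defined
    Subarctic zone; otherwise the zone is Low/High Arctic by latitude.
    """
    if not (_LAT_BOX[0] <= lat <= _LAT_BOX[1] and _LON_BOX[0] <= lon <= _LON_BOX[1]):
        raise CoordinateError(f"coordinate outside Greenland: ({lat}, {lon})")
    basis = []
    if lat < LAT_SOUTH:
        region = "South"
        basis.append(f"lat < {LAT_SOUTH}")
    elif lat >= LAT_NORTH:
        region = "North"
        basis.append(f"lat >= {LAT_NORTH}")
    elif lon >= divide_lon:
        region = "East"
        basis.append(f"lon >= {divide_lon}")
    else:
        region = "West"
        basis.append(f"lon < {divide_lon}")
    if subarctic_site:
        zone = "Subarctic"
        basis.append("explicit subarctic site flag")
    elif lat >= high_arctic_lat:
        zone = "HighArctic"
        basis.append(f"lat >= {high_arctic_lat}")
    else:
        zone = "LowArctic"
        basis.append(f"lat < {high_arctic_lat}")
    return RegionAssignment(region=region, zone=zone, basis=tuple(basis))


@dataclass(frozen=True)
class DistributionGroup:
    group: int
    region_set: frozenset


def assign_group(region_set) -> DistributionGroup:
    """Map a species' set of regions (letters ``S/W/N/E`` or full names) to its
    distribution group 1–5.  The mapping is total: any set without S falls in
    group 5; S with N anywhere is group 4."""
    rs = frozenset(_REGION_LETTER.get(r, r) for r in region_set)
    if not rs:
        raise ValueError("empty region set")
    bad = rs - set("SWNE")
    if bad:
        raise ValueError(f"unknown regions: {sorted(bad)}")
    if "S" not in rs:
        g = 5
    elif "N" in rs:
        g = 4
    elif rs == {"S"}:
        g = 1
    elif rs == {"S", "W"}:
        g = 2
    else:                      # S present, E present, N absent
        g = 3
    return DistributionGroup(group=g, region_set=rs)


def annotate_catalogue(records, **region_kwargs) -> pd.DataFrame:
    """Region/zone columns for a catalogue (list of CollectionRecord).

    A record's explicit ``region`` field (one-letter override) takes
    precedence; records without coordinates and without an override get
    nulls."""
    rows = []
    for r in records:
        region = zone = None
        if r.latitude is not None and r.longitude is not None:
            ra = assign_region(r.latitude, r.longitude, **region_kwargs)
            region, zone = ra.letter, ra.zone
        if getattr(r, "region", None):
            region = r.region
        rows.append(dict(db_ref=r.db_ref, species=r.species,
                         latitude=r.latitude, longitude=r.longitude,
                         region=region, zone=zone))
    cols = ["db_ref", "species", "latitude", "longitude", "region", "zone"]
    return pd.DataFrame(rows, columns=cols if not rows else None)


def tabulate_groups(records, taxa=None, **region_kwargs) -> pd.DataFrame:
    """Species × group table with collection counts (the distribution-group
    tabulation).

    Region sets are derived from each species' collections (override column
    first, else coordinates); species with no localizable collection are
    flagged with group 0 and excluded from region-set derivation.  When
    ``taxa`` is given, the stored group is included for cross-checking.
    """
    df = annotate_catalogue(records, **region_kwargs)
    stored = {}
    if taxa is not None:
        stored = {f"Hebeloma {t.name}": t.distribution_group for t in taxa}
    rows = []
    for species, sub in df.groupby("species", sort=True):
        regions = frozenset(x for x in sub["region"] if x)
        if regions:
            grp = assign_group(regions).group
        else:
            grp = 0
        row = dict(species=species, group=grp,
                   region_set="".join(l for l in "SWNE" if l in regions),
                   n_collections=len(sub))
        if stored:
            row["stored_group"] = stored.get(species)
            row["group_matches"] = stored.get(species) == grp
        rows.append(row)
    cols = ["species", "group", "region_set", "n_collections"]
    out = pd.DataFrame(rows, columns=cols if not rows else None)
    total = dict(species="Total", group=pd.NA, region_set="",
                 n_collections=int(out["n_collections"].sum()) if rows else 0)
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def subarctic_species_count(records, lat_cutoff: float = SUBARCTIC_LAT) -> int:
    """Number of species with at least one collection south of ``lat_cutoff``
    (default 61.25°N, the Subarctic analysis zone)."""
    south = {r.species for r in records
             if r.latitude is not None and r.latitude < lat_cutoff}
    return len(south)
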
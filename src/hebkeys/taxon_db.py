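"""Machine-readable trait database for the 28 Greenland *Hebeloma* species.

Each record compiles, from the species description, the per-collection-mean
("on ave.") ranges for spore length/width/Q, cheilocystidium dimensions, the
lamellae count {L}, the ordinal O/P/D code strings, the qualitative characters
the identification keys rely on, and — from the distribution table — the
species' distribution group (1–5), specialist/opportunist strategy and number
of collections.

Where a description gives both an "on ave." interval and an absolute interval,
the "on ave." interval is stored: the keys compare collection means.
Qualitative traits a description does not state are ``None`` (unknown), never
False.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .morphometrics import OrdinalTraitCodes, parse_opd

SECTIONS = {"Hebeloma", "Denudata", "Velutipes", "Naviculospora"}
SUBSECTIONS = {"Crustuliniformia", "Clepsydroida", "Hiemalia"}
N_SPECIES = 28
TOTAL_COLLECTIONS = 378


class TaxonDBError(ValueError):
    """Raised for schema violations in the trait database."""


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise TaxonDBError(f"malformed interval: [{self.lo}, {self.hi}]")

    @property
    def mid(self) -> float:
        return (self.lo + self.hi) / 2

    def __contains__(self, x: float) -> bool:
        return self.lo <= x <= self.hi


@dataclass(frozen=True)
class TaxonRecord:
    name: str
    section: str
    subsection: Optional[str]
    spore_mean_length_range: Interval
    spore_mean_width_range: Interval
    spore_mean_q_range: Interval
    lamellae_count_range: Interval
    ornamentation: OrdinalTraitCodes
    perispore: OrdinalTraitCodes
    dextrinoidity: OrdinalTraitCodes
    cystidia_length_range: Interval
    cystidia_apex_range: Interval
    cystidia_mid_range: Interval
    cystidia_base_range: Interval
    stem_width_range_cm: Optional[Interval]
    qualitative: dict
    distribution_group: int
    strategy: str
    n_collections: int
    hosts: tuple = ()

    @property
    def codes(self) -> OrdinalTraitCodes:
        from .morphometrics import merge_codes
        return merge_codes(self.ornamentation, self.perispore,
                           self.dextrinoidity)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hebkeys").joinpath("data", name)))


def default_taxa_path() -> Path:
    return _data_path("taxa.json")


def load_taxa(path=None) -> list[TaxonRecord]:
    """Load and validate the trait database (28 records).

    Raises :class:`TaxonDBError` on duplicate species, malformed intervals,
    unknown sections or bad strategy/group values.
    """
    path = Path(path) if path is not None else default_taxa_path()
    text = path.read_text()
    if not text.strip():
        raise TaxonDBError("empty trait database")
    raw = json.loads(text)
    records, seen = [], set()
    for obj in raw:
        name = obj["name"]
        if name in seen:
            raise TaxonDBError(f"duplicate species: {name}")
        seen.add(name)
        if obj["section"] not in SECTIONS:
            raise TaxonDBError(f"unknown section: {obj['section']}")
        sub = obj.get("subsection")
        if sub is not None and sub not in SUBSECTIONS:
            raise TaxonDBError(f"unknown subsection: {sub}")
        if obj["strategy"] not in {"specialist", "opportunist"}:
            raise TaxonDBError(f"unknown strategy: {obj['strategy']}")
        if obj["distribution_group"] not in range(1, 6):
            raise TaxonDBError(f"bad group: {obj['distribution_group']}")

        def iv(key, optional=False):
            v = obj.get(key)
            if v is None:
                if optional:
                    return None
                raise TaxonDBError(f"{name}: missing interval {key}")
            return Interval(float(v[0]), float(v[1]))

        records.append(TaxonRecord(
            name=name, section=obj["section"], subsection=sub,
            spore_mean_length_range=iv("spore_mean_length_range"),
            spore_mean_width_range=iv("spore_mean_width_range"),
            spore_mean_q_range=iv("spore_mean_q_range"),
            lamellae_count_range=iv("lamellae_count_range"),
            ornamentation=parse_opd(obj["ornamentation"]),
            perispore=parse_opd(obj["perispore"]),
            dextrinoidity=parse_opd(obj["dextrinoidity"]),
            cystidia_length_range=iv("cystidia_length_range"),
            cystidia_apex_range=iv("cystidia_apex_range"),
            cystidia_mid_range=iv("cystidia_mid_range"),
            cystidia_base_range=iv("cystidia_base_range"),
            stem_width_range_cm=iv("stem_width_range_cm", optional=True),
            qualitative=dict(obj["qualitative"]),
            distribution_group=int(obj["distribution_group"]),
            strategy=obj["strategy"],
            n_collections=int(obj["n_collections"]),
            hosts=tuple(obj.get("hosts", ()))))
    return records


def taxa_by_name(taxa=None) -> dict[str, TaxonRecord]:
    return {t.name: t for t in (taxa if taxa is not None else load_taxa())}


def dump_taxa(taxa: list[TaxonRecord], path) -> None:
    """Write records back to JSON (lossless round trip of the schema)."""

    def code_str(c: OrdinalTraitCodes) -> str:
        toks = sorted(c.ornamentation | c.perispore | c.dextrinoidity)
        return " ".join(f"({t})" if c.is_parenthetical(t) else t for t in toks)

    out = []
    for t in taxa:
        out.append(dict(
            name=t.name, section=t.section, subsection=t.subsection,
            spore_mean_length_range=[t.spore_mean_length_range.lo,
                                     t.spore_mean_length_range.hi],
            spore_mean_width_range=[t.spore_mean_width_range.lo,
                                    t.spore_mean_width_range.hi],
            spore_mean_q_range=[t.spore_mean_q_range.lo, t.spore_mean_q_range.hi],
            lamellae_count_range=[t.lamellae_count_range.lo,
                                  t.lamellae_count_range.hi],
            ornamentation=code_str(t.ornamentation),
            perispore=code_str(t.perispore),
            dextrinoidity=code_str(t.dextrinoidity),
            cystidia_length_range=[t.cystidia_length_range.lo,
                                   t.cystidia_length_range.hi],
            cystidia_apex_range=[t.cystidia_apex_range.lo,
                                 t.cystidia_apex_range.hi],
            cystidia_mid_range=[t.cystidia_mid_range.lo, t.cystidia_mid_range.hi],
            cystidia_base_range=[t.cystidia_base_range.lo,
                                 t.cystidia_base_range.hi],
            stem_width_range_cm=(None if t.stem_width_range_cm is None else
                                 [t.stem_width_range_cm.lo,
                                  t.stem_width_range_cm.hi]),
            qualitative=t.qualitative, distribution_group=t.distribution_group,
            strategy=t.strategy, n_collections=t.n_collections,
            hosts=list(t.hosts)))
    Path(path).write_text(json.dumps(out, indent=1) + "\n")


KEY_RELEVANT_INTERVALS = ("spore_mean_length_range", "spore_mean_width_range",
                          "spore_mean_q_range", "lamellae_count_range")


def centroid_profile(taxon: TaxonRecord):
    """The taxon's idealized specimen: continuous traits at interval
    midpoints, categorical traits as recorded.

    Raises :class:`TaxonDBError` listing any missing key-relevant trait.
    """
    from .key_engine import SpecimenProfile, SporeStats

    missing = [k for k in KEY_RELEVANT_INTERVALS if getattr(taxon, k) is None]
    if missing:
        raise TaxonDBError(f"{taxon.name}: missing key-relevant traits: "
                           + ", ".join(missing))
    return SpecimenProfile(
        spores=SporeStats(mean_length=taxon.spore_mean_length_range.mid,
                          mean_width=taxon.spore_mean_width_range.mid,
                          mean_q=taxon.spore_mean_q_range.mid),
        codes=taxon.codes,
        lamellae_count=taxon.lamellae_count_range.mid,
        qualitative=dict(taxon.qualitative),
        stem_width_cm=(None if taxon.stem_width_range_cm is None
                       else taxon.stem_width_range_cm.mid),
        habitat_arctic_alpine=taxon.qualitative.get("habitat_arctic_alpine"))
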
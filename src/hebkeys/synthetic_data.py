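"""Seeded synthetic specimens, catalogues and toy ITS alignments.

The generator emulates the statistical structure the analysis assumes, so
every stage of the pipeline is testable without any external data:

* **Specimens.**  A species' description gives an "on ave." interval for each
  continuous trait — the range that *collection means* fall in.  A synthetic
  collection draws its latent mean from a truncated normal centred at the
  interval midpoint with SD = width/4 (the interval is a ±2 SD envelope of
  the collection mean), truncated to the interval; individual spores and
  cystidia then scatter around that mean with a relative measurement noise
  (default 5%).  Ordinal O/P/D classes copy the taxon's recorded set, with
  parenthetical (rare) classes included at low probability and kept
  parenthetical.  Qualitative traits are copied verbatim.
* **Catalogues.**  Collections are placed around the five main survey
  localities, each species only in regions consistent with its distribution
  group, so the group tabulation recovers every species' stored group.
* **Toy alignments.**  Variant classes with engineered private/shared
  structure and a ground-truth manifest.

All outputs are bit-for-bit reproducible from ``SimulationConfig.seed``.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .catalogue import CollectionRecord
from .its_variants import AlignedSequence
from .key_engine import SpecimenProfile
from .morphometrics import (CystidiumMeasurement, OrdinalTraitCodes,
                            SporeMeasurement, summarize_cheilocystidia,
                            summarize_spores)
from .taxon_db import TaxonRecord, TaxonDBError

#: probability that a parenthetical (rare) O/P/D class is recorded at all
P_PARENTHETICAL = 0.25

#: the five main survey localities (name, lat, lon, region letter)
SITES = {
    "S": [("Narsarsuaq", 61.15, -45.42), ("Paamiut", 62.01, -49.40)],
    "W": [("Kangerlussuaq", 67.02, -50.70)],
    "N": [("Zackenberg", 74.47, -21.00)],
    "E": [("Jameson Land", 70.74, -22.65)],
}

#: region letters consistent with each distribution group
GROUP_REGIONS = {1: "S", 2: "SW", 3: "SWE", 4: "SWNE", 5: "WNE"}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_spores_per_specimen: int = 50
    n_cystidia: int = 20
    measurement_noise: float = 0.05
    specimens_per_species: int = 1
    coordinate_jitter: float = 0.05      # degrees

    def __post_init__(self):
        for k in ("n_spores_per_specimen", "n_cystidia", "specimens_per_species"):
            if getattr(self, k) < 1:
                raise ValueError(f"{k} must be >= 1")


def _rng(config: SimulationConfig, *context: str) -> np.random.Generator:
    """Deterministic generator keyed on the seed plus a stable context hash."""
    key = [config.seed] + [zlib.crc32(c.encode()) for c in context]
    return np.random.default_rng(key)


def _truncnorm(rng, lo, hi, size=None):
    """Truncated normal on [lo, hi], centred at the midpoint, SD = width/4.
    A degenerate interval (lo == hi) returns the point itself."""
    if hi <= lo:
        return np.full(size, float(lo)) if size is not None else float(lo)
    mid, sd = (lo + hi) / 2, (hi - lo) / 4
    a, b = (lo - mid) / sd, (hi - mid) / sd
    return stats.truncnorm.rvs(a, b, loc=mid, scale=sd, size=size,
                               random_state=rng)


def _positive_noise(rng, mean, rel_sd, size):
    """Measurements scattered around a latent mean; strictly positive."""
    if rel_sd <= 0:
        return np.full(size, float(mean))
    vals = rng.normal(mean, rel_sd * mean, size=size)
    return np.clip(vals, mean * 0.2, None)


def _sample_codes(rng, taxon: TaxonRecord) -> OrdinalTraitCodes:
    orn, per, dex, emph = set(), set(), set(), {}
    for dim, store in (("ornamentation", orn), ("perispore", per),
                       ("dextrinoidity", dex)):
        codes: OrdinalTraitCodes = getattr(taxon, dim)
        for cls in sorted(codes.classes(dim)):
            if codes.is_parenthetical(cls):
                if rng.random() < P_PARENTHETICAL:
                    store.add(cls)
                    emph[cls] = "parenthetical"
            else:
                store.add(cls)
    return OrdinalTraitCodes(frozenset(orn), frozenset(per), frozenset(dex), emph)


def generate_specimen(taxon: TaxonRecord, config: SimulationConfig,
                      replicate: int = 0):
    """Generate one synthetic collection of ``taxon``.

    Returns ``(spores, cystidia, profile)``: the raw measurement lists and the
    summarized :class:`~hebkeys.key_engine.SpecimenProfile` ready for the key
    engine.
    """
    for iv_name in ("spore_mean_length_range", "spore_mean_width_range",
                    "lamellae_count_range"):
        if getattr(taxon, iv_name) is None:
            raise TaxonDBError(f"{taxon.name}: incomplete ranges ({iv_name})")
    rng = _rng(config, "specimen", taxon.name, str(replicate))

    # latent collection means
    len_iv, wid_iv = taxon.spore_mean_length_range, taxon.spore_mean_width_range
    mean_len = float(_truncnorm(rng, len_iv.lo, len_iv.hi))
    mean_wid = float(_truncnorm(rng, wid_iv.lo, wid_iv.hi))
    n = config.n_spores_per_specimen
    lengths = _positive_noise(rng, mean_len, config.measurement_noise, n)
    widths = _positive_noise(rng, mean_wid, config.measurement_noise, n)
    spores = [SporeMeasurement(float(l), float(w))
              for l, w in zip(lengths, widths)]

    cyst_means = [float(_truncnorm(rng, iv.lo, iv.hi))
                  for iv in (taxon.cystidia_length_range,
                             taxon.cystidia_apex_range,
                             taxon.cystidia_mid_range,
                             taxon.cystidia_base_range)]
    nc = config.n_cystidia
    cl, ca, cm, cb = (
        _positive_noise(rng, m, config.measurement_noise, nc)
        for m in cyst_means)
    cystidia = [CystidiumMeasurement(float(a), float(b), float(c), float(d))
                for a, b, c, d in zip(cl, ca, cm, cb)]

    lam_iv = taxon.lamellae_count_range
    lamellae = int(rng.integers(int(lam_iv.lo), int(lam_iv.hi) + 1))

    profile = SpecimenProfile(
        spores=summarize_spores(spores),
        cystidia=summarize_cheilocystidia(cystidia),
        codes=_sample_codes(rng, taxon),
        lamellae_count=lamellae,
        qualitative=dict(taxon.qualitative),
        stem_width_cm=(None if taxon.stem_width_range_cm is None
                       else float(_truncnorm(rng, taxon.stem_width_range_cm.lo,
                                             taxon.stem_width_range_cm.hi))),
        habitat_arctic_alpine=taxon.qualitative.get("habitat_arctic_alpine"))
    return spores, cystidia, profile


def generate_catalogue(taxa, config: SimulationConfig) -> list[CollectionRecord]:
    """Synthetic catalogue with each species placed only in regions consistent
    with its distribution group; every region of the group's set receives at
    least one collection, so the group tabulation is exactly recoverable."""
    records = []
    counter = 1
    for taxon in taxa:
        rng = _rng(config, "catalogue", taxon.name)
        letters = GROUP_REGIONS[taxon.distribution_group]
        n = max(config.specimens_per_species, len(letters))
        for i in range(n):
            letter = letters[i % len(letters)]
            site, lat, lon = SITES[letter][int(rng.integers(len(SITES[letter])))]
            jit = config.coordinate_jitter
            lat_j = lat + float(rng.uniform(-jit, jit))
            lon_j = lon + float(rng.uniform(-jit, jit))
            # group-1 species must stay south of 62.20N, group-5 north of it
            if letter == "S":
                lat_j = min(lat_j, 62.19)
            host = (taxon.hosts[int(rng.integers(len(taxon.hosts)))]
                    if taxon.hosts else "")
            records.append(CollectionRecord(
                db_ref=f"SYN{counter:05d}",
                voucher=f"SYN-F-{counter:06d}",
                species=f"Hebeloma {taxon.name}",
                its_accession=(f"SY{counter:06d}",),
                region=letter, latitude=round(lat_j, 4),
                longitude=round(lon_j, 4),
                elevation_m=float(rng.integers(0, 500)),
                date=f"{int(rng.integers(1981, 2020))}-08-"
                     f"{int(rng.integers(1, 29)):02d}",
                collector="synthetic",
                hosts=(host,) if host else (),
                locality=site))
            counter += 1
    return records


BASES = np.array(list("ACGT"))


def generate_toy_alignment(n_species: int, n_per_species: int,
                           n_shared_variants: int, seed: int,
                           length: int = 60):
    """Aligned toy sequences with engineered variant structure.

    Each species gets one private variant; ``n_shared_variants`` additional
    variants are each shared between a pair of adjacent species (one member
    collection drawn from each).  Returns ``(sequences, manifest)`` where the
    manifest records the engineered ground truth (class count, member ids per
    class, shared species pairs).
    """
    if min(n_species, n_per_species) < 1 or n_shared_variants < 0:
        raise ValueError("parameters must be >= 0 (counts >= 1)")
    if n_shared_variants > 0 and n_species < 2:
        raise ValueError("shared variants need at least two species")
    rng = np.random.default_rng([seed, zlib.crc32(b"toy_alignment")])
    base = BASES[rng.integers(0, 4, size=length)]

    def mutate(seq, positions):
        s = seq.copy()
        for p in positions:
            s[p] = BASES[(np.where(BASES == s[p])[0][0] + 1) % 4]
        return "".join(s)

    # reserve distinct mutation positions per variant so all variants differ
    n_variants = n_species + n_shared_variants
    if 2 * n_variants > length:
        raise ValueError("alignment too short for requested variant count")
    pos = rng.permutation(length)[:2 * n_variants].reshape(n_variants, 2)
    species = [f"sp{i + 1}" for i in range(n_species)]
    private = {sp: mutate(base, pos[i]) for i, sp in enumerate(species)}
    shared = [mutate(base, pos[n_species + k]) for k in range(n_shared_variants)]

    seqs, manifest_classes = [], {}
    # allocate one collection per species to each shared variant it joins
    assignment = {sp: [private[sp]] * n_per_species for sp in species}
    pairs = []
    for k in range(n_shared_variants):
        a = species[k % n_species]
        b = species[(k + 1) % n_species]
        pairs.append(tuple(sorted((a, b))))
        for sp in (a, b):
            # replace the last still-private slot, if any remains
            slots = assignment[sp]
            for j in range(len(slots) - 1, -1, -1):
                if slots[j] == private[sp]:
                    slots[j] = shared[k]
                    break
            else:
                slots[-1] = shared[k]
    for sp in species:
        for j, res in enumerate(assignment[sp]):
            sid = f"{sp}_c{j + 1}"
            seqs.append(AlignedSequence(id=sid, residues=res,
                                        label_species=sp,
                                        label_region="Greenland"))
            manifest_classes.setdefault(res, []).append(sid)
    manifest = dict(
        n_classes=len({s.residues for s in seqs}),
        members={f"V{i + 1}": sorted(ids) for i, (res, ids) in
                 enumerate(sorted(manifest_classes.items()))},
        shared_species_pairs=sorted(set(pairs)),
        alignment_length=length)
    return seqs, manifest
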
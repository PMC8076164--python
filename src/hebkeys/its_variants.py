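"""ITS variants: per-collection consensus sequences collapsed to equivalence
classes.

Dikaryotic material and intragenomic variation often make true haplotypes
unrecoverable from direct ITS sequencing, so each collection is represented by
one consensus sequence, ambiguity codes and all ("ITS variants").  Two aligned
consensus sequences belong to the same variant iff they are identical
position by position: gaps are significant (indels are treated as insertions,
i.e. alignment columns count like any other) and IUPAC ambiguity codes compare
as literal symbols (R ≠ A) by default, because the ambiguities are part of the
variant.  An optional relaxed mode treats compatible codes as equal; it is off
by default.

Downstream the module provides Hamming distances between variant classes (the
edge lengths a haplotype network would draw) and sharing tables between
species and region labels.  The network construction itself is external and
out of scope here.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

GAP_CHARS = "-."
IUPAC = set("ACGTURYSWKMBDHVN" + GAP_CHARS)

_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class AlignmentError(ValueError):
    """Raised for ragged alignments or non-IUPAC symbols."""


@dataclass(frozen=True)
class AlignedSequence:
    id: str
    residues: str
    label_species: str = ""
    label_region: str = ""          # e.g. "Greenland" / "elsewhere"

    def __post_init__(self):
        bad = set(self.residues.upper()) - IUPAC
        if bad:
            raise AlignmentError(f"{self.id}: non-IUPAC symbols {sorted(bad)}")


@dataclass
class VariantClass:
    representative: str
    members: list = field(default_factory=list)          # AlignedSequence
    species_counts: dict = field(default_factory=dict)
    region_counts: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def species(self) -> frozenset:
        return frozenset(k for k in self.species_counts)

    @property
    def regions(self) -> frozenset:
        return frozenset(k for k in self.region_counts)


def _check_aligned(seqs) -> int:
    if not seqs:
        raise AlignmentError("no sequences")
    lengths = {len(s.residues) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal alignment lengths: {sorted(lengths)}")
    return lengths.pop()


def _compatible(a: str, b: str) -> bool:
    if a in GAP_CHARS or b in GAP_CHARS:
        return a == b            # gap only matches gap, even relaxed
    return bool(set(_AMBIG[a]) & set(_AMBIG[b]))


def same_variant(a: str, b: str, relaxed: bool = False) -> bool:
    """Column-by-column identity of two aligned consensus sequences."""
    if len(a) != len(b):
        raise AlignmentError("unequal lengths")
    a, b = a.upper(), b.upper()
    if not relaxed:
        return a == b
    return all(_compatible(x, y) for x, y in zip(a, b))


def collapse_variants(seqs, relaxed: bool = False) -> list[VariantClass]:
    """Partition aligned sequences into variant classes.

    In strict mode (default) classes are exact-string equivalence classes and
    the result is order-independent.  Relaxed mode greedily merges sequences
    compatible with a class representative (compatibility is not transitive,
    so relaxed classes can depend on input order; the mode exists for
    exploration only).
    """
    _check_aligned(seqs)
    classes: list[VariantClass] = []
    index: dict[str, VariantClass] = {}
    for s in sorted(seqs, key=lambda x: (x.residues.upper(), x.id)):
        res = s.residues.upper()
        vc = None
        if not relaxed:
            vc = index.get(res)
        else:
            vc = next((c for c in classes
                       if same_variant(res, c.representative, relaxed=True)),
                      None)
        if vc is None:
            vc = VariantClass(representative=res)
            classes.append(vc)
            index[res] = vc
        vc.members.append(s)
        if s.label_species:
            vc.species_counts[s.label_species] = \
                vc.species_counts.get(s.label_species, 0) + 1
        if s.label_region:
            vc.region_counts[s.label_region] = \
                vc.region_counts.get(s.label_region, 0) + 1
    return classes


def hamming(a: str, b: str) -> int:
    """Column differences between two aligned sequences; a gap versus a base
    counts as one difference."""
    if len(a) != len(b):
        raise AlignmentError("unequal lengths")
    x = np.frombuffer(a.upper().encode(), dtype="S1")
    y = np.frombuffer(b.upper().encode(), dtype="S1")
    return int((x != y).sum())


def pairwise_differences(classes) -> np.ndarray:
    """Symmetric matrix of Hamming distances between class representatives.
    Two classes at distance 1 are the '1 bp apart' neighbours a network links
    with an unsegmented edge."""
    n = len(classes)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = hamming(classes[i].representative, classes[j].representative)
            mat[i, j] = mat[j, i] = d
    return mat


def shared_variant_table(classes) -> dict:
    """Sharing structure between labels.

    Returns per-class label sets plus summary counts: for each species (and
    region), how many of its collections sit in classes shared with another
    species (region).
    """
    per_class = []
    shared_by_species: dict[str, int] = {}
    shared_by_region: dict[str, int] = {}
    species_pairs: dict[tuple, int] = {}
    for idx, vc in enumerate(classes):
        per_class.append(dict(index=idx, size=vc.size,
                              species=sorted(vc.species),
                              regions=sorted(vc.regions)))
        if len(vc.species) > 1:
            for sp, cnt in vc.species_counts.items():
                shared_by_species[sp] = shared_by_species.get(sp, 0) + cnt
            sps = sorted(vc.species)
            for i in range(len(sps)):
                for j in range(i + 1, len(sps)):
                    pair = (sps[i], sps[j])
                    species_pairs[pair] = species_pairs.get(pair, 0) + vc.size
        if len(vc.regions) > 1:
            for rg, cnt in vc.region_counts.items():
                shared_by_region[rg] = shared_by_region.get(rg, 0) + cnt
    return dict(classes=per_class,
                collections_in_shared_classes_by_species=shared_by_species,
                collections_in_shared_classes_by_region=shared_by_region,
                shared_class_species_pairs=species_pairs)


# ---------------------------------------------------------------- file I/O

def read_alignment(fasta_path, labels_csv=None) -> list[AlignedSequence]:
    """Read an aligned FASTA plus an optional label CSV (id, species, region)."""
    labels = {}
    if labels_csv is not None:
        with Path(labels_csv).open(newline="") as fh:
            for row in csv.DictReader(fh):
                labels[row["id"]] = (row.get("species", ""),
                                     row.get("region", ""))
    seqs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sp, rg = labels.get(rec.id, ("", ""))
        seqs.append(AlignedSequence(id=rec.id, residues=str(rec.seq),
                                    label_species=sp, label_region=rg))
    _check_aligned(seqs)
    return seqs


def write_variant_table(classes, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["variant", "size", "species", "regions", "members"])
        for i, vc in enumerate(classes):
            w.writerow([f"V{i + 1}", vc.size, ";".join(sorted(vc.species)),
                        ";".join(sorted(vc.regions)),
                        ";".join(m.id for m in vc.members)])


def write_phylip_distances(classes, path) -> None:
    """Square PHYLIP distance matrix over variant classes."""
    mat = pairwise_differences(classes)
    with Path(path).open("w") as fh:
        fh.write(f"{len(classes)}\n")
        for i in range(len(classes)):
            name = f"V{i + 1}"
            row = " ".join(f"{mat[i, j]:d}" for j in range(len(classes)))
            fh.write(f"{name:<10s} {row}\n")
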
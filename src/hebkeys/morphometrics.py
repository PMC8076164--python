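"""Spore and cheilocystidium morphometrics.

Implements the measurement protocol used in modern *Hebeloma* taxonomy:
per-collection spore summaries (length, width and the shape index
Q = length/width, each with mean, median, sample SD and 5%/95% percentiles)
and cheilocystidium summaries (length, apex width A, minimum central width M,
maximum lower-half width B, with the shape ratios A/M, A/B and B/M averaged
across cystidia).  Also parses the ordinal trait notation used for spore
ornamentation (O0-O4), perispore loosening (P0-P3) and dextrinoidity (D0-D4),
where parentheses mark rare states, e.g. ``"(D2) D3 (D4)"``.

Conventions (documented, configurable where noted):

* percentiles are linear interpolation between order statistics (the common
  "type 7" estimator; ``method`` argument of :func:`summarize_spores`);
* standard deviations are sample SDs (n-1 denominator);
* Q and the cystidium ratios are means of per-item ratios, never ratios of
  means (the ratio-of-means is exposed as a diagnostic only);
* protocol floors (>= 50 spores, >= 20 full cystidia, ~100 apex widths) are
  soft: smaller samples yield warning flags, not errors.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: protocol sample-size floors; below these a warning flag is raised
MIN_SPORES = 50
MIN_CYSTIDIA_FULL = 20
MIN_CYSTIDIA_APEX = 100

ORNAMENTATION_CLASSES = tuple(f"O{i}" for i in range(5))
PERISPORE_CLASSES = tuple(f"P{i}" for i in range(4))
DEXTRINOIDITY_CLASSES = tuple(f"D{i}" for i in range(5))

_CLASS_ALPHABETS = {
    "O": set(ORNAMENTATION_CLASSES),
    "P": set(PERISPORE_CLASSES),
    "D": set(DEXTRINOIDITY_CLASSES),
}


class MeasurementError(ValueError):
    """Raised for empty or non-positive measurement input."""


@dataclass(frozen=True)
class SporeMeasurement:
    """One spore: maximum length and width in micrometres (apiculus excluded)."""

    length: float
    width: float

    def __post_init__(self):
        if not (self.length > 0 and self.width > 0):
            raise MeasurementError(
                f"invalid measurement: {self.length} x {self.width}")

    @property
    def q(self) -> float:
        return self.length / self.width


@dataclass(frozen=True)
class CystidiumMeasurement:
    """One cheilocystidium: length, apex (A), mid (M) and base (B) widths, um."""

    length: float
    apex_a: float
    middle_m: float
    base_b: float

    def __post_init__(self):
        for v in (self.length, self.apex_a, self.middle_m, self.base_b):
            if not v > 0:
                raise MeasurementError(f"invalid measurement: {v}")


@dataclass(frozen=True)
class SporeSummary:
    n: int
    mean_length: float
    mean_width: float
    mean_q: float
    median_length: float
    median_width: float
    median_q: float
    sd_length: float
    sd_width: float
    sd_q: float
    p5_length: float
    p95_length: float
    p5_width: float
    p95_width: float
    p5_q: float
    p95_q: float
    warnings: tuple = ()

    def round_trip_row(self) -> dict:
        """One flat CSV row (full precision; round only for display)."""
        d = {k: v for k, v in self.__dict__.items() if k != "warnings"}
        d["warnings"] = ";".join(self.warnings)
        return d

    def display(self) -> str:
        """Description-style line, um to 1 decimal and Q to 2, as printed in
        taxonomic descriptions."""
        return (f"{self.p5_length:.1f}–{self.p95_length:.1f} × "
                f"{self.p5_width:.1f}–{self.p95_width:.1f} µm, "
                f"ave. {self.mean_length:.1f} × {self.mean_width:.1f} "
                f"µm, Q = {self.mean_q:.2f}")


@dataclass(frozen=True)
class CystidiaSummary:
    n_full: int
    n_apex_only: int
    mean_length: float
    mean_a: float
    mean_m: float
    mean_b: float
    mean_ratio_am: float
    mean_ratio_ab: float
    mean_ratio_bm: float
    #: diagnostic only -- ratio of the mean widths, never used by the keys
    ratio_of_means_am: float = float("nan")
    warnings: tuple = ()


@dataclass(frozen=True)
class OrdinalTraitCodes:
    """Recorded ordinal classes with optional per-class qualifiers.

    ``emphasis`` maps a class token to ``"parenthetical"`` when the source
    wrote it in parentheses (a rare state); classes without an entry are
    ordinary ("many") states.
    """

    ornamentation: frozenset = frozenset()
    perispore: frozenset = frozenset()
    dextrinoidity: frozenset = frozenset()
    emphasis: dict = field(default_factory=dict)

    def classes(self, dim: str) -> frozenset:
        return getattr(self, dim)

    def is_parenthetical(self, cls: str) -> bool:
        return self.emphasis.get(cls) == "parenthetical"

    def has_many(self, cls: str) -> bool:
        """Class recorded as an ordinary (non-parenthetical) state."""
        dim = {"O": "ornamentation", "P": "perispore", "D": "dextrinoidity"}[cls[0]]
        return cls in self.classes(dim) and not self.is_parenthetical(cls)


def _quantile(values: np.ndarray, q: float, method: str) -> float:
    return float(np.quantile(values, q, method=method))


def summarize_spores(measurements: Iterable[SporeMeasurement],
                     percentile_method: str = "linear") -> SporeSummary:
    """Summarize one collection's spore measurements.

    Q is computed per spore and then summarized (mean of ratios).  At least
    one measurement is required; fewer than 50 raises the
    ``"n_below_protocol"`` warning flag rather than an error, since the
    protocol's floor is a "wherever possible" target.
    """
    ms = list(measurements)
    if not ms:
        raise MeasurementError("no measurements")
    lengths = np.array([m.length for m in ms], dtype=float)
    widths = np.array([m.width for m in ms], dtype=float)
    if not (np.all(lengths > 0) and np.all(widths > 0)):
        raise MeasurementError("invalid measurement")
    qs = lengths / widths
    n = len(ms)
    warnings = ("n_below_protocol",) if n < MIN_SPORES else ()

    def stats(a):
        sd = float(np.std(a, ddof=1)) if n > 1 else 0.0
        return (float(a.mean()), float(np.median(a)), sd,
                _quantile(a, 0.05, percentile_method),
                _quantile(a, 0.95, percentile_method))

    ml, dl, sl, p5l, p95l = stats(lengths)
    mw, dw, sw, p5w, p95w = stats(widths)
    mq, dq, sq, p5q, p95q = stats(qs)
    return SporeSummary(
        n=n, mean_length=ml, mean_width=mw, mean_q=mq,
        median_length=dl, median_width=dw, median_q=dq,
        sd_length=sl, sd_width=sw, sd_q=sq,
        p5_length=p5l, p95_length=p95l, p5_width=p5w, p95_width=p95w,
        p5_q=p5q, p95_q=p95q, warnings=warnings)


def summarize_cheilocystidia(full: Iterable[CystidiumMeasurement],
                             apex_widths: Sequence[float] = ()) -> CystidiaSummary:
    """Summarize cheilocystidium measurements.

    ``full`` carries complete length/A/M/B quadruples; ``apex_widths`` the
    additional apex-only widths measured in bulk on the lamella edge.  When
    apex-only widths are supplied they drive ``mean_a``; otherwise the apex
    statistic comes from the quadruples.  Ratios are always means of
    per-cystidium ratios.
    """
    cs = list(full)
    if not cs:
        raise MeasurementError("no measurements")
    apex_extra = np.asarray(list(apex_widths), dtype=float)
    if apex_extra.size and not np.all(apex_extra > 0):
        raise MeasurementError("invalid measurement")
    a = np.array([c.apex_a for c in cs])
    m = np.array([c.middle_m for c in cs])
    b = np.array([c.base_b for c in cs])
    ln = np.array([c.length for c in cs])
    mean_a = float(apex_extra.mean()) if apex_extra.size else float(a.mean())
    n_apex = int(apex_extra.size)
    warnings = []
    if len(cs) < MIN_CYSTIDIA_FULL:
        warnings.append("n_full_below_protocol")
    if n_apex and n_apex < MIN_CYSTIDIA_APEX:
        warnings.append("n_apex_below_protocol")
    mean_m = float(m.mean())
    return CystidiaSummary(
        n_full=len(cs), n_apex_only=n_apex,
        mean_length=float(ln.mean()), mean_a=mean_a,
        mean_m=mean_m, mean_b=float(b.mean()),
        mean_ratio_am=float((a / m).mean()),
        mean_ratio_ab=float((a / b).mean()),
        mean_ratio_bm=float((b / m).mean()),
        ratio_of_means_am=mean_a / mean_m,
        warnings=tuple(warnings))


_TOKEN_RE = re.compile(r"\(\s*([OPD]\d)\s*\)|([OPD]\d)")


def parse_opd(code_string: str) -> OrdinalTraitCodes:
    """Parse ordinal-class notation such as ``"O1O2 (O3)"`` or ``"(D2) D3 (D4)"``.

    Parenthesized classes are flagged ``parenthetical`` (rare states); parsing
    is order-insensitive.  Unknown tokens and empty input raise
    :class:`MeasurementError` naming the offending token.
    """
    s = code_string.strip()
    if not s:
        raise MeasurementError("no classes")
    dims = {"O": set(), "P": set(), "D": set()}
    emphasis = {}
    pos = 0
    for m in _TOKEN_RE.finditer(s):
        between = s[pos:m.start()]
        if between.strip(" ()"):
            raise MeasurementError(f"unknown token: {between.strip()!r}")
        pos = m.end()
        tok = m.group(1) or m.group(2)
        if tok not in _CLASS_ALPHABETS[tok[0]]:
            raise MeasurementError(f"unknown token: {tok!r}")
        dims[tok[0]].add(tok)
        if m.group(1):
            emphasis[tok] = "parenthetical"
    if s[pos:].strip(" ()"):
        raise MeasurementError(f"unknown token: {s[pos:].strip()!r}")
    if not any(dims.values()):
        raise MeasurementError(f"unknown token: {s!r}")
    return OrdinalTraitCodes(
        ornamentation=frozenset(dims["O"]),
        perispore=frozenset(dims["P"]),
        dextrinoidity=frozenset(dims["D"]),
        emphasis=emphasis)


def merge_codes(*parts: OrdinalTraitCodes) -> OrdinalTraitCodes:
    """Combine codes parsed per dimension into one record."""
    orn, per, dex, emph = set(), set(), set(), {}
    for p in parts:
        orn |= p.ornamentation
        per |= p.perispore
        dex |= p.dextrinoidity
        emph.update(p.emphasis)
    return OrdinalTraitCodes(frozenset(orn), frozenset(per), frozenset(dex), emph)


# ---------------------------------------------------------------- file I/O

def read_spore_table(path) -> list[SporeMeasurement]:
    """Read a delimited measurement table (header ``length,width`` or
    ``length<TAB>width``, one row per spore)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return [SporeMeasurement(float(r.length), float(r.width))
            for r in df.itertuples()]


def read_cystidia_table(path) -> list[CystidiumMeasurement]:
    """Read a delimited table with columns length, apex, middle, base."""
    df = pd.read_csv(path, sep=None, engine="python")
    return [CystidiumMeasurement(float(r.length), float(r.apex),
                                 float(r.middle), float(r.base))
            for r in df.itertuples()]


def read_apex_widths(path) -> list[float]:
    """Read a single-column file of apex-only widths."""
    df = pd.read_csv(path, sep=None, engine="python")
    return [float(v) for v in df.iloc[:, 0]]


def summaries_to_csv(rows: dict[str, SporeSummary], path) -> None:
    """Write one CSV row per collection with all summary fields."""
    df = pd.DataFrame({k: v.round_trip_row() for k, v in rows.items()}).T
    df.index.name = "collection"
    df.to_csv(path)
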
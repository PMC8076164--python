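"""Dichotomous identification keys as declarative decision trees.

The four printed keys (sections/subsections, sect. Hebeloma, sect. Denudata,
sect. Velutipes) are shipped as a JSON transcription (``data/keys.json``):
couplets with two leads, each lead a predicate tree over
:class:`SpecimenProfile` fields plus an outcome (taxon, another couplet, or a
jump into another key).

Evaluation is three-valued (Kleene logic): a predicate over an unknown trait
evaluates to ``unknown``, and the traversal then follows *both* leads,
returning the union of reachable taxa as the candidate set.  Where a couplet's
printed leads are not logically exhaustive and a profile satisfies neither
(this happens for one species, whose description conflicts with its own
couplet), the couplet gives no guidance and the traversal explores every
lead, flagged ``no_lead_matched`` in the path — the printed key is reproduced
literally, never silently repaired.

"Many spores X" in a lead means class X is recorded for the collection and not
flagged parenthetical (rare); "spores X present" counts parenthetical states
too.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .morphometrics import OrdinalTraitCodes, SporeSummary

UNKNOWN = "unknown"

_DIM_FIELD = {"ornamentation": "ornamentation", "perispore": "perispore",
              "dextrinoidity": "dextrinoidity"}


class KeyError_(ValueError):
    """Raised for structural defects in a key file (dangling couplets,
    unreachable taxa, malformed predicates)."""


@dataclass(frozen=True)
class SporeStats:
    """The spore summary slots the keys read.  A full
    :class:`~hebkeys.morphometrics.SporeSummary` satisfies the same interface."""

    mean_length: Optional[float] = None
    mean_width: Optional[float] = None
    mean_q: Optional[float] = None


@dataclass
class SpecimenProfile:
    """A collection's measured/observed traits; any field may be None (unknown)."""

    spores: Union[SporeStats, SporeSummary, None] = None
    cystidia: object = None
    codes: Optional[OrdinalTraitCodes] = None
    lamellae_count: Optional[float] = None
    qualitative: dict = field(default_factory=dict)
    stem_width_cm: Optional[float] = None
    habitat_arctic_alpine: Optional[bool] = None

    def resolve(self, dotted: str):
        """Resolve a dotted field path to a value or None when unknown."""
        obj = self
        for part in dotted.split("."):
            if obj is None:
                return None
            if isinstance(obj, dict):
                obj = obj.get(part)
            else:
                if not hasattr(obj, part) and not isinstance(obj, SpecimenProfile):
                    raise KeyError_(f"predicate references undefined field: {dotted}")
                obj = getattr(obj, part, None)
        return obj


@dataclass(frozen=True)
class Lead:
    pred: object            # predicate tree (dict) or "complement"
    outcome: dict           # {"type": taxon|key|couplet, ...}
    text: str = ""


@dataclass(frozen=True)
class KeyDefinition:
    name: str
    entry: int
    couplets: dict          # couplet number -> [Lead, ...]


@dataclass
class Identification:
    result: object                    # taxon name or frozenset of names
    path: list = field(default_factory=list)
    indeterminate_traits: list = field(default_factory=list)
    visited: list = field(default_factory=list)   # every (key, couplet) touched

    @property
    def candidates(self) -> frozenset:
        if isinstance(self.result, str):
            return frozenset([self.result])
        return frozenset(self.result)

    @property
    def is_unique(self) -> bool:
        return len(self.candidates) == 1


# --------------------------------------------------------------- predicates

def _kleene_and(values):
    if any(v is False for v in values):
        return False
    if any(v == UNKNOWN for v in values):
        return UNKNOWN
    return True


def _kleene_or(values):
    if any(v is True for v in values):
        return True
    if any(v == UNKNOWN for v in values):
        return UNKNOWN
    return False


def _kleene_not(v):
    return UNKNOWN if v == UNKNOWN else (not v)


def evaluate_predicate(pred: dict, profile: SpecimenProfile):
    """Evaluate a predicate tree to True, False or ``"unknown"``.

    Unknown propagates through AND/OR/NOT with Kleene semantics.  Numeric
    comparisons use the printed operators verbatim; class predicates implement
    the many/present/absent readings of the O/P/D notation.
    """
    op = pred.get("op")
    if op == "true":
        return True
    if op == "and":
        return _kleene_and([evaluate_predicate(a, profile) for a in pred["args"]])
    if op == "or":
        return _kleene_or([evaluate_predicate(a, profile) for a in pred["args"]])
    if op == "not":
        return _kleene_not(evaluate_predicate(pred["args"][0], profile))
    if op == "cmp":
        v = profile.resolve(pred["field"])
        if v is None:
            return UNKNOWN
        t = pred["value"]
        return {"<": v < t, "<=": v <= t, ">": v > t, ">=": v >= t,
                "==": v == t}[pred["cmp"]]
    if op == "eq":
        v = profile.resolve(pred["field"])
        if v is None:
            return UNKNOWN
        return v == pred["value"]
    if op == "in":
        v = profile.resolve(pred["field"])
        if v is None:
            return UNKNOWN
        return v in pred["values"]
    if op == "class":
        codes = profile.codes
        if codes is None:
            return UNKNOWN
        dim = _DIM_FIELD[pred["dim"]]
        cls, mode = pred["cls"], pred.get("mode", "many")
        recorded = codes.classes(dim)
        if not recorded:
            return UNKNOWN           # dimension not scored for this collection
        if mode == "present":
            return cls in recorded
        if mode == "absent":
            return cls not in recorded
        if mode == "many":
            return cls in recorded and not codes.is_parenthetical(cls)
        raise KeyError_(f"unknown class mode: {mode}")
    raise KeyError_(f"unknown predicate op: {op}")


def predicate_fields(pred: dict) -> set:
    """All dotted profile fields a predicate tree references."""
    out = set()
    if not isinstance(pred, dict):
        return out
    if "field" in pred:
        out.add(pred["field"])
    if pred.get("op") == "class":
        out.add("codes." + pred["dim"])
    for a in pred.get("args", ()):  # type: ignore[union-attr]
        out |= predicate_fields(a)
    return out


# ------------------------------------------------------------------ loading

def default_keys_path() -> Path:
    return Path(str(resources.files("hebkeys").joinpath("data", "keys.json")))


def _materialize_leads(raw_leads) -> list[Lead]:
    leads = []
    for rl in raw_leads:
        pred = rl["pred"]
        if pred == "complement":
            if not leads:
                raise KeyError_("complement lead cannot come first")
            pred = {"op": "not", "args": [leads[0].pred]}
        leads.append(Lead(pred=pred, outcome=rl["outcome"],
                          text=rl.get("text", "")))
    return leads


def load_keys(path=None) -> dict[str, KeyDefinition]:
    """Load the key file and verify its structural invariants: every referenced
    couplet and key exists, no cycles, every taxon reachable from the sections
    key."""
    path = Path(path) if path is not None else default_keys_path()
    raw = json.loads(Path(path).read_text())
    keys = {}
    for name, body in raw.items():
        if name.startswith("_"):
            continue
        couplets = {int(n): _materialize_leads(leads)
                    for n, leads in body["couplets"].items()}
        keys[name] = KeyDefinition(name=name, entry=int(body.get("entry", 1)),
                                   couplets=couplets)
    _check_structure(keys)
    return keys


def _check_structure(keys: dict[str, KeyDefinition]) -> None:
    for kname, kd in keys.items():
        for cnum, leads in kd.couplets.items():
            for lead in leads:
                out = lead.outcome
                if out["type"] == "couplet":
                    if out["n"] not in kd.couplets:
                        raise KeyError_(
                            f"{kname} couplet {cnum}: dangling reference to "
                            f"couplet {out['n']}")
                elif out["type"] == "key":
                    tgt = keys.get(out["name"])
                    if tgt is None:
                        raise KeyError_(f"{kname}: dangling key {out['name']}")
                    entry = out.get("entry", tgt.entry)
                    if entry not in tgt.couplets:
                        raise KeyError_(
                            f"{kname}: entry couplet {entry} missing in "
                            f"{out['name']}")
                elif out["type"] != "taxon":
                    raise KeyError_(f"unknown outcome type: {out['type']}")
    # acyclicity within each key (couplet graph must be a DAG)
    for kname, kd in keys.items():
        state = {}

        def visit(n):
            if state.get(n) == 1:
                raise KeyError_(f"{kname}: cycle through couplet {n}")
            if state.get(n) == 2:
                return
            state[n] = 1
            for lead in kd.couplets[n]:
                if lead.outcome["type"] == "couplet":
                    visit(lead.outcome["n"])
            state[n] = 2

        for n in list(kd.couplets):
            visit(n)


def reachable_taxa(keys: dict[str, KeyDefinition], key_name: str,
                   couplet: Optional[int] = None) -> frozenset:
    """All terminal taxa reachable from a couplet (default: the key's entry)."""
    kd = keys[key_name]
    start = couplet if couplet is not None else kd.entry
    out, stack, seen = set(), [(key_name, start)], set()
    while stack:
        kn, cn = stack.pop()
        if (kn, cn) in seen:
            continue
        seen.add((kn, cn))
        for lead in keys[kn].couplets[cn]:
            o = lead.outcome
            if o["type"] == "taxon":
                out.add(o["name"])
            elif o["type"] == "couplet":
                stack.append((kn, o["n"]))
            else:
                tgt = keys[o["name"]]
                stack.append((o["name"], o.get("entry", tgt.entry)))
    return frozenset(out)


# ---------------------------------------------------------------- traversal

def identify(profile: SpecimenProfile,
             keys: Optional[dict[str, KeyDefinition]] = None,
             entry_key: str = "sections") -> Identification:
    """Run a specimen through the keys.

    Deterministic while predicates resolve; at an unknown predicate both leads
    are explored and the union of reachable taxa is returned.  The recorded
    path covers the deterministic prefix of the traversal.
    """
    if keys is None:
        keys = load_keys()
    path: list = []
    indeterminate: list = []
    visited: list = []
    memo: dict = {}

    def walk(key_name: str, couplet: int, deterministic: bool) -> set:
        kd = keys[key_name]
        if (key_name, couplet) in memo:
            return memo[(key_name, couplet)]
        visited.append((key_name, couplet))
        leads = kd.couplets[couplet]
        values = [evaluate_predicate(l.pred, profile) for l in leads]
        chosen: list[int] = []
        first_true = next((i for i, v in enumerate(values) if v is True), None)
        if first_true is not None and all(v is False for v in values[:first_true]):
            chosen = [first_true]
        else:
            chosen = [i for i, v in enumerate(values) if v is not False]
        if not chosen:
            # the printed leads are not exhaustive for this profile: the
            # couplet gives no guidance, so explore every lead, honestly
            # flagged in the path
            path.append((key_name, couplet, "no_lead_matched"))
            chosen = list(range(len(leads)))
        if len(chosen) > 1:
            for i in chosen:
                for f in sorted(predicate_fields(leads[i].pred)):
                    if f not in indeterminate:
                        indeterminate.append(f)
        out: set = set()
        for i in chosen:
            det = deterministic and len(chosen) == 1
            if det:
                path.append((key_name, couplet, i))
            o = leads[i].outcome
            if o["type"] == "taxon":
                out.add(o["name"])
            elif o["type"] == "couplet":
                out |= walk(key_name, o["n"], det)
            else:
                tgt = keys[o["name"]]
                out |= walk(o["name"], o.get("entry", tgt.entry), det)
        memo[(key_name, couplet)] = out
        return out

    result = walk(entry_key, keys[entry_key].entry, True)
    res: object = next(iter(result)) if len(result) == 1 else frozenset(result)
    return Identification(result=res, path=path,
                          indeterminate_traits=indeterminate, visited=visited)


# --------------------------------------------------------------- validation

def _numeric_thresholds(keys: dict[str, KeyDefinition]):
    """(field, value, (key, couplet)) for every numeric comparison."""
    out = []

    def scan(pred, where):
        if not isinstance(pred, dict):
            return
        if pred.get("op") == "cmp":
            out.append((pred["field"], float(pred["value"]), where))
        for a in pred.get("args", ()):
            scan(a, where)

    for kname, kd in keys.items():
        for cnum, leads in kd.couplets.items():
            for lead in leads:
                scan(lead.pred, (kname, cnum))
    return out


_FIELD_TO_INTERVAL = {
    "spores.mean_length": "spore_mean_length_range",
    "spores.mean_width": "spore_mean_width_range",
    "spores.mean_q": "spore_mean_q_range",
    "lamellae_count": "lamellae_count_range",
}


def validate_keys_against_taxa(keys: dict[str, KeyDefinition],
                               taxa) -> dict:
    """Audit the keys against the trait database.

    For every species, routes its centroid profile through the keys and
    reports whether it identifies correctly (``correct``), lands in a candidate
    set containing it (``contained``) or misroutes (``conflict``).  Also lists
    boundary collisions: numeric thresholds at couplets on the species'
    traversal that fall inside (or on an endpoint of) its described range —
    real collections of such a species can land on either side of the couplet.
    Conflicts are reported, never repaired.
    """
    from .taxon_db import centroid_profile

    report = {"species": {}, "boundary_collisions": [], "conflicts": []}
    thresholds = _numeric_thresholds(keys)
    for t in taxa:
        entry = {"centroid": None, "status": None, "collisions": []}
        try:
            prof = centroid_profile(t)
        except Exception as exc:                       # noqa: BLE001
            entry["status"] = "unidentifiable"
            entry["error"] = str(exc)
            report["species"][t.name] = entry
            report["conflicts"].append((t.name, "unidentifiable"))
            continue
        ident = identify(prof, keys)
        cands = ident.candidates
        entry["centroid"] = sorted(cands)
        if cands == {t.name}:
            entry["status"] = "correct"
        elif t.name in cands:
            entry["status"] = "contained"
        else:
            entry["status"] = "conflict"
            report["conflicts"].append((t.name, sorted(cands)))
        on_path = set(ident.visited)
        for fld, val, where in sorted(set(thresholds)):
            if where not in on_path:
                continue
            ivname = _FIELD_TO_INTERVAL.get(fld)
            if ivname is None:
                continue
            iv = getattr(t, ivname)
            if iv is not None and iv.lo <= val <= iv.hi:
                coll = (t.name, fld, val, where)
                entry["collisions"].append((fld, val, where))
                report["boundary_collisions"].append(coll)
        report["species"][t.name] = entry
    return report
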
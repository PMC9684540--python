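"""Declarative fold definitions: segments, pairings, sheets, constraints.

A fold definition is the ranged, fold-level description the builder
consumes: an ordered list of secondary-structure segments with length
ranges, loop ABEGO menus, element pairings (strand-strand with register
shifts and bulges, helix-helix, helix-sheet), sheet declarations, and
ambiguous distance constraints resolved only once lengths are chosen.

Two equivalent document dialects are supported (schema id "foldsmith/1"):
a YAML mapping and an XML form.  Unknown elements are a hard error, never a
silent skip.  Defaults applied on parse: constraint target 8 A, standard
deviation 2 A, harmonic functional form, bound width 1 A.
"""

from __future__ import annotations

import io
import math
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from xml.etree import ElementTree

import yaml

SCHEMA_VERSION = "foldsmith/1"

DEFAULT_TARGET = 8.0
DEFAULT_SD = 2.0
DEFAULT_FUNCTION = "harmonic"
DEFAULT_BOUND_WIDTH = 1.0

ANCHORS = ("N-end", "C-end", "midpoint")
KINDS = ("helix", "strand", "loop")
MIN_LENGTH = {"helix": 6, "strand": 3, "loop": 1}


class FoldDefinitionError(ValueError):
    """Raised for schema violations; the message names the offending element."""


@dataclass
class SegmentSpec:
    name: str
    kind: str  # helix | strand | loop
    length_range: tuple[int, int]
    loop_abegos: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise FoldDefinitionError(f"segment {self.name}: empty length range")
        if self.kind not in KINDS:
            raise FoldDefinitionError(f"segment {self.name}: unknown kind {self.kind!r}")
        if lo < MIN_LENGTH[self.kind]:
            raise FoldDefinitionError(
                f"segment {self.name}: {self.kind} minimum length is {MIN_LENGTH[self.kind]}"
            )
        if self.kind != "loop" and self.loop_abegos:
            raise FoldDefinitionError(f"segment {self.name}: ABEGO menu only valid on loops")
        for a in self.loop_abegos:
            if not (lo <= len(a) <= hi):
                raise FoldDefinitionError(
                    f"segment {self.name}: loop ABEGO {a!r} outside length range"
                )

    @property
    def ss_letter(self) -> str:
        return {"helix": "H", "strand": "E", "loop": "L"}[self.kind]


@dataclass
class StrandPairingSpec:
    first: str
    second: str
    orientation: str  # parallel | antiparallel
    register_range: tuple[int, int] = (0, 0)
    bulges: tuple[tuple[str, int], ...] = ()  # (segment, 1-based strand-local index)

    def __post_init__(self) -> None:
        if self.orientation not in ("parallel", "antiparallel"):
            raise FoldDefinitionError(
                f"pairing {self.first}-{self.second}: bad orientation {self.orientation!r}"
            )
        if self.first == self.second:
            raise FoldDefinitionError(f"strand {self.first} paired to itself")
        if self.register_range[0] > self.register_range[1]:
            raise FoldDefinitionError(
                f"pairing {self.first}-{self.second}: empty register range"
            )


@dataclass
class HelixPairingSpec:
    first: str
    second: str
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ("parallel", "antiparallel"):
            raise FoldDefinitionError(
                f"helix pairing {self.first}-{self.second}: bad orientation"
            )


@dataclass
class HelixSheetPairingSpec:
    helix: str
    strands: tuple[str, ...]


@dataclass
class ConstraintSpec:
    a: tuple[str, str]  # (segment name, anchor)
    b: tuple[str, str]
    function: str = DEFAULT_FUNCTION  # harmonic | bounded
    target: float = DEFAULT_TARGET
    sd: float = DEFAULT_SD
    bound_width: float = DEFAULT_BOUND_WIDTH

    def __post_init__(self) -> None:
        for seg, anchor in (self.a, self.b):
            if anchor not in ANCHORS:
                raise FoldDefinitionError(f"constraint on {seg}: unknown anchor {anchor!r}")
        if self.function not in ("harmonic", "bounded"):
            raise FoldDefinitionError(f"constraint: unknown function {self.function!r}")
        if self.target <= 0 or self.sd <= 0:
            raise FoldDefinitionError("constraint: target and sd must be positive")


@dataclass
class SheetSpec:
    """Spatially ordered strand list: adjacent entries are paired neighbors."""

    strands: tuple[str, ...]


@dataclass
class FoldDefinition:
    segments: list[SegmentSpec]
    strand_pairings: list[StrandPairingSpec] = field(default_factory=list)
    helix_pairings: list[HelixPairingSpec] = field(default_factory=list)
    helix_sheet_pairings: list[HelixSheetPairingSpec] = field(default_factory=list)
    constraints: list[ConstraintSpec] = field(default_factory=list)
    sheets: list[SheetSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise FoldDefinitionError(f"duplicate segment names: {sorted(dupes)}")
        self._by_name = {s.name: s for s in self.segments}
        prev = None
        for s in self.segments:
            if prev is not None and prev.kind != "loop" and s.kind != "loop":
                raise FoldDefinitionError(
                    f"adjacent elements {prev.name},{s.name} lack a connecting loop"
                )
            prev = s
        self._check_references()

    # -- lookups ----------------------------------------------------------
    def segment(self, name: str) -> SegmentSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise FoldDefinitionError(f"unknown segment {name!r}") from None

    @property
    def segment_names(self) -> list[str]:
        return [s.name for s in self.segments]

    def ss_segments(self) -> list[SegmentSpec]:
        return [s for s in self.segments if s.kind != "loop"]

    def _check_references(self) -> None:
        for p in self.strand_pairings:
            for nm in (p.first, p.second):
                if self.segment(nm).kind != "strand":
                    raise FoldDefinitionError(f"pairing references non-strand {nm!r}")
            for seg, idx in p.bulges:
                self.segment(seg)
                if idx < 1:
                    raise FoldDefinitionError(f"bulge index must be >= 1 on {seg}")
        for p in self.helix_pairings:
            for nm in (p.first, p.second):
                if self.segment(nm).kind != "helix":
                    raise FoldDefinitionError(f"helix pairing references non-helix {nm!r}")
        for p in self.helix_sheet_pairings:
            if self.segment(p.helix).kind != "helix":
                raise FoldDefinitionError(f"helix-sheet pairing: {p.helix!r} is not a helix")
            for nm in p.strands:
                if self.segment(nm).kind != "strand":
                    raise FoldDefinitionError(f"helix-sheet pairing: {nm!r} is not a strand")
        for sh in self.sheets:
            for nm in sh.strands:
                if self.segment(nm).kind != "strand":
                    raise FoldDefinitionError(f"sheet lists non-strand {nm!r}")
        for c in self.constraints:
            self.segment(c.a[0])
            self.segment(c.b[0])
        # register ranges must leave >= 2 paired residues for every length choice
        for p in self.strand_pairings:
            s1, s2 = self.segment(p.first), self.segment(p.second)
            for l1, l2 in itertools.product(
                range(s1.length_range[0], s1.length_range[1] + 1),
                range(s2.length_range[0], s2.length_range[1] + 1),
            ):
                for r in range(p.register_range[0], p.register_range[1] + 1):
                    if len(partner_pairs_local(p, l1, l2, r)) < 2:
                        raise FoldDefinitionError(
                            f"pairing {p.first}-{p.second}: register {r} leaves "
                            f"<2 paired residues at lengths ({l1},{l2})"
                        )


# ---------------------------------------------------------------------------
# strand register arithmetic


def _effective_indices(pairing: StrandPairingSpec, name: str, length: int) -> list[int | None]:
    """Pairing-effective index per 0-based residue; None marks a bulge residue.

    A bulge at strand-local index k (1-based) is itself unpaired and shifts
    the register of every later residue by one.
    """
    bulge_locals = sorted(idx - 1 for seg, idx in pairing.bulges if seg == name)
    eff: list[int | None] = []
    shift = 0
    for i in range(length):
        if i in bulge_locals:
            eff.append(None)
            shift += 1
        else:
            eff.append(i - shift)
    return eff


def partner_pairs_local(
    pairing: StrandPairingSpec, len1: int, len2: int, register: int
) -> list[tuple[int, int]]:
    """0-based (i, j) partner pairs between the two strands at a register.

    Parallel pairing aligns effective indices with an offset of ``register``;
    antiparallel pairing reverses the second strand.  Bulge residues never
    pair.
    """
    e1 = _effective_indices(pairing, pairing.first, len1)
    e2 = _effective_indices(pairing, pairing.second, len2)
    n2 = max((v for v in e2 if v is not None), default=-1) + 1
    inv2 = {v: j for j, v in enumerate(e2) if v is not None}
    pairs = []
    for i, v in enumerate(e1):
        if v is None:
            continue
        want = v - register if pairing.orientation == "parallel" else (n2 - 1) - v + register
        j = inv2.get(want)
        if j is not None:
            pairs.append((i, j))
    return pairs


def validate_sheet(fold: FoldDefinition) -> list[str]:
    """Check the no-unpaired-residue rule over every length combination.

    For each declared sheet and every combination of strand length choices,
    some register assignment (within the declared ranges) must leave every
    residue of every *inner* strand paired to a neighbor; outer strands may
    overhang.  Returns a list of human-readable violations (empty = ok).
    """
    violations: list[str] = []
    pair_lookup: dict[frozenset, StrandPairingSpec] = {}
    for p in fold.strand_pairings:
        pair_lookup[frozenset((p.first, p.second))] = p
    for sh in fold.sheets:
        strands = sh.strands
        if len(set(strands)) != len(strands):
            violations.append(f"sheet {strands}: strand repeated")
            continue
        neighbor_pairings = []
        for a, b in zip(strands, strands[1:]):
            p = pair_lookup.get(frozenset((a, b)))
            if p is None:
                violations.append(f"sheet {strands}: no pairing declared for {a}-{b}")
            neighbor_pairings.append(p)
        if any(p is None for p in neighbor_pairings):
            continue
        ranges = [fold.segment(n).length_range for n in strands]
        for lengths in itertools.product(*(range(lo, hi + 1) for lo, hi in ranges)):
            if not _sheet_coverable(strands, neighbor_pairings, lengths):
                violations.append(
                    f"sheet {strands}: inner strand uncoverable at lengths "
                    f"{dict(zip(strands, lengths))}"
                )
    return violations


def _sheet_coverable(strands, pairings, lengths) -> bool:
    reg_ranges = [range(p.register_range[0], p.register_range[1] + 1) for p in pairings]
    by_name = dict(zip(strands, lengths))
    for regs in itertools.product(*reg_ranges):
        if sheet_coverage_ok(strands, pairings, by_name, regs):
            return True
    return False


def sheet_coverage_ok(strands, pairings, lengths_by_name, registers) -> bool:
    """True if every inner-strand residue pairs with a neighbor at these registers."""
    covered: dict[str, set[int]] = {n: set() for n in strands}
    for p, r in zip(pairings, registers):
        l1 = lengths_by_name[p.first]
        l2 = lengths_by_name[p.second]
        for i, j in partner_pairs_local(p, l1, l2, r):
            covered[p.first].add(i)
            covered[p.second].add(j)
    for name in strands[1:-1]:
        length = lengths_by_name[name]
        bulges = {idx - 1 for pr in pairings if pr is not None
                  for seg, idx in pr.bulges if seg == name}
        need = set(range(length)) - bulges
        if not need <= covered[name]:
            return False
    return True


# ---------------------------------------------------------------------------
# residue numbering


def segment_bounds(fold: FoldDefinition, chosen_lengths: dict[str, int]) -> dict[str, tuple[int, int]]:
    """1-based inclusive (start, end) per segment for the chosen lengths."""
    bounds = {}
    pos = 1
    for s in fold.segments:
        L = chosen_lengths.get(s.name)
        if L is None:
            raise FoldDefinitionError(f"no length chosen for {s.name}")
        lo, hi = s.length_range
        if not (lo <= L <= hi):
            raise FoldDefinitionError(f"length {L} outside range for {s.name}")
        bounds[s.name] = (pos, pos + L - 1)
        pos += L
    return bounds


def resolve_segment(
    fold: FoldDefinition, chosen_lengths: dict[str, int], name: str, anchor: str
) -> int:
    """Resolve (segment, anchor) to a 1-based residue index in the full chain."""
    if anchor not in ANCHORS:
        raise FoldDefinitionError(f"unknown anchor {anchor!r}")
    start, end = segment_bounds(fold, chosen_lengths)[_checked_name(fold, name)]
    if anchor == "N-end":
        return start
    if anchor == "C-end":
        return end
    return (start + end) // 2


def _checked_name(fold: FoldDefinition, name: str) -> str:
    fold.segment(name)
    return name


# ---------------------------------------------------------------------------
# parsing — YAML dialect


_SEGMENT_KEYS = {"name", "kind", "length", "abego"}
_STRAND_PAIRING_KEYS = {"type", "first", "second", "orientation", "register", "bulges"}
_HELIX_PAIRING_KEYS = {"type", "first", "second", "orientation"}
_HS_PAIRING_KEYS = {"type", "helix", "strands"}
_CONSTRAINT_KEYS = {"a", "b", "function", "target", "sd", "bound_width"}
_TOP_KEYS = {"foldsmith", "segments", "pairings", "constraints", "sheets"}


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise FoldDefinitionError(f"{where}: unknown element(s) {sorted(unknown)}")


def _pair_range(value) -> tuple[int, int]:
    if isinstance(value, int):
        return (value, value)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return (int(value[0]), int(value[1]))
    raise FoldDefinitionError(f"bad range {value!r}")


def _anchor_ref(value, where: str) -> tuple[str, str]:
    if isinstance(value, str) and ":" in value:
        seg, anchor = value.split(":", 1)
        return (seg, anchor)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return (str(value[0]), str(value[1]))
    raise FoldDefinitionError(f"{where}: bad anchor reference {value!r}")


def _from_mapping(doc: dict) -> FoldDefinition:
    if not isinstance(doc, dict):
        raise FoldDefinitionError("document root must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "document")
    if doc.get("foldsmith") not in (1, "1", SCHEMA_VERSION):
        raise FoldDefinitionError("missing or unsupported 'foldsmith' schema version")
    segments = []
    for raw in doc.get("segments", []):
        _reject_unknown(raw, _SEGMENT_KEYS, f"segment {raw.get('name')}")
        segments.append(
            SegmentSpec(
                name=str(raw["name"]),
                kind=str(raw["kind"]),
                length_range=_pair_range(raw["length"]),
                loop_abegos=tuple(raw.get("abego", ())),
            )
        )
    sp, hp, hsp = [], [], []
    for raw in doc.get("pairings", []):
        ptype = raw.get("type")
        if ptype == "strand":
            _reject_unknown(raw, _STRAND_PAIRING_KEYS, "strand pairing")
            sp.append(
                StrandPairingSpec(
                    first=str(raw["first"]),
                    second=str(raw["second"]),
                    orientation=str(raw["orientation"]),
                    register_range=_pair_range(raw.get("register", 0)),
                    bulges=tuple((str(b[0]), int(b[1])) for b in raw.get("bulges", ())),
                )
            )
        elif ptype == "helix":
            _reject_unknown(raw, _HELIX_PAIRING_KEYS, "helix pairing")
            hp.append(
                HelixPairingSpec(
                    first=str(raw["first"]),
                    second=str(raw["second"]),
                    orientation=str(raw["orientation"]),
                )
            )
        elif ptype == "helix_sheet":
            _reject_unknown(raw, _HS_PAIRING_KEYS, "helix-sheet pairing")
            hsp.append(
                HelixSheetPairingSpec(
                    helix=str(raw["helix"]), strands=tuple(raw["strands"])
                )
            )
        else:
            raise FoldDefinitionError(f"pairing: unknown type {ptype!r}")
    constraints = []
    for raw in doc.get("constraints", []):
        _reject_unknown(raw, _CONSTRAINT_KEYS, "constraint")
        constraints.append(
            ConstraintSpec(
                a=_anchor_ref(raw["a"], "constraint"),
                b=_anchor_ref(raw["b"], "constraint"),
                function=str(raw.get("function", DEFAULT_FUNCTION)),
                target=float(raw.get("target", DEFAULT_TARGET)),
                sd=float(raw.get("sd", DEFAULT_SD)),
                bound_width=float(raw.get("bound_width", DEFAULT_BOUND_WIDTH)),
            )
        )
    sheets = [SheetSpec(strands=tuple(s)) for s in doc.get("sheets", ())]
    return FoldDefinition(
        segments=segments,
        strand_pairings=sp,
        helix_pairings=hp,
        helix_sheet_pairings=hsp,
        constraints=constraints,
        sheets=sheets,
    )


# ---------------------------------------------------------------------------
# parsing — XML dialect


def _from_xml(root: ElementTree.Element) -> FoldDefinition:
    if root.tag != "FoldDefinition":
        raise FoldDefinitionError(f"root element must be FoldDefinition, got {root.tag}")
    if root.get("version") != SCHEMA_VERSION:
        raise FoldDefinitionError("missing or unsupported schema version attribute")
    doc: dict = {"foldsmith": 1, "segments": [], "pairings": [], "constraints": [], "sheets": []}
    for el in root:
        if el.tag == "Segment":
            seg = {"name": el.get("name"), "kind": el.get("kind"),
                   "length": [int(el.get("min")), int(el.get("max"))]}
            if el.get("abego"):
                seg["abego"] = el.get("abego").split(",")
            extra = set(el.keys()) - {"name", "kind", "min", "max", "abego"}
            if extra:
                raise FoldDefinitionError(f"Segment: unknown attribute(s) {sorted(extra)}")
            doc["segments"].append(seg)
        elif el.tag == "StrandPairing":
            reg = el.get("register", "0")
            reg_range = [int(v) for v in reg.split(":")] if ":" in reg else int(reg)
            bulges = [[b.get("segment"), int(b.get("index"))] for b in el if b.tag == "Bulge"]
            bad = [b.tag for b in el if b.tag != "Bulge"]
            if bad:
                raise FoldDefinitionError(f"StrandPairing: unknown child element(s) {bad}")
            doc["pairings"].append(
                {"type": "strand", "first": el.get("first"), "second": el.get("second"),
                 "orientation": el.get("orientation"), "register": reg_range,
                 "bulges": bulges}
            )
        elif el.tag == "HelixPairing":
            doc["pairings"].append(
                {"type": "helix", "first": el.get("first"), "second": el.get("second"),
                 "orientation": el.get("orientation")}
            )
        elif el.tag == "HelixSheetPairing":
            doc["pairings"].append(
                {"type": "helix_sheet", "helix": el.get("helix"),
                 "strands": el.get("strands").split(",")}
            )
        elif el.tag == "Sheet":
            doc["sheets"].append(el.get("strands").split(","))
        elif el.tag == "Constraint":
            c = {"a": el.get("a"), "b": el.get("b")}
            for key in ("function", "target", "sd", "bound_width"):
                if el.get(key) is not None:
                    c[key] = el.get(key)
            extra = set(el.keys()) - {"a", "b", "function", "target", "sd", "bound_width"}
            if extra:
                raise FoldDefinitionError(f"Constraint: unknown attribute(s) {sorted(extra)}")
            c["target"] = float(c.get("target", DEFAULT_TARGET))
            c["sd"] = float(c.get("sd", DEFAULT_SD))
            doc["constraints"].append(c)
        else:
            raise FoldDefinitionError(f"unknown element <{el.tag}>")
    return _from_mapping(doc)


def parse_fold_definition(document: str | Path) -> FoldDefinition:
    """Parse a fold definition from a path or document string (XML or YAML)."""
    text = None
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and Path(document).exists()
    ):
        text = Path(document).read_text()
    else:
        text = str(document)
    stripped = text.lstrip()
    if stripped.startswith("<"):
        try:
            root = ElementTree.parse(io.StringIO(text)).getroot()
        except ElementTree.ParseError as exc:
            raise FoldDefinitionError(f"malformed XML: {exc}") from exc
        return _from_xml(root)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FoldDefinitionError(f"malformed YAML: {exc}") from exc
    return _from_mapping(doc)


def serialize_fold_definition(fold: FoldDefinition) -> str:
    """Canonical YAML form; parse(serialize(parse(x))) is a fixed point."""
    doc: dict = {"foldsmith": 1, "segments": []}
    for s in fold.segments:
        seg: dict = {"name": s.name, "kind": s.kind, "length": list(s.length_range)}
        if s.loop_abegos:
            seg["abego"] = list(s.loop_abegos)
        doc["segments"].append(seg)
    pairings = []
    for p in fold.strand_pairings:
        item = {"type": "strand", "first": p.first, "second": p.second,
                "orientation": p.orientation, "register": list(p.register_range)}
        if p.bulges:
            item["bulges"] = [[seg, idx] for seg, idx in p.bulges]
        pairings.append(item)
    for p in fold.helix_pairings:
        pairings.append({"type": "helix", "first": p.first, "second": p.second,
                         "orientation": p.orientation})
    for p in fold.helix_sheet_pairings:
        pairings.append({"type": "helix_sheet", "helix": p.helix,
                         "strands": list(p.strands)})
    if pairings:
        doc["pairings"] = pairings
    if fold.constraints:
        doc["constraints"] = [
            {"a": list(c.a), "b": list(c.b), "function": c.function,
             "target": c.target, "sd": c.sd, "bound_width": c.bound_width}
            for c in fold.constraints
        ]
    if fold.sheets:
        doc["sheets"] = [list(sh.strands) for sh in fold.sheets]
    return yaml.safe_dump(doc, sort_keys=False)
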
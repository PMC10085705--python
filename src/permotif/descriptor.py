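"""Block-structured RNA motif descriptors: parsing, permutation, topology.

A motif is modelled as a set of *blocks* — indivisible runs of conserved
sequence and stem half-sites whose internal 5'→3' order is fixed — plus a set
of stems whose two halves sit in (possibly different) blocks.  Reordering the
blocks yields the permuted forms of the motif; the relative order of the stem
halves along the sequence then determines whether the stems nest (a helical
junction) or interleave (pseudoknots).

The canonical example is the hammerhead ribozyme: Block C carries the
conserved CUGAnGA core between halves of stems I and II, Block G carries GAAA
between halves of stems II and III, and Block S carries the cleavage site
between halves of stems III and I.  Its three previously known circular
permutations (types I/II/III = block orders CGS/GSC/SCG) form a three-stem
junction; the three non-circular orders (SGC/CSG/GCS) are pseudoknotted.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "MotifElement",
    "StemSpec",
    "Block",
    "MotifDescriptor",
    "PermutationLayout",
    "LayoutItem",
    "TopologyReport",
    "DescriptorError",
    "parse_descriptor",
    "serialize_descriptor",
    "enumerate_permutations",
    "layout_for",
    "count_pseudoknots",
    "hammerhead_descriptor",
    "twister_descriptor",
    "HAMMERHEAD_DESCRIPTOR_TEXT",
    "TWISTER_DESCRIPTOR_TEXT",
    "IUPAC_SETS",
]

# IUPAC degenerate nucleotide codes over the RNA alphabet.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

WATSON_CRICK: frozenset[tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
)
WOBBLE: frozenset[tuple[str, str]] = frozenset([("G", "U"), ("U", "G")])

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class DescriptorError(ValueError):
    """Raised on a malformed descriptor, with the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _normalize_rna(s: str) -> str:
    return s.upper().replace("T", "U")


@dataclass(frozen=True)
class MotifElement:
    """One matchable unit inside a block.

    kind is one of ``literal`` (degenerate IUPAC string), ``stem_half``
    (one side of a declared stem; carries no sequence), ``spacer``
    (unconserved run with a length range), or ``cleavage_site`` (a
    zero-width inter-nucleotide marker).
    """

    kind: str
    literal: str | None = None
    stem_id: str | None = None
    side: str | None = None  # "first" | "second"
    length_range: tuple[int, int] | None = None

    def __post_init__(self):
        if self.kind == "literal":
            if not self.literal:
                raise ValueError("literal element requires a sequence")
            bad = set(self.literal) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"non-IUPAC characters in literal: {sorted(bad)}")
        elif self.kind == "stem_half":
            if self.stem_id is None or self.side not in ("first", "second"):
                raise ValueError("stem_half requires stem_id and side first/second")
            if self.literal is not None:
                raise ValueError("stem_half elements carry no sequence")
        elif self.kind == "spacer":
            lo, hi = self.length_range or (None, None)
            if lo is None or hi is None or lo < 0 or lo > hi:
                raise ValueError("spacer requires 0 <= min <= max")
        elif self.kind == "cleavage_site":
            pass
        else:
            raise ValueError(f"unknown element kind {self.kind!r}")


@dataclass(frozen=True)
class StemSpec:
    """Length range and pairing policy for one stem."""

    stem_id: str
    min_len: int
    max_len: int
    wobble_allowed: bool = False
    mismatch_budget: int = 0
    required: bool = True

    def __post_init__(self):
        if self.min_len < 1 or self.min_len > self.max_len:
            raise ValueError(f"stem {self.stem_id}: need 1 <= min <= max")
        if self.mismatch_budget < 0 or self.mismatch_budget >= self.min_len:
            raise ValueError(
                f"stem {self.stem_id}: mismatch budget must be >= 0 and < min length"
            )


@dataclass(frozen=True)
class Block:
    """An indivisible, ordered run of elements; order is fixed under permutation."""

    label: str
    elements: tuple[MotifElement, ...]

    def __post_init__(self):
        if len(self.label) != 1:
            raise ValueError("block labels are single characters")
        if not self.elements:
            raise ValueError(f"block {self.label} is empty")


@dataclass(frozen=True)
class MotifDescriptor:
    """A permutable motif: blocks, stems, and the inter-block linker range."""

    name: str
    blocks: tuple[Block, ...]
    stems: tuple[StemSpec, ...]
    linker_range: tuple[int, int] = (0, 50)
    notes: str = ""

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    def stem(self, stem_id: str) -> StemSpec:
        for s in self.stems:
            if s.stem_id == stem_id:
                return s
        raise KeyError(stem_id)

    def block(self, label: str) -> Block:
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(label)

    def half_placements(self) -> dict[str, list[tuple[str, int, str]]]:
        """Map stem_id -> [(block label, element index, side), ...]."""
        out: dict[str, list[tuple[str, int, str]]] = {}
        for b in self.blocks:
            for i, e in enumerate(b.elements):
                if e.kind == "stem_half":
                    out.setdefault(e.stem_id, []).append((b.label, i, e.side))
        return out

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("descriptor needs at least one block")
        labels = [b.label for b in self.blocks]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate block label")
        lo, hi = self.linker_range
        if lo < 0 or lo > hi:
            raise ValueError("linker range must satisfy 0 <= min <= max")
        ids = [s.stem_id for s in self.stems]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate stem id")
        placed = self.half_placements()
        declared = set(ids)
        for sid in placed:
            if sid not in declared:
                raise ValueError(f"undeclared stem reference: {sid}")
        for s in self.stems:
            halves = placed.get(s.stem_id, [])
            sides = sorted(h[2] for h in halves)
            if s.required:
                if sides != ["first", "second"]:
                    raise ValueError(
                        f"required stem {s.stem_id} must have exactly one first "
                        f"and one second half placed (found {len(halves)})"
                    )
            else:
                # optional stems (e.g. the loop I-loop II interaction) may be
                # declared without placed halves; if placed, both halves must be
                if sides not in ([], ["first", "second"]):
                    raise ValueError(
                        f"optional stem {s.stem_id} must place zero or two halves"
                    )
        n_cleave = sum(
            1 for b in self.blocks for e in b.elements if e.kind == "cleavage_site"
        )
        if n_cleave > 1:
            raise ValueError("at most one cleavage site per descriptor")


@dataclass(frozen=True)
class LayoutItem:
    """One linearized slot of a permutation: an element or an inter-block linker."""

    element: MotifElement
    block_label: str | None  # None for linkers
    slot: int


@dataclass(frozen=True)
class PermutationLayout:
    """A block ordering linearized into slots, with per-stem linear extents."""

    descriptor: MotifDescriptor
    order: tuple[str, ...]
    items: tuple[LayoutItem, ...]
    stem_extents: dict[str, tuple[int, int]] = field(compare=False, default_factory=dict)

    @property
    def type_name(self) -> str:
        return "".join(self.order)


def _linearize(descriptor: MotifDescriptor, order: tuple[str, ...]) -> PermutationLayout:
    items: list[LayoutItem] = []
    slot = 0
    linker = MotifElement(kind="spacer", length_range=descriptor.linker_range)
    for i, label in enumerate(order):
        if i > 0:
            items.append(LayoutItem(element=linker, block_label=None, slot=slot))
            slot += 1
        for e in descriptor.block(label).elements:
            items.append(LayoutItem(element=e, block_label=label, slot=slot))
            slot += 1
    extents: dict[str, tuple[int, int]] = {}
    for it in items:
        e = it.element
        if e.kind == "stem_half":
            if e.stem_id in extents:
                extents[e.stem_id] = (extents[e.stem_id][0], it.slot)
            else:
                extents[e.stem_id] = (it.slot, it.slot)
    # drop stems with only one/zero placed halves (optional, unplaced)
    extents = {k: v for k, v in extents.items() if v[0] != v[1]}
    return PermutationLayout(
        descriptor=descriptor, order=order, items=tuple(items), stem_extents=extents
    )


def enumerate_permutations(descriptor: MotifDescriptor) -> list[PermutationLayout]:
    """All n! block orderings, sorted lexicographically by type name."""
    orders = sorted(itertools.permutations(b.label for b in descriptor.blocks))
    return [_linearize(descriptor, tuple(o)) for o in orders]


def layout_for(descriptor: MotifDescriptor, type_name: str) -> PermutationLayout:
    """The layout for one block order given by its type name (e.g. ``"SGC"``)."""
    labels = {b.label for b in descriptor.blocks}
    if sorted(type_name) != sorted(labels):
        raise ValueError(
            f"type name {type_name!r} is not an ordering of blocks {sorted(labels)}"
        )
    return _linearize(descriptor, tuple(type_name))


@dataclass(frozen=True)
class TopologyReport:
    crossing_pairs: int
    classification: str  # "junction" | "pseudoknotted"
    crossings: tuple[tuple[str, str], ...]


def count_pseudoknots(
    layout: PermutationLayout, include_optional: bool = False
) -> TopologyReport:
    """Count crossing stem pairs in a linearized permutation.

    Two stems with linear extents (i, j) and (i', j') cross when
    i < i' < j < j'.  A layout with zero crossings is a helical junction;
    otherwise it is pseudoknotted.  Optional stems (tertiary interactions)
    are excluded unless ``include_optional`` is set.
    """
    d = layout.descriptor
    stems = [
        sid
        for sid in layout.stem_extents
        if d.stem(sid).required or include_optional
    ]
    crossings = []
    for a, b in itertools.combinations(sorted(stems), 2):
        (i, j), (i2, j2) = layout.stem_extents[a], layout.stem_extents[b]
        if (i, j) > (i2, j2):
            (i, j), (i2, j2) = (i2, j2), (i, j)
            a, b = b, a
        if i < i2 < j < j2:
            crossings.append((a, b))
    n = len(crossings)
    return TopologyReport(
        crossing_pairs=n,
        classification="junction" if n == 0 else "pseudoknotted",
        crossings=tuple(crossings),
    )


# ---------------------------------------------------------------------------
# descriptor grammar
# ---------------------------------------------------------------------------
#
#   motif <name>
#   stem <id> len=<min>:<max> [wobble] [mismatch=<k>] [optional]
#   linker <min>:<max>
#   block <label>
#     seq <IUPAC>
#     stem5 <id> | stem3 <id>
#     spacer <min>:<max>
#     cleave
#   # comment

_RANGE_RE = re.compile(r"^(\d+):(\d+)$")


def _parse_range(tok: str, line: int) -> tuple[int, int]:
    m = _RANGE_RE.match(tok)
    if not m:
        raise DescriptorError(f"expected <min>:<max>, got {tok!r}", line)
    return int(m.group(1)), int(m.group(2))


def parse_descriptor(text: str) -> MotifDescriptor:
    """Parse a descriptor file; validates all invariants, normalizes T to U."""
    name: str | None = None
    stems: list[StemSpec] = []
    linker: tuple[int, int] = (0, 50)
    blocks: list[Block] = []
    cur_label: str | None = None
    cur_elems: list[MotifElement] = []
    lineno = 0

    def flush(line: int):
        nonlocal cur_label, cur_elems
        if cur_label is not None:
            try:
                blocks.append(Block(label=cur_label, elements=tuple(cur_elems)))
            except ValueError as e:
                raise DescriptorError(str(e), line) from e
            cur_label, cur_elems = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        toks = line.split()
        kw = toks[0]
        try:
            if kw == "motif":
                if len(toks) != 2:
                    raise DescriptorError("motif takes one name", lineno)
                name = toks[1]
            elif kw == "stem":
                if len(toks) < 3 or not toks[2].startswith("len="):
                    raise DescriptorError(
                        "stem syntax: stem <id> len=<min>:<max> [wobble]"
                        " [mismatch=<k>] [optional]",
                        lineno,
                    )
                lo, hi = _parse_range(toks[2][4:], lineno)
                wobble, mismatch, required = False, 0, True
                for t in toks[3:]:
                    if t == "wobble":
                        wobble = True
                    elif t == "optional":
                        required = False
                    elif t.startswith("mismatch="):
                        mismatch = int(t[9:])
                    else:
                        raise DescriptorError(f"unknown stem flag {t!r}", lineno)
                stems.append(
                    StemSpec(toks[1], lo, hi, wobble_allowed=wobble,
                             mismatch_budget=mismatch, required=required)
                )
            elif kw == "linker":
                linker = _parse_range(toks[1], lineno)
            elif kw == "block":
                flush(lineno)
                if len(toks) != 2:
                    raise DescriptorError("block takes one label", lineno)
                cur_label = toks[1]
            elif kw in ("seq", "stem5", "stem3", "spacer", "cleave"):
                if cur_label is None:
                    raise DescriptorError(f"{kw} outside a block", lineno)
                if kw == "seq":
                    cur_elems.append(
                        MotifElement(kind="literal", literal=_normalize_rna(toks[1]))
                    )
                elif kw in ("stem5", "stem3"):
                    cur_elems.append(
                        MotifElement(
                            kind="stem_half",
                            stem_id=toks[1],
                            side="first" if kw == "stem5" else "second",
                        )
                    )
                elif kw == "spacer":
                    cur_elems.append(
                        MotifElement(
                            kind="spacer", length_range=_parse_range(toks[1], lineno)
                        )
                    )
                else:  # cleave
                    cur_elems.append(MotifElement(kind="cleavage_site"))
            else:
                raise DescriptorError(f"unknown directive {kw!r}", lineno)
        except DescriptorError:
            raise
        except (ValueError, IndexError) as e:
            raise DescriptorError(str(e), lineno) from e
    flush(lineno)
    if name is None:
        raise DescriptorError("missing 'motif <name>' directive")
    try:
        return MotifDescriptor(
            name=name, blocks=tuple(blocks), stems=tuple(stems), linker_range=linker
        )
    except ValueError as e:
        raise DescriptorError(str(e)) from e


def serialize_descriptor(d: MotifDescriptor) -> str:
    """Emit descriptor text that parses back to an equal descriptor."""
    out = [f"motif {d.name}"]
    for s in d.stems:
        parts = [f"stem {s.stem_id} len={s.min_len}:{s.max_len}"]
        if s.wobble_allowed:
            parts.append("wobble")
        if s.mismatch_budget:
            parts.append(f"mismatch={s.mismatch_budget}")
        if not s.required:
            parts.append("optional")
        out.append(" ".join(parts))
    out.append(f"linker {d.linker_range[0]}:{d.linker_range[1]}")
    for b in d.blocks:
        out.append(f"block {b.label}")
        for e in b.elements:
            if e.kind == "literal":
                out.append(f"  seq {e.literal}")
            elif e.kind == "stem_half":
                out.append(
                    f"  {'stem5' if e.side == 'first' else 'stem3'} {e.stem_id}"
                )
            elif e.kind == "spacer":
                out.append(f"  spacer {e.length_range[0]}:{e.length_range[1]}")
            else:
                out.append("  cleave")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# built-in descriptors
# ---------------------------------------------------------------------------

HAMMERHEAD_DESCRIPTOR_TEXT = """\
# Hammerhead ribozyme core, decomposed into three permutable blocks.
# Block C: conserved CUGAnGA flanked by halves of stems I and II.
# Block G: conserved GAAA flanked by halves of stems II and III.
# Block S: cleavage site (3' of the NUH triplet) flanked by halves of
#          stems III and I.
# The ILII stem models the tertiary interaction between the loops of stems
# I and II; its halves sit in permutation-dependent loop regions, so it is
# declared optional and unplaced.
motif hammerhead
stem I len=3:8 wobble
stem II len=3:8 wobble
stem III len=2:8 wobble
stem ILII len=3:7 wobble optional
linker 0:50
block C
  stem5 I
  seq CUGANGA
  stem5 II
block G
  stem3 II
  seq GAAA
  stem5 III
block S
  stem3 III
  seq NUH
  cleave
  stem3 I
"""

TWISTER_DESCRIPTOR_TEXT = """\
# Twister ribozyme, approximate three-block decomposition.
# The published block figure is graphical; literals here keep only the
# conserved cleavage-site UA dinucleotide and a purine-rich internal loop,
# with representative stem length ranges.  This fixture is an approximation,
# suitable for permutation/topology arithmetic, not a faithful consensus.
motif twister
stem P1 len=3:8 wobble
stem P2 len=3:8 wobble
stem P4 len=2:7 wobble
linker 0:30
block T
  stem5 P1
  seq NU
  cleave
  seq AR
  stem5 P2
block U
  stem3 P2
  spacer 2:12
  stem5 P4
block V
  stem3 P4
  seq RA
  stem3 P1
"""


def hammerhead_descriptor() -> MotifDescriptor:
    """The built-in three-block hammerhead descriptor (stems I-III + optional I/II loop interaction)."""
    return parse_descriptor(HAMMERHEAD_DESCRIPTOR_TEXT)


def twister_descriptor() -> MotifDescriptor:
    """The built-in (approximate) three-block twister descriptor."""
    return parse_descriptor(TWISTER_DESCRIPTOR_TEXT)
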
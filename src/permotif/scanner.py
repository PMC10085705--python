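"""Compile permuted motif descriptors into search patterns and scan sequences.

A compiled pattern is the linearized element plan of one block permutation:
literals with IUPAC degeneracy, stem halves with length ranges and an
antiparallel complementarity constraint between the two halves (Watson-Crick,
optionally G.U wobble, with a per-stem mismatch budget), spacers and
inter-block linkers with length ranges, and an optional zero-width cleavage
marker.  Scanning is exhaustive backtracking over element lengths and
positions, so pseudoknotted permutations (crossing stems) are handled exactly
like nested ones; conserved literals are used as cheap window gates to prune
start positions.

Coordinates are 0-based half-open on the forward strand throughout (BED
convention).  T and U are treated as identical; matching is case-insensitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .descriptor import (
    IUPAC_SETS,
    WATSON_CRICK,
    WOBBLE,
    MotifDescriptor,
    PermutationLayout,
    StemSpec,
)

__all__ = [
    "ScanConfig",
    "PlanUnit",
    "CompiledPattern",
    "Match",
    "CleavageProducts",
    "compile_pattern",
    "scan",
    "scan_sequence",
    "scan_fasta",
    "matches_to_table",
    "predict_cleavage",
    "verify_match",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the RNA alphabet (input may be DNA; N kept)."""
    return _normalize(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanConfig:
    """Scan options: strand policy and N handling."""

    both_strands: bool = True
    allow_n: bool = False  # if True, N in the sequence matches any literal position


@dataclass(frozen=True)
class PlanUnit:
    index: int
    kind: str  # literal | stem_half | spacer | linker | cleave
    name: str
    min_len: int
    max_len: int
    literal: str | None = None
    stem_id: str | None = None
    side: str | None = None


@dataclass(frozen=True)
class CompiledPattern:
    """A (descriptor, permutation) pair lowered to an ordered matchable plan."""

    descriptor: MotifDescriptor
    layout: PermutationLayout
    units: tuple[PlanUnit, ...]
    stem_pairs: dict[str, tuple[int, int]] = field(compare=False, default_factory=dict)
    stem_specs: dict[str, StemSpec] = field(compare=False, default_factory=dict)
    min_total: int = 0
    max_total: int = 0
    cleave_index: int | None = None

    @property
    def type_name(self) -> str:
        return self.layout.type_name


def compile_pattern(
    descriptor: MotifDescriptor, layout: PermutationLayout
) -> CompiledPattern:
    """Lower one permutation layout into a linear plan with pairing constraints."""
    units: list[PlanUnit] = []
    stem_seen: dict[str, int] = {}
    stem_pairs: dict[str, tuple[int, int]] = {}
    n_linker = 0
    cleave_index = None
    for it in layout.items:
        e = it.element
        i = len(units)
        if it.block_label is None:
            n_linker += 1
            lo, hi = e.length_range
            units.append(PlanUnit(i, "linker", f"linker{n_linker}", lo, hi))
            continue
        prefix = it.block_label
        if e.kind == "literal":
            units.append(
                PlanUnit(i, "literal", f"{prefix}.seq:{e.literal}",
                         len(e.literal), len(e.literal), literal=e.literal)
            )
        elif e.kind == "spacer":
            lo, hi = e.length_range
            if hi is None:
                raise ValueError("unbounded spacer cannot be compiled")
            units.append(PlanUnit(i, "spacer", f"{prefix}.spacer", lo, hi))
        elif e.kind == "cleavage_site":
            if cleave_index is not None:
                raise ValueError("multiple cleavage sites")
            cleave_index = i
            units.append(PlanUnit(i, "cleave", f"{prefix}.cleave", 0, 0))
        elif e.kind == "stem_half":
            spec = descriptor.stem(e.stem_id)
            units.append(
                PlanUnit(i, "stem_half", f"{prefix}.stem:{e.stem_id}",
                         spec.min_len, spec.max_len,
                         stem_id=e.stem_id, side=e.side)
            )
            if e.stem_id in stem_seen:
                stem_pairs[e.stem_id] = (stem_seen[e.stem_id], i)
            else:
                stem_seen[e.stem_id] = i
    unpaired = set(stem_seen) - set(stem_pairs)
    if unpaired:
        raise ValueError(f"stem(s) with a single placed half: {sorted(unpaired)}")
    stem_specs = {sid: descriptor.stem(sid) for sid in stem_pairs}
    return CompiledPattern(
        descriptor=descriptor,
        layout=layout,
        units=tuple(units),
        stem_pairs=stem_pairs,
        stem_specs=stem_specs,
        min_total=sum(u.min_len for u in units),
        max_total=sum(u.max_len for u in units),
        cleave_index=cleave_index,
    )


@dataclass(frozen=True)
class CleavageProducts:
    site: int
    five_prime_len: int
    three_prime_len: int
    degenerate: bool


@dataclass(frozen=True)
class Match:
    """A located motif instance.

    ``start``/``end`` and all element spans are 0-based half-open on the
    forward strand; for minus-strand matches the spans have been mapped back
    from the reverse complement, and ``stem_seqs`` stay in transcript (scanned
    strand) orientation.
    """

    sequence_id: str
    strand: str
    start: int
    end: int
    type_name: str
    element_spans: tuple[tuple[str, int, int], ...]
    stem_seqs: dict[str, tuple[str, str]] = field(compare=False, default_factory=dict)
    predicted_cleavage: int | None = None

    def sort_key(self):
        return (self.sequence_id, self.start, self.type_name, self.end,
                self.element_spans)


# ---------------------------------------------------------------------------
# matching primitives
# ---------------------------------------------------------------------------

def _iupac_ok(seq_char: str, pat_char: str, allow_n: bool) -> bool:
    if seq_char == "N":
        return allow_n
    return seq_char in IUPAC_SETS[pat_char]


def _literal_positions(s: str, literal: str, allow_n: bool) -> np.ndarray:
    """Boolean array: literal matches s starting at each position."""
    L, k = len(s), len(literal)
    out = np.zeros(L, dtype=bool)
    for p in range(L - k + 1):
        ok = True
        for m in range(k):
            if not _iupac_ok(s[p + m], literal[m], allow_n):
                ok = False
                break
        out[p] = ok
    return out


def _pairing_mismatches(s: str, a0: int, b0: int, k: int, wobble: bool) -> int:
    """Antiparallel pairing mismatches between s[a0:a0+k] and s[b0:b0+k]."""
    bad = 0
    for m in range(k):
        x, y = s[a0 + m], s[b0 + k - 1 - m]
        pair = (x, y)
        if pair in WATSON_CRICK:
            continue
        if wobble and pair in WOBBLE:
            continue
        bad += 1
    return bad


def _gate_selectivity(literal: str) -> float:
    p = 1.0
    for c in literal:
        p *= len(IUPAC_SETS[c]) / 4.0
    return p


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan(
    sequence: str,
    pattern: CompiledPattern,
    config: ScanConfig | None = None,
    sequence_id: str = "",
) -> list[Match]:
    """All distinct placements of ``pattern`` on the forward strand of ``sequence``.

    Exhaustive backtracking over element lengths, shortest-first; output is
    deduplicated by (span, element spans) and sorted by (start, type name,
    end).
    """
    config = config or ScanConfig()
    s = _normalize(sequence)
    L = len(s)
    units = pattern.units
    n = len(units)
    if L < pattern.min_total:
        return []

    suffix_min = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_min[i] = suffix_min[i + 1] + units[i].min_len

    lit_arr: dict[str, np.ndarray] = {}
    for u in units:
        if u.kind == "literal" and u.literal not in lit_arr:
            lit_arr[u.literal] = _literal_positions(s, u.literal, config.allow_n)

    # window gates on selective literals: a start survives only if every such
    # literal has a hit inside its feasible offset window
    gates = []
    for u in units:
        if u.kind == "literal" and _gate_selectivity(u.literal) <= 1 / 64:
            lo = sum(units[j].min_len for j in range(u.index))
            hi = sum(units[j].max_len for j in range(u.index))
            csum = np.concatenate([[0], np.cumsum(lit_arr[u.literal])])
            gates.append((lo, hi, csum))

    results: list[Match] = []
    spans: list[tuple[int, int] | None] = [None] * n

    def emit(start: int, end: int) -> None:
        espans = tuple(
            (units[i].name, spans[i][0], spans[i][1]) for i in range(n)
        )
        stem_seqs = {}
        for sid, (ia, ib) in pattern.stem_pairs.items():
            (a0, a1), (b0, b1) = spans[ia], spans[ib]
            stem_seqs[sid] = (s[a0:a1], s[b0:b1])
        cleave = (
            spans[pattern.cleave_index][0]
            if pattern.cleave_index is not None
            else None
        )
        results.append(
            Match(
                sequence_id=sequence_id,
                strand="+",
                start=start,
                end=end,
                type_name=pattern.type_name,
                element_spans=espans,
                stem_seqs=stem_seqs,
                predicted_cleavage=cleave,
            )
        )

    def bt(i: int, pos: int, start: int) -> None:
        if i == n:
            emit(start, pos)
            return
        u = units[i]
        budget = L - pos - suffix_min[i + 1]  # max length available to this unit
        if u.kind == "cleave":
            spans[i] = (pos, pos)
            bt(i + 1, pos, start)
        elif u.kind == "literal":
            k = u.min_len
            if k <= budget and lit_arr[u.literal][pos]:
                spans[i] = (pos, pos + k)
                bt(i + 1, pos + k, start)
        elif u.kind in ("spacer", "linker"):
            for k in range(u.min_len, min(u.max_len, budget) + 1):
                spans[i] = (pos, pos + k)
                bt(i + 1, pos + k, start)
        else:  # stem_half
            spec = pattern.stem_specs[u.stem_id]
            first_i, second_i = pattern.stem_pairs[u.stem_id]
            if i == first_i:
                for k in range(spec.min_len, min(spec.max_len, budget) + 1):
                    spans[i] = (pos, pos + k)
                    bt(i + 1, pos + k, start)
            else:
                a0, a1 = spans[first_i]
                k = a1 - a0
                if k <= budget:
                    bad = _pairing_mismatches(s, a0, pos, k, spec.wobble_allowed)
                    if bad <= spec.mismatch_budget:
                        spans[i] = (pos, pos + k)
                        bt(i + 1, pos + k, start)
        spans[i] = None

    for start in range(L - pattern.min_total + 1):
        ok = True
        for lo, hi, csum in gates:
            w0 = start + lo
            w1 = min(start + hi, L - 1)
            if w0 > w1 or csum[w1 + 1] - csum[w0] == 0:
                ok = False
                break
        if ok:
            bt(0, start, start)

    seen = set()
    unique = []
    for m in sorted(results, key=Match.sort_key):
        key = (m.start, m.end, m.element_spans)
        if key not in seen:
            seen.add(key)
            unique.append(m)
    return unique


def _map_to_forward(m: Match, L: int) -> Match:
    """Map a match found on the reverse complement back to forward coordinates."""
    espans = tuple(
        sorted(((name, L - e, L - s) for name, s, e in m.element_spans),
               key=lambda t: (t[1], t[2]))
    )
    return Match(
        sequence_id=m.sequence_id,
        strand="-",
        start=L - m.end,
        end=L - m.start,
        type_name=m.type_name,
        element_spans=espans,
        stem_seqs=m.stem_seqs,
        predicted_cleavage=(
            None if m.predicted_cleavage is None else L - m.predicted_cleavage
        ),
    )


def scan_sequence(
    sequence: str,
    patterns: list[CompiledPattern],
    config: ScanConfig | None = None,
    sequence_id: str = "",
) -> list[Match]:
    """Scan one sequence with several patterns, optionally on both strands."""
    config = config or ScanConfig()
    out: list[Match] = []
    L = len(sequence)
    rc = reverse_complement(sequence) if config.both_strands else None
    for pat in patterns:
        out.extend(scan(sequence, pat, config, sequence_id=sequence_id))
        if rc is not None:
            for m in scan(rc, pat, config, sequence_id=sequence_id):
                out.append(_map_to_forward(m, L))
    return sorted(out, key=Match.sort_key)


def scan_fasta(
    fasta_path,
    descriptor: MotifDescriptor,
    type_names: list[str] | None = None,
    config: ScanConfig | None = None,
) -> list[Match]:
    """Scan every record of a FASTA file with all (or selected) permutations."""
    from .descriptor import enumerate_permutations, layout_for
    from .io import read_fasta

    if type_names is None:
        layouts = enumerate_permutations(descriptor)
    else:
        layouts = [layout_for(descriptor, t) for t in type_names]
    patterns = [compile_pattern(descriptor, lay) for lay in layouts]
    records = read_fasta(fasta_path)
    seen_ids = set()
    out: list[Match] = []
    for rec in records:
        if rec.id in seen_ids:
            raise ValueError(f"duplicate record ID in FASTA: {rec.id!r}")
        seen_ids.add(rec.id)
        out.extend(
            scan_sequence(str(rec.seq), patterns, config, sequence_id=rec.id)
        )
    return sorted(out, key=Match.sort_key)


def matches_to_table(matches: list[Match]):
    """BED-like table: seq_id, start, end, type, score, strand, elements (JSON)."""
    import pandas as pd

    rows = [
        {
            "seq_id": m.sequence_id,
            "start": m.start,
            "end": m.end,
            "name": m.type_name,
            "score": ".",
            "strand": m.strand,
            "elements": json.dumps(
                [[n, s, e] for n, s, e in m.element_spans], separators=(",", ":")
            ),
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows, columns=["seq_id", "start", "end", "name", "score", "strand", "elements"]
    )


def predict_cleavage(match: Match, construct: str) -> CleavageProducts:
    """Cleavage site and 5'/3' fragment lengths for a full-length construct.

    The site is the inter-nucleotide coordinate in transcript orientation
    (the scanned strand), so the 5' fragment length equals the site and the
    two fragment lengths always sum to the construct length.
    """
    if match.predicted_cleavage is None:
        raise ValueError("no cleavage site annotated in this descriptor")
    L = len(construct)
    site = match.predicted_cleavage
    if match.strand == "-":
        site = L - site
    return CleavageProducts(
        site=site,
        five_prime_len=site,
        three_prime_len=L - site,
        degenerate=(site == 0 or site == L),
    )


def verify_match(sequence: str, pattern: CompiledPattern, match: Match) -> bool:
    """Independent re-check of a reported match against the raw constraints.

    Checks: element spans tile the match span in order; literal spans satisfy
    their IUPAC patterns; spacer/linker/stem lengths lie in range; each stem's
    halves have equal length and pair antiparallel within policy.  Minus-strand
    matches are re-checked on the reverse complement.
    """
    s = _normalize(sequence)
    L = len(s)
    if match.strand == "-":
        s = reverse_complement(sequence)
        spans = [(name, L - e, L - s_) for name, s_, e in match.element_spans]
        spans.sort(key=lambda t: (t[1], t[2]))
        start, end = L - match.end, L - match.start
    else:
        spans = list(match.element_spans)
        start, end = match.start, match.end
    units = pattern.units
    if len(spans) != len(units):
        return False
    pos = start
    placed: dict[int, tuple[int, int]] = {}
    for u, (name, a, b) in zip(units, spans):
        if name != u.name or a != pos or b < a or b > L:
            return False
        k = b - a
        if u.kind == "literal":
            if k != len(u.literal):
                return False
            for m in range(k):
                if s[a + m] == "N" or s[a + m] not in IUPAC_SETS[u.literal[m]]:
                    return False
        elif u.kind == "cleave":
            if k != 0:
                return False
        elif u.kind in ("spacer", "linker"):
            if not (u.min_len <= k <= u.max_len):
                return False
        elif u.kind == "stem_half":
            spec = pattern.stem_specs[u.stem_id]
            if not (spec.min_len <= k <= spec.max_len):
                return False
            placed[u.index] = (a, b)
        pos = b
    if pos != end:
        return False
    for sid, (ia, ib) in pattern.stem_pairs.items():
        spec = pattern.stem_specs[sid]
        (a0, a1), (b0, b1) = placed[ia], placed[ib]
        if a1 - a0 != b1 - b0:
            return False
        if _pairing_mismatches(s, a0, b0, a1 - a0, spec.wobble_allowed) > spec.mismatch_budget:
            return False
    return True
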
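"""Ground-truthed synthetic data generators.

Everything the other modules consume can be generated here with a recorded
seed and an explicit truth record: planted permuted-motif instances inside
i.i.d. background sequence, compensatory-mutation alignments with an attached
consensus pair table, and noisy one-phase decay time courses.  All generators
are pure functions of (parameters, seed).

Defaults mirror the biology they emulate: inter-block linkers of three
nucleotides (the typical linker seen between blocks in permuted hammerhead
ribozymes), G.U wobble emitted at 10% of stem positions where the stem allows
wobble, and uniform sampling over IUPAC sets at degenerate literal positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptor import IUPAC_SETS, MotifDescriptor, PermutationLayout
from .kinetics import TimeSeries
from .scanner import compile_pattern, reverse_complement

__all__ = [
    "PlantTruth",
    "MutationPolicy",
    "sample_instance",
    "plant_in_background",
    "simulate_alignment",
    "simulate_decay",
]

_BASES = "ACGU"
_WC_PAIRS = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
_WOBBLE_PAIRS = [("G", "U"), ("U", "G")]


@dataclass(frozen=True)
class MutationPolicy:
    """How to perturb stem positions of a sampled instance.

    kind "none": emit exactly as sampled.
    kind "compensatory": each stem position is jointly resampled to a
    different *paired* type with probability ``rate`` (structure preserved).
    kind "breaking": ``count`` stem positions get one partner mutated so the
    pair no longer satisfies the stem's pairing policy.
    """

    kind: str = "none"
    rate: float = 0.0
    count: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "compensatory", "breaking"):
            raise ValueError(f"unknown mutation policy {self.kind!r}")


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for one emitted instance (coordinates on the forward strand)."""

    sequence_id: str
    span: tuple[int, int]
    strand: str
    type_name: str
    element_spans: tuple[tuple[str, int, int], ...]
    cleavage: int | None
    mutations: tuple[dict, ...] = ()


def _sample_pair(rng, wobble_allowed: bool, wobble_prob: float) -> tuple[str, str]:
    if wobble_allowed and rng.random() < wobble_prob:
        return _WOBBLE_PAIRS[rng.integers(len(_WOBBLE_PAIRS))]
    return _WC_PAIRS[rng.integers(len(_WC_PAIRS))]


def sample_instance(
    descriptor: MotifDescriptor,
    layout: PermutationLayout,
    seed: int | np.random.Generator = 0,
    policy: MutationPolicy | None = None,
    wobble_prob: float = 0.1,
    linker_length: int | None = 3,
) -> tuple[str, PlantTruth]:
    """Emit one motif instance for ``layout`` plus its truth record.

    Degenerate literal positions are sampled uniformly over their IUPAC sets;
    stems are emitted as jointly sampled antiparallel pairs.  ``linker_length``
    fixes the inter-block linker (clipped into the descriptor's range); pass
    ``None`` to sample linker lengths uniformly from the range.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    policy = policy or MutationPolicy()
    pattern = compile_pattern(descriptor, layout)
    units = pattern.units

    # choose lengths
    lengths: dict[int, int] = {}
    for u in units:
        if u.kind == "stem_half":
            first_i, second_i = pattern.stem_pairs[u.stem_id]
            if u.index == first_i:
                k = int(rng.integers(u.min_len, u.max_len + 1))
                lengths[first_i] = k
                lengths[second_i] = k
        elif u.kind == "linker":
            if linker_length is None:
                lengths[u.index] = int(rng.integers(u.min_len, u.max_len + 1))
            else:
                lengths[u.index] = min(max(linker_length, u.min_len), u.max_len)
        elif u.kind == "spacer":
            lengths[u.index] = int(rng.integers(u.min_len, u.max_len + 1))
        elif u.kind == "literal":
            lengths[u.index] = len(u.literal)
        else:  # cleave
            lengths[u.index] = 0

    # stem pair assignments
    stem_pairs_seq: dict[str, list[tuple[str, str]]] = {}
    for sid, (ia, _ib) in pattern.stem_pairs.items():
        spec = pattern.stem_specs[sid]
        stem_pairs_seq[sid] = [
            _sample_pair(rng, spec.wobble_allowed, wobble_prob)
            for _ in range(lengths[ia])
        ]

    mutations: list[dict] = []
    if policy.kind == "compensatory":
        for sid, pairs in stem_pairs_seq.items():
            for m, (x, y) in enumerate(pairs):
                if rng.random() < policy.rate:
                    spec = pattern.stem_specs[sid]
                    pool = list(_WC_PAIRS) + (
                        list(_WOBBLE_PAIRS) if spec.wobble_allowed else []
                    )
                    pool = [p for p in pool if p != (x, y)]
                    new = pool[rng.integers(len(pool))]
                    pairs[m] = new
                    mutations.append(
                        {"kind": "compensatory", "stem": sid, "pos": m,
                         "before": x + y, "after": new[0] + new[1]}
                    )
    elif policy.kind == "breaking":
        sites = [
            (sid, m)
            for sid, pairs in stem_pairs_seq.items()
            for m in range(len(pairs))
        ]
        if policy.count > len(sites):
            raise ValueError("more breaking mutations than stem positions")
        chosen = rng.choice(len(sites), size=policy.count, replace=False)
        for ci in sorted(int(c) for c in chosen):
            sid, m = sites[ci]
            spec = pattern.stem_specs[sid]
            x, y = stem_pairs_seq[sid][m]
            allowed = {p for p in _WC_PAIRS} | (
                set(_WOBBLE_PAIRS) if spec.wobble_allowed else set()
            )
            candidates = [
                b for b in _BASES if (x, b) not in allowed
            ]
            new_y = candidates[rng.integers(len(candidates))]
            stem_pairs_seq[sid][m] = (x, new_y)
            mutations.append(
                {"kind": "breaking", "stem": sid, "pos": m,
                 "before": x + y, "after": x + new_y}
            )

    # emit sequence
    chunks: list[str] = []
    spans: list[tuple[str, int, int]] = []
    pos = 0
    cleavage = None
    for u in units:
        k = lengths[u.index]
        if u.kind == "literal":
            chunk = "".join(
                sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))]
                for c in u.literal
            )
        elif u.kind in ("spacer", "linker"):
            chunk = "".join(_BASES[rng.integers(4)] for _ in range(k))
        elif u.kind == "cleave":
            chunk = ""
            cleavage = pos
        else:  # stem_half
            first_i, _second_i = pattern.stem_pairs[u.stem_id]
            pairs = stem_pairs_seq[u.stem_id]
            if u.index == first_i:
                chunk = "".join(p[0] for p in pairs)
            else:
                chunk = "".join(p[1] for p in reversed(pairs))
        chunks.append(chunk)
        spans.append((u.name, pos, pos + len(chunk)))
        pos += len(chunk)
    seq = "".join(chunks)
    truth = PlantTruth(
        sequence_id="",
        span=(0, len(seq)),
        strand="+",
        type_name=layout.type_name,
        element_spans=tuple(spans),
        cleavage=cleavage,
        mutations=tuple(mutations),
    )
    return seq, truth


def _random_background(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=length, p=p)])


def _shift_truth(
    truth: PlantTruth, seq_id: str, offset: int, strand: str, inst_len: int
) -> PlantTruth:
    if strand == "+":
        spans = tuple(
            (n, offset + s, offset + e) for n, s, e in truth.element_spans
        )
        cleav = None if truth.cleavage is None else offset + truth.cleavage
    else:
        spans = tuple(
            sorted(
                ((n, offset + inst_len - e, offset + inst_len - s)
                 for n, s, e in truth.element_spans),
                key=lambda t: (t[1], t[2]),
            )
        )
        cleav = (
            None if truth.cleavage is None else offset + inst_len - truth.cleavage
        )
    return PlantTruth(
        sequence_id=seq_id,
        span=(offset, offset + inst_len),
        strand=strand,
        type_name=truth.type_name,
        element_spans=spans,
        cleavage=cleav,
        mutations=truth.mutations,
    )


def plant_in_background(
    instances: list[tuple[str, PlantTruth]],
    n_decoys: int,
    background_gc: float = 0.5,
    seed: int = 0,
    host_length: int = 200,
    random_strand: bool = True,
) -> tuple[list[tuple[str, str]], list[PlantTruth]]:
    """Embed instances in i.i.d. background hosts plus pure-decoy records.

    Returns ``(records, truths)`` where records are (id, sequence) pairs:
    one host per instance (ids ``plant_NNNN``) followed by ``n_decoys``
    backgrounds (ids ``decoy_NNNN``).  Truths carry forward-strand
    coordinates of every planted element.
    """
    if not 0 < background_gc < 1:
        raise ValueError("background GC fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truths: list[PlantTruth] = []
    for idx, (inst, truth) in enumerate(instances):
        L = len(inst)
        if L > host_length:
            raise ValueError(
                f"instance of length {L} does not fit host of length {host_length}"
            )
        host = _random_background(rng, host_length, background_gc)
        offset = int(rng.integers(0, host_length - L + 1))
        strand = "+" if not random_strand or rng.random() < 0.5 else "-"
        planted = inst if strand == "+" else reverse_complement(inst)
        seq = host[:offset] + planted + host[offset + L:]
        seq_id = f"plant_{idx:04d}"
        records.append((seq_id, seq))
        truths.append(_shift_truth(truth, seq_id, offset, strand, L))
    for idx in range(n_decoys):
        records.append(
            (f"decoy_{idx:04d}", _random_background(rng, host_length, background_gc))
        )
    return records, truths


def simulate_alignment(
    descriptor: MotifDescriptor,
    layout: PermutationLayout,
    n: int,
    compensatory_rate: float = 0.3,
    seed: int = 0,
    wobble_prob: float = 0.1,
    linker_length: int = 3,
):
    """Gapless alignment of instances sharing one geometry, with pair table.

    Element lengths are sampled once, then each of the ``n`` sequences
    resamples degenerate literal positions, unconserved spacers/linkers, and
    stem pair types (each stem position jointly mutated with probability
    ``compensatory_rate`` relative to a reference assignment — the
    compensatory signal the covariation screen must detect).  The attached
    consensus pair table maps stem positions to column pairs, with pseudoknot
    tiers assigned so each tier is internally non-crossing.
    """
    from .covariation import StructuredAlignment

    if n < 2:
        raise ValueError("an alignment needs n >= 2 sequences")
    rng = np.random.default_rng(seed)
    pattern = compile_pattern(descriptor, layout)
    units = pattern.units

    lengths: dict[int, int] = {}
    for u in units:
        if u.kind == "stem_half":
            fi, si = pattern.stem_pairs[u.stem_id]
            if u.index == fi:
                k = int(rng.integers(u.min_len, u.max_len + 1))
                lengths[fi] = k
                lengths[si] = k
        elif u.kind == "linker":
            lengths[u.index] = min(max(linker_length, u.min_len), u.max_len)
        elif u.kind == "spacer":
            lengths[u.index] = int(rng.integers(u.min_len, u.max_len + 1))
        elif u.kind == "literal":
            lengths[u.index] = len(u.literal)
        else:
            lengths[u.index] = 0

    ref_pairs: dict[str, list[tuple[str, str]]] = {
        sid: [
            _sample_pair(rng, pattern.stem_specs[sid].wobble_allowed, wobble_prob)
            for _ in range(lengths[ia])
        ]
        for sid, (ia, _ib) in pattern.stem_pairs.items()
    }

    rows: list[str] = []
    for _ in range(n):
        pairs_here = {
            sid: list(pairs) for sid, pairs in ref_pairs.items()
        }
        for sid, pairs in pairs_here.items():
            spec = pattern.stem_specs[sid]
            pool = list(_WC_PAIRS) + (
                list(_WOBBLE_PAIRS) if spec.wobble_allowed else []
            )
            for m, cur in enumerate(pairs):
                if rng.random() < compensatory_rate:
                    alt = [p for p in pool if p != cur]
                    pairs[m] = alt[rng.integers(len(alt))]
        chunks = []
        for u in units:
            k = lengths[u.index]
            if u.kind == "literal":
                chunks.append(
                    "".join(
                        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))]
                        for c in u.literal
                    )
                )
            elif u.kind in ("spacer", "linker"):
                chunks.append("".join(_BASES[rng.integers(4)] for _ in range(k)))
            elif u.kind == "cleave":
                chunks.append("")
            else:
                fi, _si = pattern.stem_pairs[u.stem_id]
                ps = pairs_here[u.stem_id]
                chunks.append(
                    "".join(p[0] for p in ps)
                    if u.index == fi
                    else "".join(p[1] for p in reversed(ps))
                )
        rows.append("".join(chunks))

    # column pairs per stem + tier assignment (greedy, non-crossing per tier)
    starts: dict[int, int] = {}
    pos = 0
    for u in units:
        starts[u.index] = pos
        pos += lengths[u.index]
    stem_cols: dict[str, list[tuple[int, int]]] = {}
    extents: dict[str, tuple[int, int]] = {}
    for sid, (ia, ib) in pattern.stem_pairs.items():
        k = lengths[ia]
        a0, b0 = starts[ia], starts[ib]
        stem_cols[sid] = [(a0 + m, b0 + k - 1 - m) for m in range(k)]
        extents[sid] = (a0, b0 + k - 1)

    tiers: dict[str, int] = {}
    for sid in sorted(extents, key=lambda s: extents[s]):
        i, j = extents[sid]
        t = 0
        while any(
            tiers.get(o) == t
            and (min(i, extents[o][0]) < max(i, extents[o][0])
                 < min(j, extents[o][1]) < max(j, extents[o][1]))
            for o in tiers
        ):
            t += 1
        tiers[sid] = t
    pair_table = tuple(
        sorted(
            (i, j, tiers[sid])
            for sid, cols in stem_cols.items()
            for i, j in cols
        )
    )
    ids = tuple(f"seq_{i:03d}" for i in range(n))
    return StructuredAlignment(ids=ids, rows=tuple(rows), pairs=pair_table)


def simulate_decay(
    k: float,
    y0: float = 1.0,
    plateau: float = 0.0,
    t=None,
    sigma: float = 0.0,
    seed: int = 0,
    n_points: int = 30,
    span_half_lives: float = 3.5,
    construct: str = "",
    replicate: str = "",
) -> TimeSeries:
    """Noisy one-phase decay curve f(t) = (y0-plateau)exp(-kt)+plateau.

    With ``t=None`` the grid is ``n_points`` evenly spaced samples spanning
    ``span_half_lives`` half-lives of ``k`` (slow rates need long windows to
    be identifiable).  Gaussian noise of SD ``sigma`` is added and fractions
    are clipped back into [0, 1].
    """
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    if sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    if t is None:
        t = np.linspace(0.0, span_half_lives * np.log(2) / k, n_points)
    t = np.asarray(t, dtype=float)
    f = (y0 - plateau) * np.exp(-k * t) + plateau
    if sigma > 0:
        f = f + rng.normal(0.0, sigma, size=f.shape)
    n_clipped = int(np.sum((f < 0) | (f > 1)))
    if n_clipped:
        import logging

        logging.getLogger(__name__).debug(
            "clipped %d noisy fractions into [0,1]", n_clipped
        )
    f = np.clip(f, 0.0, 1.0)
    return TimeSeries(
        t=tuple(t), f=tuple(f), construct=construct, replicate=replicate
    )
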
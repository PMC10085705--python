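"""Covariation screening of candidate motif alignments.

Manual curation of candidate structured RNAs asks whether the proposed base
pairs are supported by compensatory mutations — paired columns that change
together while staying complementary — and rejects implausible candidates
(stems realizing almost no C-G pairs; long insertions that cannot fold away
into a hairpin).  This module makes those screens computable:

* per-pair statistics: pair-type tallies, compensatory row-pair count,
  mutual information (MI) with average-product correction (APC), and a
  column-permutation null p-value;
* a C-G scarcity filter and an insertion/hairpin plausibility filter;
* an overall verdict ("promising" / "not promising" / "insufficient data").

MI + APC with a permutation null is an explicit stand-in for the G-test
statistic of dedicated covariation software; the thresholds that formalize
"compelling covariation" are configuration, not inferred constants.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .descriptor import WATSON_CRICK, WOBBLE

__all__ = [
    "StructuredAlignment",
    "PairStats",
    "CovariationConfig",
    "CandidateReport",
    "parse_wuss",
    "pairs_to_wuss",
    "pair_statistics",
    "mutual_information",
    "apc_corrected_mi",
    "cg_scarcity_filter",
    "insertion_hairpin_filter",
    "evaluate_candidate",
]

logger = logging.getLogger(__name__)

_GAPS = set("-.~_")
_BASES = set("ACGU")

_OPEN = {"<": ">", "(": ")", "[": "]", "{": "}"}


def parse_wuss(ss: str) -> tuple[tuple[int, int, int], ...]:
    """Pair table (i, j, tier) from a WUSS consensus structure string.

    All bracket types (``<>``, ``()``, ``[]``, ``{}``) form the nested tier 0;
    uppercase/lowercase letter pairs (Aa, Bb, ...) form one extra tier per
    letter, encoding pseudoknots.  Unknown characters are treated as unpaired
    with a warning.
    """
    stacks: dict[str, list[int]] = {c: [] for c in _OPEN}
    letter_stacks: dict[str, list[int]] = {}
    pairs: list[tuple[int, int, int]] = []
    warned: set[str] = set()
    for i, c in enumerate(ss):
        if c in _OPEN:
            stacks[c].append(i)
        elif c in _OPEN.values():
            opener = {v: k for k, v in _OPEN.items()}[c]
            if not stacks[opener]:
                raise ValueError(f"unbalanced {c!r} at column {i}")
            pairs.append((stacks[opener].pop(), i, 0))
        elif c.isalpha() and c.isupper():
            letter_stacks.setdefault(c, []).append(i)
        elif c.isalpha() and c.islower():
            up = c.upper()
            if not letter_stacks.get(up):
                raise ValueError(f"unbalanced pseudoknot letter {c!r} at column {i}")
            tier = ord(up) - ord("A") + 1
            pairs.append((letter_stacks[up].pop(), i, tier))
        elif c in ".,:-_~":
            pass
        else:
            if c not in warned:
                warned.add(c)
                logger.warning("unknown WUSS character %r treated as unpaired", c)
    for c, st in stacks.items():
        if st:
            raise ValueError(f"unbalanced {c!r} in consensus structure")
    for c, st in letter_stacks.items():
        if st:
            raise ValueError(f"unbalanced pseudoknot letter {c!r}")
    return tuple(sorted(pairs))


def pairs_to_wuss(pairs, length: int) -> str:
    """Render a pair table back to WUSS (tier 0 as ``<>``, tiers 1+ as letters)."""
    out = ["."] * length
    for i, j, tier in pairs:
        if tier == 0:
            out[i], out[j] = "<", ">"
        else:
            letter = chr(ord("A") + tier - 1)
            out[i], out[j] = letter, letter.lower()
    return "".join(out)


@dataclass(frozen=True)
class StructuredAlignment:
    """Aligned rows plus a consensus pair table with pseudoknot tiers."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    pairs: tuple[tuple[int, int, int], ...]
    reference: str | None = None

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        L = lengths.pop() if lengths else 0
        cols: set[int] = set()
        for i, j, _tier in self.pairs:
            if not (0 <= i < j < L):
                raise ValueError(f"pair ({i},{j}) out of range")
            if i in cols or j in cols:
                raise ValueError(f"column reused across pairs: ({i},{j})")
            cols.update((i, j))
        for tier, group in itertools.groupby(
            sorted(self.pairs, key=lambda p: p[2]), key=lambda p: p[2]
        ):
            g = [(i, j) for i, j, _ in group]
            for (i, j), (i2, j2) in itertools.combinations(sorted(g), 2):
                if i < i2 < j < j2:
                    raise ValueError(
                        f"tier {tier} crosses internally: ({i},{j}) vs ({i2},{j2})"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)


def _usable_rows(aln: StructuredAlignment, i: int, j: int) -> list[int]:
    """Rows with concrete bases at both columns (gaps excluded pairwise)."""
    out = []
    for r, row in enumerate(aln.rows):
        x, y = row[i].upper().replace("T", "U"), row[j].upper().replace("T", "U")
        if x in _BASES and y in _BASES:
            out.append(r)
    return out


def _pair_chars(aln: StructuredAlignment, r: int, i: int, j: int) -> tuple[str, str]:
    row = aln.rows[r]
    return (row[i].upper().replace("T", "U"), row[j].upper().replace("T", "U"))


def mutual_information(aln: StructuredAlignment, i: int, j: int) -> float:
    """MI in bits between columns i and j over rows ungapped at both."""
    rows = _usable_rows(aln, i, j)
    if not rows:
        return 0.0
    joint: dict[tuple[str, str], int] = {}
    for r in rows:
        xy = _pair_chars(aln, r, i, j)
        joint[xy] = joint.get(xy, 0) + 1
    n = len(rows)
    px: dict[str, float] = {}
    py: dict[str, float] = {}
    for (x, y), c in joint.items():
        px[x] = px.get(x, 0) + c / n
        py[y] = py.get(y, 0) + c / n
    mi = 0.0
    for (x, y), c in joint.items():
        p = c / n
        mi += p * math.log2(p / (px[x] * py[y]))
    return max(mi, 0.0)


@lru_cache(maxsize=8)
def _full_mi_matrix(aln: StructuredAlignment) -> dict[tuple[int, int], float]:
    """MI for every column pair of the alignment (cached per alignment)."""
    L = aln.n_cols
    return {
        (i, j): mutual_information(aln, i, j)
        for i in range(L)
        for j in range(i + 1, L)
    }


def apc_corrected_mi(
    aln: StructuredAlignment, pairs: list[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """MI minus the average-product correction for the requested column pairs.

    APC(i,j) = mean(MI of i with every other column) x mean(MI of j with
    every other column) / mean(MI over all column pairs), computed on the
    full column-pair MI matrix.  The correction removes shared background
    signal (conservation, phylogeny, row-count effects) so genuinely
    covarying pairs rank above coincidentally similar ones.
    """
    mat = _full_mi_matrix(aln)
    if not mat:
        return {pq: 0.0 for pq in pairs}
    L = aln.n_cols
    overall = float(np.mean(list(mat.values())))
    col_mean = {
        c: float(np.mean([mat[tuple(sorted((c, x)))] for x in range(L) if x != c]))
        for c in range(L)
    }
    out = {}
    for i, j in pairs:
        mi = mat[(i, j)] if (i, j) in mat else mutual_information(aln, i, j)
        apc = col_mean[i] * col_mean[j] / overall if overall > 0 else 0.0
        out[(i, j)] = mi - apc
    return out


@dataclass(frozen=True)
class PairStats:
    pair: tuple[int, int]
    n_usable: int
    n_canonical: int
    n_wobble: int
    n_non_canonical: int
    n_gapped: int
    compensatory: int
    mi: float
    mi_apc: float
    p_perm: float | None
    defined: bool = True


def _is_paired(x: str, y: str, include_wobble: bool = True) -> bool:
    return (x, y) in WATSON_CRICK or (include_wobble and (x, y) in WOBBLE)


def pair_statistics(
    aln: StructuredAlignment,
    pair: tuple[int, int],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> PairStats:
    """Covariation statistics for one consensus pair.

    MI is computed over rows ungapped at both columns; the APC term is taken
    from the full column-pair MI matrix (see ``apc_corrected_mi``).  The
    compensatory count is the number
    of row pairs that differ at both columns while both rows remain paired
    (Watson-Crick or wobble).  ``p_perm`` comes from independent within-column
    shuffles preserving column composition.
    """
    i, j = pair
    if not any((i, j) == (p, q) for p, q, _ in aln.pairs):
        raise ValueError(f"({i},{j}) is not a consensus pair")
    rows = _usable_rows(aln, i, j)
    n_gapped = aln.n_rows - len(rows)
    if not rows:
        return PairStats(pair, 0, 0, 0, 0, n_gapped, 0, 0.0, 0.0, None, defined=False)

    n_can = n_wob = n_non = 0
    for r in rows:
        x, y = _pair_chars(aln, r, i, j)
        if (x, y) in WATSON_CRICK:
            n_can += 1
        elif (x, y) in WOBBLE:
            n_wob += 1
        else:
            n_non += 1

    comp = 0
    for r, t in itertools.combinations(rows, 2):
        xr, yr = _pair_chars(aln, r, i, j)
        xt, yt = _pair_chars(aln, t, i, j)
        if xr != xt and yr != yt and _is_paired(xr, yr) and _is_paired(xt, yt):
            comp += 1

    mi = mutual_information(aln, i, j)

    mi_apc = apc_corrected_mi(aln, [(i, j)])[(i, j)]

    # permutation null: shuffle column j within usable rows
    rng = np.random.default_rng(seed)
    ys = [_pair_chars(aln, r, i, j)[1] for r in rows]
    xs = [_pair_chars(aln, r, i, j)[0] for r in rows]
    count = 0
    ys_arr = np.array(ys)
    for _ in range(n_shuffles):
        perm = rng.permutation(len(ys_arr))
        mi_perm = _mi_from_lists(xs, ys_arr[perm])
        if mi_perm >= mi - 1e-12:
            count += 1
    p_perm = (1 + count) / (1 + n_shuffles)

    return PairStats(
        pair=(i, j),
        n_usable=len(rows),
        n_canonical=n_can,
        n_wobble=n_wob,
        n_non_canonical=n_non,
        n_gapped=n_gapped,
        compensatory=comp,
        mi=mi,
        mi_apc=mi_apc,
        p_perm=p_perm,
    )


def _mi_from_lists(xs, ys) -> float:
    n = len(xs)
    joint: dict[tuple[str, str], int] = {}
    px: dict[str, int] = {}
    py: dict[str, int] = {}
    for x, y in zip(xs, ys):
        joint[(x, y)] = joint.get((x, y), 0) + 1
        px[x] = px.get(x, 0) + 1
        py[y] = py.get(y, 0) + 1
    mi = 0.0
    for (x, y), c in joint.items():
        mi += (c / n) * math.log2(c * n / (px[x] * py[y]))
    return max(mi, 0.0)


def cg_scarcity_filter(
    aln: StructuredAlignment,
    stems: dict[str, list[tuple[int, int]]],
    threshold: float = 0.15,
) -> dict[str, bool]:
    """Flag sequences whose realized stem pairs are almost never C-G.

    For each sequence, over all required-stem pair columns where both
    positions hold concrete bases, the fraction that are C-G or G-C is
    computed; the sequence is flagged when that fraction is strictly below
    ``threshold``.
    """
    all_pairs = [pq for pairs in stems.values() for pq in pairs]
    flags: dict[str, bool] = {}
    for r, sid in enumerate(aln.ids):
        realized = 0
        cg = 0
        for i, j in all_pairs:
            x, y = _pair_chars(aln, r, i, j)
            if x in _BASES and y in _BASES:
                realized += 1
                if (x, y) in (("C", "G"), ("G", "C")):
                    cg += 1
        frac = cg / realized if realized else 0.0
        flags[sid] = frac < threshold
    return flags


def insertion_hairpin_filter(
    insertion: str,
    max_unstructured: int = 12,
    min_stem: int = 3,
    min_loop: int = 3,
    wobble: bool = True,
) -> bool:
    """True (flagged) when a long insertion cannot fold into a hairpin.

    Insertions of length <= ``max_unstructured`` are never flagged.  Longer
    insertions are cleared when an exhaustive small-window search finds a
    self-complementary hairpin with stem >= ``min_stem`` bp and loop >=
    ``min_loop`` nt anywhere inside the insertion.
    """
    s = insertion.upper().replace("T", "U")
    L = len(s)
    if L <= max_unstructured:
        return False
    for k in range(min_stem, L // 2 + 1):
        for a in range(0, L - (2 * k + min_loop) + 1):
            for b in range(a + k + min_loop, L - k + 1):
                ok = True
                for m in range(k):
                    x, y = s[a + m], s[b + k - 1 - m]
                    if not _is_paired(x, y, include_wobble=wobble):
                        ok = False
                        break
                if ok:
                    return False
    return True


@dataclass(frozen=True)
class CovariationConfig:
    seed: int = 0
    n_shuffles: int = 1000
    min_supported_pairs: int = 3  # K: pairs needing compensatory support
    p_threshold: float = 0.05
    cg_threshold: float = 0.15
    insertion_max_unstructured: int = 12


@dataclass(frozen=True)
class CandidateReport:
    verdict: str  # "promising" | "not promising" | "insufficient data"
    pair_stats: tuple[PairStats, ...]
    cg_flags: dict[str, bool] = field(default_factory=dict)
    invariant_stems: tuple[str, ...] = ()
    config: dict = field(default_factory=dict)


def evaluate_candidate(
    aln: StructuredAlignment,
    config: CovariationConfig | None = None,
    stem_map: dict[str, list[tuple[int, int]]] | None = None,
) -> CandidateReport:
    """Screen one candidate alignment and return a verdict with evidence.

    Verdict is "promising" iff at least K consensus pairs show a compensatory
    count >= 1 with permutation p < threshold, and no stem group is entirely
    invariant.  Alignments with fewer than two sequences are "insufficient
    data" (a single example cannot exhibit covariation).  Stem groups default
    to the pseudoknot tiers of the pair table.
    """
    config = config or CovariationConfig()
    echo = {
        "seed": config.seed,
        "n_shuffles": config.n_shuffles,
        "min_supported_pairs": config.min_supported_pairs,
        "p_threshold": config.p_threshold,
        "cg_threshold": config.cg_threshold,
        "insertion_max_unstructured": config.insertion_max_unstructured,
    }
    if aln.n_rows < 2:
        return CandidateReport(verdict="insufficient data", pair_stats=(), config=echo)

    if stem_map is None:
        stem_map = {}
        for i, j, tier in aln.pairs:
            stem_map.setdefault(f"tier{tier}", []).append((i, j))

    stats = tuple(
        pair_statistics(aln, (i, j), n_shuffles=config.n_shuffles,
                        seed=config.seed + 7919 * idx)
        for idx, (i, j, _t) in enumerate(aln.pairs)
    )
    by_pair = {st.pair: st for st in stats}

    invariant_stems = []
    for name, pairs in stem_map.items():
        def _invariant(pq):
            i, j = pq
            rows = _usable_rows(aln, i, j)
            return (
                len({_pair_chars(aln, r, i, j) for r in rows}) <= 1
            )
        if pairs and all(_invariant(pq) for pq in pairs):
            invariant_stems.append(name)

    supported = sum(
        1
        for st in stats
        if st.defined and st.compensatory >= 1 and st.p_perm is not None
        and st.p_perm < config.p_threshold
    )
    promising = (
        supported >= config.min_supported_pairs and not invariant_stems
    )
    cg_flags = cg_scarcity_filter(aln, stem_map, threshold=config.cg_threshold)
    return CandidateReport(
        verdict="promising" if promising else "not promising",
        pair_stats=stats,
        cg_flags=cg_flags,
        invariant_stems=tuple(sorted(invariant_stems)),
        config=echo,
    )
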
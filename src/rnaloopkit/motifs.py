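"""Decomposition of nested secondary structures into stems and loops.

A *stem* is a maximal run of stacked base pairs (i, j), (i+1, j-1), ...
Every stem's inner face closes a *loop*: a hairpin if no further helices
emanate from it, an internal loop (order 2, bulges included) if exactly one
does, and an n-way junction for n >= 3 outgoing helices.  The unenclosed
exterior region is tracked as its own motif but is never a junction.

For every loop of order >= 2 the module can emit the three design-target
instances used throughout the dataset: the isolated loop, the loop together
with its connecting stems (entire helices), and the full structure.  Where
excising a child helix's enclosed subtree leaves a discontinuity, a short
run of unpaired 'N' residues (default 3, the minimum hairpin length) is
spliced in so that every emitted dot-bracket remains well-formed and
foldable; reported lengths count only original residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .structio import SecondaryStructure, parse_dotbracket

__all__ = [
    "Stem",
    "LoopMotif",
    "InstanceTriple",
    "find_stems",
    "decompose_loops",
    "make_instances",
    "junction_features",
    "generate_random_structure",
    "brute_force_decompose",
]

_COMPLEMENTS = ["AU", "UA", "GC", "CG", "GU", "UG"]
# GC-rich draw favours stable helices, as in natural structured RNA.
_COMPLEMENT_WEIGHTS = [0.17, 0.17, 0.26, 0.26, 0.07, 0.07]

DEFAULT_BRANCHING_WEIGHTS = {0: 0.50, 1: 0.28, 2: 0.14, 3: 0.06, 4: 0.02}


@dataclass(frozen=True)
class Stem:
    """A maximal helix: stacked pairs ordered outermost to innermost."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("stem needs at least one pair")
        for (i, j), (k, l) in zip(self.pairs, self.pairs[1:]):
            if (k, l) != (i + 1, j - 1):
                raise ValueError(f"pairs ({i},{j}) and ({k},{l}) do not stack")

    @property
    def outer(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def inner(self) -> tuple[int, int]:
        return self.pairs[-1]

    @property
    def positions(self) -> set[int]:
        return {p for pair in self.pairs for p in pair}


@dataclass(frozen=True)
class LoopMotif:
    """A loop: closing pair, child helices, and unpaired strands.

    ``strands`` are inclusive (start, end) ranges in 5'->3' order; an empty
    strand is encoded as (p, p-1).  For closed loops ``order`` is
    1 + number of child helices; the exterior region has no closing pair
    and is classified ``exterior`` regardless of how many top-level stems
    it touches.
    """

    closing_pair: tuple[int, int] | None
    child_pairs: tuple[tuple[int, int], ...]
    strands: tuple[tuple[int, int], ...]
    order: int
    loop_class: str
    enclosing_stem: Stem | None = field(default=None, compare=False)
    child_stems: tuple[Stem, ...] = field(default=(), compare=False)

    @property
    def strand_lengths(self) -> tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.strands)

    @property
    def strand_positions(self) -> set[int]:
        return {p for start, end in self.strands for p in range(start, end + 1)}


@dataclass(frozen=True)
class InstanceTriple:
    """The three design-target encodings of one loop motif."""

    loop_seq: str
    loop_db: str
    loop_stems_seq: str
    loop_stems_db: str
    full_seq: str
    full_db: str
    len_loop: int
    len_loop_stems: int
    len_full: int


def _require_nested(ss: SecondaryStructure) -> None:
    if not ss.is_nested:
        raise ValueError(
            "structure contains crossing pairs; remove pseudoknots first"
        )


def find_stems(ss: SecondaryStructure) -> list[Stem]:
    """Partition the pairs of a nested structure into maximal helices."""
    _require_nested(ss)
    ordered = sorted(ss.pairs)
    stems: list[Stem] = []
    run: list[tuple[int, int]] = []
    pair_set = set(ordered)
    for pair in ordered:
        i, j = pair
        if (i - 1, j + 1) in pair_set:
            continue  # not a stem start; reached via its outer neighbour
        run = [pair]
        while (run[-1][0] + 1, run[-1][1] - 1) in pair_set:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        stems.append(Stem(tuple(run)))
    stems.sort(key=lambda s: s.outer)
    return stems


def _classify(order: int) -> str:
    if order == 1:
        return "hairpin"
    if order == 2:
        return "internal"
    return "junction"


def _walk_face(
    left: int, right: int, partner: Mapping[int, int], outer_stems: Mapping[tuple[int, int], Stem]
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...], tuple[Stem, ...]]:
    """Collect child helices and strands on the face spanning [left, right]."""
    children: list[tuple[int, int]] = []
    child_stems: list[Stem] = []
    strands: list[tuple[int, int]] = []
    pos = left
    strand_start = pos
    while pos <= right:
        if pos in partner:
            strands.append((strand_start, pos - 1))
            j = partner[pos]
            children.append((pos, j))
            child_stems.append(outer_stems[(pos, j)])
            pos = j + 1
            strand_start = pos
        else:
            pos += 1
    strands.append((strand_start, right))
    return tuple(children), tuple(strands), tuple(child_stems)


def decompose_loops(ss: SecondaryStructure) -> list[LoopMotif]:
    """Decompose a nested structure into loop motifs (exterior included).

    Every position of the structure belongs to exactly one of: a stem pair,
    a closed-loop strand, or an exterior strand.
    """
    stems = find_stems(ss)
    partner = ss.partner_map()
    outer_stems = {stem.outer: stem for stem in stems}
    loops: list[LoopMotif] = []
    for stem in stems:
        i, j = stem.inner
        children, strands, child_stems = _walk_face(i + 1, j - 1, partner, outer_stems)
        order = 1 + len(children)
        loops.append(
            LoopMotif(
                closing_pair=(i, j),
                child_pairs=children,
                strands=strands,
                order=order,
                loop_class=_classify(order),
                enclosing_stem=stem,
                child_stems=child_stems,
            )
        )
    if ss.length > 0 and (stems or len(ss.paired_positions) < ss.length):
        children, strands, child_stems = _walk_face(1, ss.length, partner, outer_stems)
        loops.append(
            LoopMotif(
                closing_pair=None,
                child_pairs=children,
                strands=strands,
                order=len(children),
                loop_class="exterior",
                enclosing_stem=None,
                child_stems=child_stems,
            )
        )
    return loops


def junction_features(loop: LoopMotif, any_order: bool = False) -> tuple[int, ...]:
    """Unpaired-residue counts of the loop's strands in 5'->3' order.

    By default only 3-way junctions are accepted (the feature vector used
    for riboswitch recognition); pass ``any_order=True`` to get the n
    counts of any closed loop.
    """
    if loop.loop_class == "exterior":
        raise ValueError("the exterior region has no junction feature vector")
    if not any_order and loop.order != 3:
        raise ValueError(f"expected a 3-way junction, got order {loop.order}")
    return loop.strand_lengths


# ---------------------------------------------------------------------------
# instance generation


def make_instances(
    loop: LoopMotif, ss: SecondaryStructure, cap_length: int = 3
) -> InstanceTriple:
    """Emit the three design-target instances for a loop of order >= 2."""
    if loop.closing_pair is None or loop.order < 2:
        raise ValueError("design targets are generated only for loops of order >= 2")
    if ss.sequence is None:
        raise ValueError("structure carries no sequence")
    if loop.enclosing_stem is None:
        raise ValueError("loop lacks stem context; use decompose_loops output")

    loop_positions = (
        set(loop.closing_pair)
        | {p for pair in loop.child_pairs for p in pair}
        | loop.strand_positions
    )
    loop_pairs = {loop.closing_pair, *loop.child_pairs}

    stems_positions = set(loop.enclosing_stem.positions) | loop.strand_positions
    stems_pairs = set(loop.enclosing_stem.pairs)
    for child in loop.child_stems:
        stems_positions |= child.positions
        stems_pairs |= set(child.pairs)

    loop_seq, loop_db = _splice(loop_positions, loop_pairs, ss, cap_length)
    stems_seq, stems_db = _splice(stems_positions, stems_pairs, ss, cap_length)
    full_db = _render(ss)
    return InstanceTriple(
        loop_seq=loop_seq,
        loop_db=loop_db,
        loop_stems_seq=stems_seq,
        loop_stems_db=stems_db,
        full_seq=ss.sequence,
        full_db=full_db,
        len_loop=len(loop_positions),
        len_loop_stems=len(stems_positions),
        len_full=ss.length,
    )


def _splice(
    positions: set[int],
    pairs: set[tuple[int, int]],
    ss: SecondaryStructure,
    cap_length: int,
) -> tuple[str, str]:
    """Concatenate the selected positions, capping internal discontinuities."""
    ordered = sorted(positions)
    seq_chars: list[str] = []
    db_chars: list[str] = []
    new_index: dict[int, int] = {}
    prev = None
    for p in ordered:
        if prev is not None and p > prev + 1:
            seq_chars.extend("N" * cap_length)
            db_chars.extend("." * cap_length)
        seq_chars.append(ss.sequence[p - 1])
        db_chars.append(".")
        new_index[p] = len(db_chars) - 1
        prev = p
    for i, j in pairs:
        db_chars[new_index[i]] = "("
        db_chars[new_index[j]] = ")"
    return "".join(seq_chars), "".join(db_chars)


def _render(ss: SecondaryStructure) -> str:
    chars = ["."] * ss.length
    for i, j in ss.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# synthetic fixtures


def generate_random_structure(
    length: int,
    branching_weights: Mapping[int, float] | None = None,
    min_hairpin: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SecondaryStructure:
    """Generate a random valid nested structure with a compatible sequence.

    ``branching_weights`` gives the relative probability of a loop region
    spawning k child helices (renormalized over the feasible k at each
    decision); the default mixture yields hairpins, internal loops and a
    tail of higher-order junctions.  Paired positions receive complementary
    nucleotides (Watson-Crick or wobble); unpaired positions are uniform
    over ACGU.  The same seed always yields the same structure.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if min_hairpin < 1:
        raise ValueError("min_hairpin must be >= 1")
    weights = dict(branching_weights or DEFAULT_BRANCHING_WEIGHTS)
    if rng is None:
        rng = np.random.default_rng(seed)
    min_subtree = min_hairpin + 2

    def choose_children(n: int, at_top: bool) -> int:
        k_max = n // min_subtree
        feasible = [k for k in range(k_max + 1) if weights.get(k, 0.0) > 0]
        if not feasible:
            raise ValueError(
                f"no feasible branching for region of length {n} "
                f"(min hairpin {min_hairpin}, weights {weights})"
            )
        w = np.array([weights[k] for k in feasible], dtype=float)
        return int(rng.choice(feasible, p=w / w.sum()))

    def region(n: int, at_top: bool = False) -> str:
        if n == 0:
            return ""
        k = choose_children(n, at_top)
        if k == 0:
            return "." * n
        slack = n - k * min_subtree
        # distribute slack over k subtree enlargements and k+1 spacers
        cuts = rng.multinomial(slack, np.full(2 * k + 1, 1.0 / (2 * k + 1)))
        parts: list[str] = ["." * int(cuts[0])]
        for t in range(k):
            parts.append(subtree(min_subtree + int(cuts[2 * t + 1])))
            parts.append("." * int(cuts[2 * t + 2]))
        return "".join(parts)

    def subtree(m: int) -> str:
        max_h = (m - min_hairpin) // 2
        h = int(rng.integers(1, min(max_h, 6) + 1))
        inner = region(m - 2 * h)
        return "(" * h + inner + ")" * h

    db = region(length, at_top=True)
    ss = parse_dotbracket(db)
    seq = [""] * length
    for i, j in ss.pairs:
        left, right = _COMPLEMENTS[
            rng.choice(len(_COMPLEMENTS), p=_COMPLEMENT_WEIGHTS)
        ]
        seq[i - 1] = left
        seq[j - 1] = right
    bases = "ACGU"
    for p in range(length):
        if not seq[p]:
            seq[p] = bases[rng.integers(0, 4)]
    return SecondaryStructure(length, ss.pairs, "".join(seq))


# ---------------------------------------------------------------------------
# independent oracle


def brute_force_decompose(ss: SecondaryStructure) -> list[LoopMotif]:
    """Direct-containment loop decomposition (quadratic; test oracle).

    For every pair, its loop consists of the positions strictly inside it
    that are not strictly inside any pair it directly contains.  A pair
    whose loop is empty except for a single directly stacked child is a
    helix continuation, not a loop.  Independent of :func:`decompose_loops`.
    """
    _require_nested(ss)
    pairs = sorted(ss.pairs)

    def directly_inside(a: int, b: int, i: int, j: int) -> bool:
        # (a,b) inside (i,j) with no intervening pair
        if not (i < a and b < j):
            return False
        for c, d in pairs:
            if (c, d) in ((i, j), (a, b)):
                continue
            if i < c < a and b < d < j:
                return False
        return True

    loops: list[LoopMotif] = []
    for i, j in pairs:
        children = [(a, b) for a, b in pairs if directly_inside(a, b, i, j)]
        children.sort()
        inside = set(range(i + 1, j))
        for a, b in children:
            inside -= set(range(a, b + 1))
        if len(children) == 1 and not inside:
            continue  # stacked pair: helix continuation
        strands = _ranges_between(i, j, children)
        order = 1 + len(children)
        loops.append(
            LoopMotif(
                closing_pair=(i, j),
                child_pairs=tuple(children),
                strands=strands,
                order=order,
                loop_class=_classify(order),
            )
        )
    top = [
        (a, b)
        for a, b in pairs
        if not any(c < a and b < d for c, d in pairs)
    ]
    if ss.length > 0 and (pairs or True):
        if top or len(ss.paired_positions) < ss.length:
            strands = _ranges_between(0, ss.length + 1, top)
            loops.append(
                LoopMotif(
                    closing_pair=None,
                    child_pairs=tuple(top),
                    strands=strands,
                    order=len(top),
                    loop_class="exterior",
                )
            )
    return loops


def _ranges_between(
    left: int, right: int, children: Sequence[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    """Unpaired ranges on the face between (exclusive) left and right."""
    strands: list[tuple[int, int]] = []
    pos = left + 1
    for a, b in children:
        strands.append((pos, a - 1))
        pos = b + 1
    strands.append((pos, right - 1))
    return tuple(strands)
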
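"""Multi-annotator base-pair unification.

Base-pair annotators frequently disagree on individual pairs, especially
near helix ends and around non-canonical interactions.  The unification
protocol here builds a single conflict-free consensus structure by admitting
pairs in decreasing order of annotator support: first pairs every annotator
reports, then pairs reported by all but one, and so on.  A candidate is
admitted only if neither of its residues is already claimed by an admitted
pair.  The resulting structure is labelled with an agreement category — the
minimum support among the pairs it retains — so that downstream users can
filter by annotation confidence (category equal to the number of annotators
means unanimous agreement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .structcore import SuitabilityCategory
from .structio import SecondaryStructure

__all__ = ["SupportedPair", "AgreementCategory", "tally_support", "unify"]

CANONICAL_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


@dataclass(frozen=True)
class SupportedPair:
    """A candidate base pair with the number of annotators reporting it."""

    pair: tuple[int, int]
    support: int

    def __post_init__(self) -> None:
        i, j = self.pair
        if not i < j:
            raise ValueError(f"pair ({i}, {j}) must satisfy i < j")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True)
class AgreementCategory:
    """Structure-level agreement label: an integer 1..A, or a filter value."""

    value: int | SuitabilityCategory

    def __str__(self) -> str:
        if isinstance(self.value, SuitabilityCategory):
            return self.value.value
        return str(self.value)


def tally_support(annotations: Sequence[Iterable[tuple[int, int]]]) -> list[SupportedPair]:
    """Count, for each distinct pair, how many annotations contain it."""
    counts: dict[tuple[int, int], int] = {}
    for annotation in annotations:
        for pair in set(annotation):
            counts[pair] = counts.get(pair, 0) + 1
    return [SupportedPair(pair, n) for pair, n in sorted(counts.items())]


def filter_canonical(
    supported: Iterable[SupportedPair], sequence: str
) -> list[SupportedPair]:
    """Keep only Watson-Crick and wobble pairs, judged from the sequence."""
    out = []
    for sp in supported:
        i, j = sp.pair
        if sequence[i - 1].upper() + sequence[j - 1].upper() in CANONICAL_PAIRS:
            out.append(sp)
    return out


def unify(
    supported: Sequence[SupportedPair],
    n_annotators: int,
    length: int | None = None,
    sequence: str | None = None,
    strict_nested: bool = False,
) -> tuple[SecondaryStructure, AgreementCategory]:
    """Build the consensus structure from support-annotated candidate pairs.

    Pairs are visited in order of descending support, ties broken by
    ascending (i, j); a pair is admitted iff neither residue is used by an
    already-admitted pair.  With ``strict_nested=True`` a candidate that
    crosses an admitted pair is also rejected; by default crossings are
    tolerated here and handled later by pseudoknot removal.

    Returns the consensus structure and its agreement category: the minimum
    support among admitted pairs, or ``empty`` if none were admitted.
    """
    for sp in supported:
        if sp.support > n_annotators:
            raise ValueError(
                f"pair {sp.pair} has support {sp.support} > {n_annotators} annotators"
            )
    if length is None:
        length = max((j for sp in supported for j in sp.pair), default=0)
    used: set[int] = set()
    admitted: list[SupportedPair] = []
    for sp in sorted(supported, key=lambda s: (-s.support, s.pair)):
        i, j = sp.pair
        if i in used or j in used:
            continue
        if strict_nested and any(
            k < i < l < j or i < k < j < l for (k, l), _ in ((a.pair, a) for a in admitted)
        ):
            continue
        admitted.append(sp)
        used.add(i)
        used.add(j)
    ss = SecondaryStructure(
        length, frozenset(sp.pair for sp in admitted), sequence
    )
    if not admitted:
        return ss, AgreementCategory(SuitabilityCategory.EMPTY)
    return ss, AgreementCategory(min(sp.support for sp in admitted))
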
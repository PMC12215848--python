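"""Structure-level transforms.

Pseudoknot elimination by maximum nested-subset selection, projection of an
alignment-level consensus structure onto an individual (gapped) sequence,
and suitability categorization of annotated 3D chains.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from .structio import AlignedFamily, SecondaryStructure

__all__ = [
    "ChainMeta",
    "SuitabilityCategory",
    "remove_pseudoknots",
    "project_onto_sequence",
    "categorize_chain",
    "rscape_cacofold",
]

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class ChainMeta:
    """Chain identifiers and author residue numbering of a 3D structure.

    ``residue_numbers`` holds one strictly increasing list per chain, in
    the same order as ``chain_ids``.
    """

    chain_ids: tuple[str, ...]
    residue_numbers: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if not self.chain_ids:
            raise ValueError("at least one chain required")
        if len(self.chain_ids) != len(self.residue_numbers):
            raise ValueError("chain_ids and residue_numbers differ in length")
        for chain, numbers in zip(self.chain_ids, self.residue_numbers):
            if not numbers:
                raise ValueError(f"chain {chain!r}: empty residue list")
            if any(b <= a for a, b in zip(numbers, numbers[1:])):
                raise ValueError(f"chain {chain!r}: residue numbers not increasing")


class SuitabilityCategory(str, Enum):
    """Filter outcome for a 3D chain prior to consensus annotation."""

    EMPTY = "empty"
    GAPPED = "gapped"
    MULTISTRAND = "multistrand"
    OK = "ok"


def categorize_chain(meta: ChainMeta, ss: SecondaryStructure) -> SuitabilityCategory:
    """Classify a chain as multistrand / gapped / empty / ok, in that precedence.

    Chains failing the first three checks are unsuitable as design targets:
    multiple strands cannot be encoded in one dot-bracket sequence, chain
    breaks leave residues with unknown structural context, and a structure
    with no base pairs carries no design signal.
    """
    if len(meta.chain_ids) > 1:
        return SuitabilityCategory.MULTISTRAND
    numbers = meta.residue_numbers[0]
    if any(b != a + 1 for a, b in zip(numbers, numbers[1:])):
        return SuitabilityCategory.GAPPED
    if not ss.pairs:
        return SuitabilityCategory.EMPTY
    return SuitabilityCategory.OK


# ---------------------------------------------------------------------------
# pseudoknot removal


def remove_pseudoknots(
    ss: SecondaryStructure,
    layer_priority: Sequence[int] | None = None,
) -> SecondaryStructure:
    """Return the maximum-cardinality nested subset of ``ss.pairs``.

    Crossing pairs (pseudoknots) are eliminated by dynamic programming over
    the candidate pair set (a Nussinov-style recursion restricted to the
    pairs actually present), so the result is the largest possible nested
    structure contained in the input.  Among equally large subsets, pairs
    whose recorded notation layer ranks earlier in ``layer_priority``
    (default: primary layer first, then ascending layer index) are
    preferred; remaining ties resolve to the lexicographically smallest
    pair set under ascending (i, j), deterministically.
    """
    if not ss.pairs:
        return ss
    n_layers = max(ss.layers.values(), default=0) + 1
    if layer_priority is None:
        layer_priority = list(range(n_layers))
    rank = {layer: r for r, layer in enumerate(layer_priority)}
    worst = len(rank)
    # Secondary DP weight: small bonus for preferred layers, decided after
    # cardinality.  Bonuses are scaled so no sum of them can trade against
    # one unit of cardinality.
    denom = len(ss.pairs) * (worst + 1) + 1

    def bonus(i: int, j: int) -> int:
        layer = ss.layers.get((i, j), 0)
        return worst + 1 - rank.get(layer, worst)

    # Only pair endpoints matter for nestedness; compress coordinates so the
    # DP is quadratic in the number of pairs, not the sequence length.
    points = sorted({p for pair in ss.pairs for p in pair})
    index = {p: a for a, p in enumerate(points)}
    m = len(points)
    # partners_at[a] = sorted compact indices c such that (points[a], points[c]) is a pair
    partners_at: list[list[int]] = [[] for _ in range(m)]
    for i, j in ss.pairs:
        partners_at[index[i]].append(index[j])
    for lst in partners_at:
        lst.sort()

    # score[a][b] = best (cardinality * denom + bonus sum) using pairs whose
    # endpoints both lie in points[a..b]; empty interval encoded as b < a.
    score = [[0] * m for _ in range(m + 1)]

    def get(a: int, b: int) -> int:
        return score[a][b] if a <= b else 0

    for a in range(m - 1, -1, -1):
        for b in range(a, m):
            s = get(a + 1, b)
            for c in partners_at[a]:
                if c > b:
                    break
                cand = denom + bonus(points[a], points[c]) + get(a + 1, c - 1) + get(c + 1, b)
                if cand > s:
                    s = cand
            score[a][b] = s

    chosen: list[tuple[int, int]] = []
    stack = [(0, m - 1)]
    while stack:
        a, b = stack.pop()
        while a <= b:
            target = get(a, b)
            # Prefer pairing the leftmost endpoint (smallest partner first)
            # over skipping it, so ties resolve toward lexicographically
            # smaller pair sets.
            paired = False
            for c in partners_at[a]:
                if c > b:
                    break
                if (
                    denom
                    + bonus(points[a], points[c])
                    + get(a + 1, c - 1)
                    + get(c + 1, b)
                    == target
                ):
                    chosen.append((points[a], points[c]))
                    stack.append((c + 1, b))
                    a, b = a + 1, c - 1
                    paired = True
                    break
            if not paired:
                a += 1

    kept = frozenset(chosen)
    return SecondaryStructure(
        ss.length,
        kept,
        ss.sequence,
        layers={p: ss.layers[p] for p in kept if p in ss.layers},
    )


# ---------------------------------------------------------------------------
# consensus projection


def project_onto_sequence(family: AlignedFamily, row_index: int) -> SecondaryStructure:
    """Project the family consensus structure onto one alignment row.

    Gap characters are removed from the row; a consensus pair survives iff
    both of its columns are non-gap in this row, and surviving pairs are
    re-indexed to ungapped sequence coordinates.  Half-gapped pairs are
    dropped entirely rather than re-paired.
    """
    if not (0 <= row_index < len(family.rows)):
        raise IndexError(f"row index {row_index} out of range")
    _, gapped = family.rows[row_index]
    col_to_pos: dict[int, int] = {}
    seq_chars: list[str] = []
    for col, ch in enumerate(gapped, start=1):
        if ch in GAP_CHARS:
            continue
        seq_chars.append(ch.upper().replace("T", "U"))
        col_to_pos[col] = len(seq_chars)
    pairs: set[tuple[int, int]] = set()
    layers: dict[tuple[int, int], int] = {}
    layer_index = {"primary": 0}
    for (ci, cj), label in family.consensus_pairs.items():
        if ci in col_to_pos and cj in col_to_pos:
            pair = (col_to_pos[ci], col_to_pos[cj])
            pairs.add(pair)
            layers[pair] = layer_index.setdefault(label, len(layer_index))
    return SecondaryStructure(
        len(seq_chars), frozenset(pairs), "".join(seq_chars), layers=layers
    )


# ---------------------------------------------------------------------------
# optional R-scape / CaCoFold wrapper


def rscape_cacofold(stockholm_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run ``R-scape --rfam --cacofold`` on a STOCKHOLM file (optional).

    Returns the path of the CaCoFold-annotated STOCKHOLM output.  Requires
    the ``R-scape`` executable on PATH; raises ``RuntimeError`` otherwise.
    """
    exe = shutil.which("R-scape")
    if exe is None:
        raise RuntimeError("R-scape backend unavailable: executable not on PATH")
    stockholm_path = Path(stockholm_path)
    out = Path(out_dir) if out_dir is not None else Path(tempfile.mkdtemp())
    subprocess.run(
        [exe, "--rfam", "--cacofold", "--outdir", str(out), str(stockholm_path)],
        check=True,
        capture_output=True,
        text=True,
    )
    matches = sorted(out.glob("*.cacofold.sto")) or sorted(out.glob("*.sto"))
    if not matches:
        raise RuntimeError("R-scape produced no CaCoFold STOCKHOLM output")
    return matches[0]
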
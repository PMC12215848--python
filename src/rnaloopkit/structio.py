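"""Readers and writers for RNA secondary-structure formats.

Covers dot-bracket (multi-layer, with pseudoknot layers), BPSEQ, CT,
FASTA, STOCKHOLM alignments with WUSS consensus lines, and the loop-motif
dataset CSV dialect.  All coordinates are 1-based inclusive, matching the
BPSEQ/CT convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO

__all__ = [
    "SecondaryStructure",
    "AlignedFamily",
    "StructureFormatError",
    "parse_dotbracket",
    "write_dotbracket",
    "read_bpseq",
    "write_bpseq",
    "read_ct",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "read_dataset_csv",
    "write_dataset_csv",
    "DATASET_COLUMNS",
]

# Bracket layers usable in dot-bracket output, in greedy assignment order.
# Layer 0 is the primary (nested) layer; letters encode pseudoknot layers.
_OPEN = "([{<" + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))
_CLOSE = ")]}>" + "".join(chr(c) for c in range(ord("a"), ord("z") + 1))
_N_LAYERS = len(_OPEN)


class StructureFormatError(ValueError):
    """Raised for malformed structure files or notation strings."""


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA secondary structure: a length, base pairs, optional sequence.

    Parameters
    ----------
    length
        Number of residues.
    pairs
        Base pairs as 1-based ``(i, j)`` tuples with ``i < j``.  No residue
        may participate in more than one pair.
    sequence
        Optional nucleotide string over ``{A, C, G, U, N}`` of ``length``.
    layers
        Optional mapping pair -> layer index (0 = primary bracket layer,
        1+ = pseudoknot layers) recording which notation layer a pair came
        from.  Purely informational; not part of equality.
    """

    length: int
    pairs: frozenset[tuple[int, int]]
    sequence: str | None = None
    layers: dict[tuple[int, int], int] = field(
        default_factory=dict, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative length {self.length}")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i}, {j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"residue reused by pair ({i}, {j})")
            seen.add(i)
            seen.add(j)
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != structure length {self.length}"
            )

    @property
    def is_nested(self) -> bool:
        """True iff no two pairs cross (i < k < j < l)."""
        ordered = sorted(self.pairs)
        stack: list[int] = []
        events: list[tuple[int, int, int]] = []
        for i, j in ordered:
            events.append((i, 0, j))
            events.append((j, 1, i))
        for pos, kind, other in sorted(events):
            if kind == 0:
                stack.append(other)
            else:
                if not stack or stack[-1] != pos:
                    return False
                stack.pop()
        return True

    @property
    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out

    def partner_map(self) -> dict[int, int]:
        """Map every paired position to its partner."""
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m

    def with_pairs(self, pairs: Iterable[tuple[int, int]]) -> "SecondaryStructure":
        return SecondaryStructure(self.length, frozenset(pairs), self.sequence)


@dataclass
class AlignedFamily:
    """A multiple sequence alignment with a WUSS consensus structure.

    ``consensus_pairs`` maps a column pair ``(i, j)`` (1-based) to a layer
    label: ``"primary"`` for the bracket layers of WUSS, or the uppercase
    letter of a pseudoknot layer.
    """

    accession: str
    rows: list[tuple[str, str]]
    consensus_pairs: dict[tuple[int, int], str]
    n_columns: int

    def __post_init__(self) -> None:
        for name, seq in self.rows:
            if len(seq) != self.n_columns:
                raise ValueError(
                    f"row {name!r} has length {len(seq)}, expected {self.n_columns}"
                )
        used: set[int] = set()
        for i, j in self.consensus_pairs:
            if not (1 <= i < j <= self.n_columns):
                raise ValueError(f"consensus pair ({i}, {j}) outside alignment")
            if i in used or j in used:
                raise ValueError(f"column reused by consensus pair ({i}, {j})")
            used.add(i)
            used.add(j)


# ---------------------------------------------------------------------------
# dot-bracket


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a (possibly multi-layer) dot-bracket string.

    Layers ``()``, ``[]``, ``{}``, ``<>`` and ``Aa``..``Zz`` are matched
    independently, each with its own stack.  Raises
    :class:`StructureFormatError` on unbalanced brackets or illegal
    characters, naming the layer and 1-based position.
    """
    stacks: dict[int, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    layers: dict[tuple[int, int], int] = {}
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        open_layer = _OPEN.find(ch)
        if open_layer >= 0:
            stacks.setdefault(open_layer, []).append(pos)
            continue
        close_layer = _CLOSE.find(ch)
        if close_layer >= 0:
            stack = stacks.get(close_layer)
            if not stack:
                raise StructureFormatError(
                    f"unbalanced {_CLOSE[close_layer]!r} at position {pos}"
                )
            i = stack.pop()
            pairs.add((i, pos))
            layers[(i, pos)] = close_layer
            continue
        raise StructureFormatError(f"illegal character {ch!r} at position {pos}")
    for layer, stack in stacks.items():
        if stack:
            raise StructureFormatError(
                f"unbalanced {_OPEN[layer]!r} at position {stack[0]}"
            )
    return SecondaryStructure(len(text), frozenset(pairs), layers=layers)


def write_dotbracket(ss: SecondaryStructure) -> str:
    """Render a structure as dot-bracket notation.

    Nested pairs go to the primary ``()`` layer; crossing pairs are
    assigned to further layers greedily (first layer in which they do not
    cross any pair already placed there), so each layer is internally
    nested and the output re-parses to the same pair set.
    """
    layer_pairs: list[list[tuple[int, int]]] = []

    def crosses(p: tuple[int, int], placed: list[tuple[int, int]]) -> bool:
        i, j = p
        for k, l in placed:
            if k < i < l < j or i < k < j < l:
                return True
        return False

    for pair in sorted(ss.pairs):
        for placed in layer_pairs:
            if not crosses(pair, placed):
                placed.append(pair)
                break
        else:
            if len(layer_pairs) >= _N_LAYERS:
                raise StructureFormatError(
                    f"structure needs more than {_N_LAYERS} pseudoknot layers"
                )
            layer_pairs.append([pair])
    chars = ["."] * ss.length
    for layer, placed in enumerate(layer_pairs):
        for i, j in placed:
            chars[i - 1] = _OPEN[layer]
            chars[j - 1] = _CLOSE[layer]
    return "".join(chars)


# ---------------------------------------------------------------------------
# BPSEQ / CT


def _pairs_from_partner_rows(
    rows: list[tuple[int, str, int]], where: str
) -> SecondaryStructure:
    n = len(rows)
    indices = [r[0] for r in rows]
    if indices != list(range(1, n + 1)):
        for lineno, idx in enumerate(indices, start=1):
            if idx != lineno:
                raise StructureFormatError(
                    f"{where}: expected index {lineno}, got {idx} (line {lineno})"
                )
    partner = {r[0]: r[2] for r in rows}
    seq = "".join(r[1] for r in rows)
    pairs: set[tuple[int, int]] = set()
    for i, _, j in rows:
        if j == 0:
            continue
        if not (1 <= j <= n):
            raise StructureFormatError(f"{where}: partner {j} of {i} out of range")
        if partner.get(j) != i:
            raise StructureFormatError(
                f"{where}: non-reciprocal pair, line {i} names {j} "
                f"but line {j} names {partner.get(j)}"
            )
        if i < j:
            pairs.add((i, j))
    return SecondaryStructure(n, frozenset(pairs), seq)


def read_bpseq(lines: Iterable[str]) -> SecondaryStructure:
    """Read BPSEQ (``index base partner``, partner 0 = unpaired)."""
    rows: list[tuple[int, str, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise StructureFormatError(f"BPSEQ line {lineno}: expected 3 fields")
        try:
            idx, partner = int(parts[0]), int(parts[2])
        except ValueError as exc:
            raise StructureFormatError(f"BPSEQ line {lineno}: {exc}") from exc
        rows.append((idx, parts[1], partner))
    return _pairs_from_partner_rows(rows, "BPSEQ")


def write_bpseq(ss: SecondaryStructure) -> list[str]:
    """Write BPSEQ lines; sequence defaults to 'N' where unknown."""
    seq = ss.sequence or "N" * ss.length
    partner = ss.partner_map()
    return [f"{i} {seq[i - 1]} {partner.get(i, 0)}" for i in range(1, ss.length + 1)]


def read_ct(lines: Iterable[str]) -> SecondaryStructure:
    """Read a CT file (header with residue count, then 6-column rows)."""
    lines = [l for l in (raw.rstrip("\n") for raw in lines) if l.strip()]
    if not lines:
        raise StructureFormatError("CT: empty input")
    header = lines[0].split()
    try:
        count = int(header[0])
    except (IndexError, ValueError) as exc:
        raise StructureFormatError("CT: bad header") from exc
    body = lines[1:]
    if len(body) != count:
        raise StructureFormatError(
            f"CT: header says {count} rows, {len(body)} present"
        )
    rows: list[tuple[int, str, int]] = []
    for lineno, line in enumerate(body, start=2):
        parts = line.split()
        if len(parts) < 6:
            raise StructureFormatError(f"CT line {lineno}: expected 6 columns")
        rows.append((int(parts[0]), parts[1], int(parts[4])))
    return _pairs_from_partner_rows(rows, "CT")


def write_ct(ss: SecondaryStructure, title: str = "") -> list[str]:
    seq = ss.sequence or "N" * ss.length
    partner = ss.partner_map()
    out = [f"{ss.length} {title}".rstrip()]
    for i in range(1, ss.length + 1):
        nxt = i + 1 if i < ss.length else 0
        out.append(f"{i} {seq[i - 1]} {i - 1} {nxt} {partner.get(i, 0)} {i}")
    return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(handle: io.TextIOBase | str) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) tuples."""
    from Bio import SeqIO

    if isinstance(handle, str):
        with open(handle) as fh:
            return [(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
    return [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], handle: io.TextIOBase) -> None:
    for name, seq in records:
        handle.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# STOCKHOLM / WUSS

_WUSS_UNPAIRED = set(".:,_-~")
_WUSS_OPEN = {"<": 0, "(": 1, "[": 2, "{": 3}
_WUSS_CLOSE = {">": 0, ")": 1, "]": 2, "}": 3}


def parse_wuss(ss_cons: str) -> dict[tuple[int, int], str]:
    """Map a WUSS consensus line to {(i, j): layer label}.

    The four bracket types are primary-compatible (mutually nested) layers,
    labelled ``"primary"``; uppercase/lowercase letter pairs ``Aa``..``Zz``
    are pseudoknot layers labelled by their uppercase letter.  Unpaired
    symbols are ``. : , _ - ~``.
    """
    bracket_stacks: dict[int, list[int]] = {k: [] for k in range(4)}
    letter_stacks: dict[str, list[int]] = {}
    pairs: dict[tuple[int, int], str] = {}
    used: set[int] = set()

    def claim(col: int) -> None:
        if col in used:
            raise StructureFormatError(f"WUSS: column {col} used by two pairs")
        used.add(col)

    for col, ch in enumerate(ss_cons, start=1):
        if ch in _WUSS_UNPAIRED:
            continue
        if ch in _WUSS_OPEN:
            bracket_stacks[_WUSS_OPEN[ch]].append(col)
        elif ch in _WUSS_CLOSE:
            stack = bracket_stacks[_WUSS_CLOSE[ch]]
            if not stack:
                raise StructureFormatError(f"WUSS: unbalanced {ch!r} at column {col}")
            i = stack.pop()
            claim(i)
            claim(col)
            pairs[(i, col)] = "primary"
        elif ch.isupper():
            letter_stacks.setdefault(ch, []).append(col)
        elif ch.islower():
            stack = letter_stacks.get(ch.upper())
            if not stack:
                raise StructureFormatError(
                    f"WUSS: {ch!r} at column {col} has no open {ch.upper()!r}"
                )
            i = stack.pop()
            claim(i)
            claim(col)
            pairs[(i, col)] = ch.upper()
        else:
            raise StructureFormatError(f"WUSS: illegal symbol {ch!r} at column {col}")
    for layer, stack in bracket_stacks.items():
        if stack:
            raise StructureFormatError(
                f"WUSS: unbalanced bracket layer {layer} at column {stack[0]}"
            )
    for letter, stack in letter_stacks.items():
        if stack:
            raise StructureFormatError(
                f"WUSS: letter {letter!r} opened at column {stack[0]} never closed"
            )
    return pairs


def read_stockholm(source: io.TextIOBase | str) -> AlignedFamily:
    """Read a STOCKHOLM family (wrapped blocks supported) with SS_cons."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_stockholm(fh)
    text = source.read()
    alignment = AlignIO.read(io.StringIO(text), "stockholm")
    ss_cons = alignment.column_annotations.get("secondary_structure")
    if ss_cons is None:
        raise StructureFormatError("STOCKHOLM: missing #=GC SS_cons line")
    accession = "unknown"
    for line in text.splitlines():
        if line.startswith("#=GF AC"):
            accession = line.split(None, 2)[2].strip()
            break
    rows = [(rec.id, str(rec.seq)) for rec in alignment]
    return AlignedFamily(
        accession=accession,
        rows=rows,
        consensus_pairs=parse_wuss(ss_cons),
        n_columns=alignment.get_alignment_length(),
    )


# ---------------------------------------------------------------------------
# dataset CSV

DATASET_COLUMNS = [
    "source_db",
    "source_id",
    "family_or_pdb",
    "loop_type",
    "loop_order",
    "category",
    "loop_seq",
    "loop_db",
    "loop_stems_seq",
    "loop_stems_db",
    "full_seq",
    "full_db",
    "len_loop",
    "len_loop_stems",
    "len_full",
]

_INT_COLUMNS = ["loop_order", "len_loop", "len_loop_stems", "len_full"]


def write_dataset_csv(records: pd.DataFrame | list[dict], path_or_handle) -> None:
    """Write loop-motif records with the fixed column schema."""
    df = pd.DataFrame(records, columns=DATASET_COLUMNS)
    df.to_csv(path_or_handle, index=False)


def read_dataset_csv(path_or_handle) -> pd.DataFrame:
    """Read a loop-motif dataset CSV, validating schema and row consistency."""
    df = pd.read_csv(path_or_handle, dtype={"category": str})
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise StructureFormatError(f"dataset CSV: missing columns {missing}")
    df = df[DATASET_COLUMNS]
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(int)
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        for seq_col, db_col in [
            ("loop_seq", "loop_db"),
            ("loop_stems_seq", "loop_stems_db"),
            ("full_seq", "full_db"),
        ]:
            seq = getattr(row, seq_col)
            db = getattr(row, db_col)
            if len(seq) != len(db):
                raise StructureFormatError(
                    f"dataset CSV row {row_number}: {seq_col}/{db_col} length mismatch"
                )
    return df
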
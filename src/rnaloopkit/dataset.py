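"""End-to-end dataset construction and summary statistics.

Two routes produce loop-motif records:

* the alignment route — family seed alignments with a consensus structure
  are projected onto each member sequence, pseudoknots are removed, and
  every loop of order >= 2 becomes a record;
* the 3D-annotation route — per-chain base-pair lists from multiple
  annotators are unified into a consensus structure (after filtering out
  chains that are empty, gapped, or multi-strand), pseudoknots are removed,
  and records carry the numeric agreement category.

Records are plain dicts matching the dataset CSV schema; summaries group
them by loop type with count, percentage and length statistics of the
loop-with-stems instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import consensus as cons
from .motifs import decompose_loops, make_instances
from .structcore import (
    ChainMeta,
    SuitabilityCategory,
    categorize_chain,
    project_onto_sequence,
    remove_pseudoknots,
)
from .structio import AlignedFamily, SecondaryStructure, read_stockholm

logger = logging.getLogger(__name__)

__all__ = [
    "BuildOptions",
    "build_rfam_records",
    "build_family_records",
    "build_rnasolo_records",
    "records_from_structure",
    "summarize",
    "loop_type_label",
]


def loop_type_label(order: int) -> str:
    return "internal" if order == 2 else f"{order}way"


@dataclass
class BuildOptions:
    """Knobs of the record-building pipelines.

    cap_length
        Unpaired 'N' residues spliced into excision discontinuities.
    use_cacofold
        Augment family consensus pairs via the external R-scape/CaCoFold
        wrapper before projection (requires the R-scape executable).
    refold_constrained
        Refold each projected sequence with RNAfold, passing the projected
        pairs as hard constraints (requires RNAfold).
    remove_pk_before_projection
        Also drop pseudoknot layers at the consensus level, before
        per-sequence projection (the per-sequence removal always runs).
    strict_consensus
        Reject crossing pairs already at consensus insertion instead of
        leaving them to pseudoknot removal.
    """

    cap_length: int = 3
    use_cacofold: bool = False
    refold_constrained: bool = False
    remove_pk_before_projection: bool = False
    strict_consensus: bool = False
    counters: dict[str, int] = field(default_factory=dict)

    def count(self, key: str) -> None:
        self.counters[key] = self.counters.get(key, 0) + 1


def records_from_structure(
    ss: SecondaryStructure,
    source_db: str,
    source_id: str,
    family_or_pdb: str,
    category: str = "n/a",
    cap_length: int = 3,
) -> list[dict]:
    """Emit one record per loop of order >= 2 in a nested structure."""
    records = []
    for loop in decompose_loops(ss):
        if loop.closing_pair is None or loop.order < 2:
            continue
        inst = make_instances(loop, ss, cap_length=cap_length)
        records.append(
            {
                "source_db": source_db,
                "source_id": source_id,
                "family_or_pdb": family_or_pdb,
                "loop_type": loop_type_label(loop.order),
                "loop_order": loop.order,
                "category": category,
                "loop_seq": inst.loop_seq,
                "loop_db": inst.loop_db,
                "loop_stems_seq": inst.loop_stems_seq,
                "loop_stems_db": inst.loop_stems_db,
                "full_seq": inst.full_seq,
                "full_db": inst.full_db,
                "len_loop": inst.len_loop,
                "len_loop_stems": inst.len_loop_stems,
                "len_full": inst.len_full,
            }
        )
    return records


def build_family_records(
    family: AlignedFamily, options: BuildOptions | None = None
) -> list[dict]:
    """Project a family consensus onto every row and extract loop records."""
    options = options or BuildOptions()
    if options.use_cacofold:
        raise NotImplementedError(
            "CaCoFold augmentation operates on files; use build_rfam_records"
        )
    records: list[dict] = []
    consensus_family = family
    if options.remove_pk_before_projection:
        primary = {
            pair: label
            for pair, label in family.consensus_pairs.items()
            if label == "primary"
        }
        consensus_family = AlignedFamily(
            family.accession, family.rows, primary, family.n_columns
        )
    for row_index, (row_id, _) in enumerate(consensus_family.rows):
        ss = project_onto_sequence(consensus_family, row_index)
        ss = remove_pseudoknots(ss)
        if options.refold_constrained and ss.length > 0:
            from .evalbench import constrained_fold
            from .motifs import _render

            ss = constrained_fold(ss.sequence, _render(ss))
        if not ss.pairs:
            options.count("rows_without_pairs")
            continue
        row_records = records_from_structure(
            ss,
            source_db="rfam",
            source_id=row_id,
            family_or_pdb=family.accession,
            category="n/a",
            cap_length=options.cap_length,
        )
        if row_records:
            options.count("rows_with_records")
        records.extend(row_records)
    return records


def build_rfam_records(
    stockholm_files: Iterable[str], options: BuildOptions | None = None
) -> list[dict]:
    """Run the alignment route over a set of STOCKHOLM seed files.

    Malformed files are skipped with a logged warning (counted in
    ``options.counters['families_failed']``).
    """
    options = options or BuildOptions()
    records: list[dict] = []
    for path in stockholm_files:
        try:
            if options.use_cacofold:
                from .structcore import rscape_cacofold

                path = str(rscape_cacofold(path))
            family = read_stockholm(path)
        except Exception as exc:  # malformed input: skip, keep building
            logger.warning("skipping family file %s: %s", path, exc)
            options.count("families_failed")
            continue
        records.extend(build_family_records(family, options))
        options.count("families_processed")
    return records


def build_rnasolo_records(
    chains: Sequence[
        tuple[str, str, str, ChainMeta, Sequence[Iterable[tuple[int, int]]]]
    ],
    options: BuildOptions | None = None,
) -> list[dict]:
    """Run the 3D-annotation route.

    Each chain is a tuple ``(chain_id, pdb_id, sequence, meta, annotations)``
    where ``annotations`` holds one base-pair set per annotator (all
    annotators must be present, possibly with empty sets).  Chains filtered
    as empty / gapped / multistrand yield no records and are tallied in
    ``options.counters``.
    """
    options = options or BuildOptions()
    records: list[dict] = []
    for chain_id, pdb_id, sequence, meta, annotations in chains:
        if not annotations:
            raise ValueError(f"chain {chain_id}: zero annotators")
        supported = cons.tally_support([set(a) for a in annotations])
        ss, category = cons.unify(
            supported,
            n_annotators=len(annotations),
            length=len(sequence),
            sequence=sequence,
            strict_nested=options.strict_consensus,
        )
        suitability = categorize_chain(meta, ss)
        if suitability is not SuitabilityCategory.OK:
            options.count(f"filtered_{suitability.value}")
            continue
        ss = remove_pseudoknots(ss)
        records.extend(
            records_from_structure(
                ss,
                source_db="rnasolo",
                source_id=chain_id,
                family_or_pdb=pdb_id,
                category=str(category),
                cap_length=options.cap_length,
            )
        )
        options.count("chains_processed")
    return records


def summarize(records: Sequence[Mapping] | pd.DataFrame) -> pd.DataFrame:
    """Per-loop-type summary: count, percent, length min/max/mean/std.

    Length statistics are over the loop-with-stems instance length.  The
    standard deviation is the sample standard deviation (ddof=1), reported
    as 0 for single-record groups; percentages are rounded to 2 decimals.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    total = len(df)
    rows = []
    order_of = df.groupby("loop_type")["loop_order"].first()
    for loop_type, group in df.groupby("loop_type"):
        lengths = group["len_loop_stems"].to_numpy(dtype=float)
        std = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0
        rows.append(
            {
                "loop_type": loop_type,
                "count": len(group),
                "percent": round(100.0 * len(group) / total, 2),
                "min": int(lengths.min()),
                "max": int(lengths.max()),
                "mean": float(lengths.mean()),
                "std": std,
            }
        )
    out = pd.DataFrame(rows)
    out["_order"] = out["loop_type"].map(order_of)
    out = out.sort_values("_order").drop(columns="_order").reset_index(drop=True)
    return out
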
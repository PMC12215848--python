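"""Metrics and statistics for inverse-folding benchmarks.

Native implementations of the two structure-level metrics (base-pair
F1-score and ordered-tree edit distance on the full structure tree) plus
failure-aware aggregation, pairwise one-sided Wilcoxon signed-rank
matrices, the energy-based candidate-selection rule used with Boltzmann
samplers, and thin subprocess wrappers around the ViennaRNA command-line
programs (RNAfold, RNAdistance, RNApdist) for refolding and cross-checks.

Failure convention: a design tool that produced no output for a case is
scored with the worst possible value of each metric — positive infinity
for distances and 0 for F1 — so a failing tool always loses that case in a
pairwise comparison.
"""

from __future__ import annotations

import math
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structio import SecondaryStructure, parse_dotbracket

__all__ = [
    "FAILED",
    "EvalCase",
    "CandidateEnergetics",
    "ComparisonMatrix",
    "bp_f1",
    "tree_edit_distance",
    "normalize_distance",
    "aggregate_with_failures",
    "wilcoxon_pvalue",
    "wilcoxon_matrix",
    "target_probability",
    "select_candidate",
    "fold_wrapper",
    "pdist_wrapper",
    "rnadistance_wrapper",
    "METRIC_DIRECTIONS",
    "RT_37C",
]

FAILED = "FAILED"

#: Gas constant times temperature at 37 degrees C, kcal/mol.
RT_37C = 0.61633

#: Metric name -> "lower" (better) or "higher" (better).
METRIC_DIRECTIONS = {
    "rnadistance": "lower",
    "normalized_rnadistance": "lower",
    "rnapdist": "lower",
    "f1": "higher",
    "precision": "higher",
    "recall": "higher",
}


@dataclass
class EvalCase:
    """One (tool, target) evaluation with metric values or failure flags."""

    target: SecondaryStructure
    designed_sequence: str | None
    refolded: SecondaryStructure | None
    metrics: dict[str, float] = field(default_factory=dict)
    runtime_seconds: float | None = None

    @property
    def failed(self) -> bool:
        return self.designed_sequence is None or self.refolded is None


@dataclass(frozen=True)
class CandidateEnergetics:
    """Thermodynamic summary of one sampled candidate sequence."""

    sequence: str
    mfe: float
    ensemble_energy: float
    target_energies: tuple[float, ...]
    rt: float = RT_37C

    @property
    def target_probabilities(self) -> tuple[float, ...]:
        return tuple(
            target_probability(e, self.ensemble_energy, self.rt)
            for e in self.target_energies
        )

    @property
    def psum(self) -> float:
        return sum(self.target_probabilities)


@dataclass
class ComparisonMatrix:
    """Pairwise one-sided Wilcoxon p-values: p[a, b] tests 'a better than b'."""

    tools: list[str]
    p: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.tools, columns=self.tools)


# ---------------------------------------------------------------------------
# base-pair F1


def bp_f1(
    target: SecondaryStructure, predicted: SecondaryStructure
) -> tuple[float, float, float]:
    """Precision, recall and F1 of predicted base pairs vs the target.

    A true positive is an exactly identical (i, j) pair.  When both
    structures are empty the score is 1 by convention; an empty prediction
    against a non-empty target scores 0.
    """
    if target.length != predicted.length:
        raise ValueError(
            f"length mismatch: target {target.length}, predicted {predicted.length}"
        )
    tp = len(target.pairs & predicted.pairs)
    if not target.pairs and not predicted.pairs:
        return 1.0, 1.0, 1.0
    precision = tp / len(predicted.pairs) if predicted.pairs else 0.0
    recall = tp / len(target.pairs) if target.pairs else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


# ---------------------------------------------------------------------------
# tree edit distance (Zhang-Shasha)

#: Default edit costs, calibrated so the distance reproduces the reference
#: RNAdistance program's full-structure output: inserting or deleting an
#: unpaired base costs 1, a base pair costs 2, and relabelling between the
#: two costs 1.
DEFAULT_COSTS = {
    ("U", None): 1.0,
    ("P", None): 2.0,
    ("R", None): 0.0,
    ("U", "P"): 1.0,
    ("U", "R"): math.inf,
    ("P", "R"): math.inf,
}


def _cost(a: str | None, b: str | None, table: Mapping) -> float:
    if a == b:
        return 0.0
    key = (a, b) if (a, b) in table else (b, a)
    return float(table[key])


class _Tree:
    """Postorder-indexed ordered tree of a secondary structure."""

    __slots__ = ("labels", "lml", "keyroots")

    def __init__(self, ss: SecondaryStructure):
        if not ss.is_nested:
            raise ValueError("tree encoding requires a nested structure")
        children_of: dict[int, list[int]] = {}
        labels: list[str] = []
        lml: list[int] = []

        partner = ss.partner_map()

        def build(left: int, right: int, label: str) -> int:
            kids: list[int] = []
            pos = left
            while pos <= right:
                if pos in partner:
                    j = partner[pos]
                    kids.append(build(pos + 1, j - 1, "P"))
                    pos = j + 1
                else:
                    labels.append("U")
                    lml.append(len(labels) - 1)
                    kids.append(len(labels) - 1)
                    pos += 1
            labels.append(label)
            me = len(labels) - 1
            children_of[me] = kids
            lml.append(lml[kids[0]] if kids else me)
            return me

        # Iterative rebuild to avoid recursion limits on long structures.
        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * ss.length + 100))
        try:
            build(1, ss.length, "R")
        finally:
            sys.setrecursionlimit(old)

        self.labels = labels
        self.lml = lml
        n = len(labels)
        seen: set[int] = set()
        keyroots = []
        for i in range(n - 1, -1, -1):
            if lml[i] not in seen:
                keyroots.append(i)
                seen.add(lml[i])
        self.keyroots = sorted(keyroots)


def tree_edit_distance(
    a: SecondaryStructure,
    b: SecondaryStructure,
    costs: Mapping | None = None,
) -> float:
    """Ordered-labeled-tree edit distance between two nested structures.

    Each structure is encoded as a tree with a virtual root ``R``, one
    internal ``P`` node per base pair and one ``U`` leaf per unpaired base,
    and compared with the Zhang-Shasha algorithm under :data:`DEFAULT_COSTS`
    (overridable).  Symmetric, zero on identical structures, and equal to
    the reference RNAdistance program's full-structure distance under the
    default cost table.
    """
    table = DEFAULT_COSTS if costs is None else costs
    t1, t2 = _Tree(a), _Tree(b)
    n, m = len(t1.labels), len(t2.labels)
    td = np.zeros((n, m))

    l1, l2 = t1.lml, t2.lml
    lab1, lab2 = t1.labels, t2.labels

    def treedist(i: int, j: int) -> None:
        li, lj = l1[i], l2[j]
        ni, nj = i - li + 2, j - lj + 2
        fd = np.zeros((ni, nj))
        for x in range(1, ni):
            fd[x][0] = fd[x - 1][0] + _cost(lab1[li + x - 1], None, table)
        for y in range(1, nj):
            fd[0][y] = fd[0][y - 1] + _cost(lab2[lj + y - 1], None, table)
        for x in range(1, ni):
            node1 = li + x - 1
            for y in range(1, nj):
                node2 = lj + y - 1
                if l1[node1] == li and l2[node2] == lj:
                    fd[x][y] = min(
                        fd[x - 1][y] + _cost(lab1[node1], None, table),
                        fd[x][y - 1] + _cost(lab2[node2], None, table),
                        fd[x - 1][y - 1] + _cost(lab1[node1], lab2[node2], table),
                    )
                    td[node1][node2] = fd[x][y]
                else:
                    p = l1[node1] - li
                    q = l2[node2] - lj
                    fd[x][y] = min(
                        fd[x - 1][y] + _cost(lab1[node1], None, table),
                        fd[x][y - 1] + _cost(lab2[node2], None, table),
                        fd[p][q] + td[node1][node2],
                    )

    for i in t1.keyroots:
        for j in t2.keyroots:
            treedist(i, j)
    return float(td[n - 1][m - 1])


def normalize_distance(d: float, target_length: int) -> float:
    """Divide a tree-edit distance by the target sequence length."""
    if target_length <= 0:
        raise ValueError("target length must be positive")
    return d / target_length


# ---------------------------------------------------------------------------
# failure-aware aggregation


def aggregate_with_failures(
    values_by_tool: Mapping[str, Sequence], metric: str
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Substitute worst-case values for failures; report the common subset.

    ``FAILED`` (or None/NaN) entries become ``+inf`` for lower-is-better
    metrics and ``0`` for higher-is-better ones.  Also returns a boolean
    mask of the cases solved by every tool, on which headline tables are
    computed.
    """
    if metric not in METRIC_DIRECTIONS:
        raise ValueError(f"unknown metric {metric!r}")
    worst = math.inf if METRIC_DIRECTIONS[metric] == "lower" else 0.0
    out: dict[str, np.ndarray] = {}
    solved: list[np.ndarray] = []
    n = None
    for tool, values in values_by_tool.items():
        ok = np.array(
            [
                v is not None
                and not (isinstance(v, str) and v == FAILED)
                and not (isinstance(v, float) and math.isnan(v))
                for v in values
            ]
        )
        if n is None:
            n = len(ok)
        elif len(ok) != n:
            raise ValueError("tools report different numbers of cases")
        arr = np.full(len(ok), worst, dtype=float)
        arr[ok] = [float(v) for v, good in zip(values, ok) if good]
        out[tool] = arr
        solved.append(ok)
    common = np.logical_and.reduce(solved) if solved else np.array([], dtype=bool)
    return out, common


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_pvalue(ranks2: np.ndarray, w2: float, alternative: str) -> float:
    """Exact sign-flip distribution of the signed-rank statistic.

    ``ranks2`` are doubled midranks (integers even with ties); ``w2`` the
    doubled observed positive-rank sum.  Enumerates the 2^n equally likely
    sign assignments by dynamic programming over achievable sums.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w2))
    if alternative == "less":
        return float(counts[: w2 + 1].sum())
    return float(counts[w2:].sum())


def wilcoxon_pvalue(
    a: Sequence[float], b: Sequence[float], alternative: str = "less"
) -> float:
    """One-sided Wilcoxon signed-rank p-value for paired samples.

    ``alternative="less"`` tests that the differences a - b tend to be
    negative.  Zero differences are dropped (Wilcoxon's convention); if all
    differences are zero the p-value is 1.  Infinite values are handled by
    rank: any finite value beats +inf, and two infinities of the same sign
    tie (difference zero).  Exact distribution for n <= 25 (ties included,
    via midranks), normal approximation with continuity and tie correction
    beyond.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    finite = np.concatenate([x[np.isfinite(x)], y[np.isfinite(y)]])
    cap = float(finite.max()) + 1.0 if finite.size else 1.0
    x = np.where(np.isposinf(x), cap, x)
    y = np.where(np.isposinf(y), cap, y)
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= 25:
        return _exact_signed_rank_pvalue(
            np.round(2 * ranks).astype(int), 2 * w_plus, alternative
        )
    mean = n * (n + 1) / 4
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_term / 48
    if alternative == "less":
        z = (w_plus - mean + 0.5) / math.sqrt(var)
        return float(stats.norm.cdf(z))
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


def wilcoxon_matrix(
    tool_vectors: Mapping[str, Sequence[float]], direction: str
) -> ComparisonMatrix:
    """All-pairs one-sided Wilcoxon matrix: p[a, b] tests 'a better than b'.

    ``direction`` is ``"lower"`` or ``"higher"`` (which way is better for
    the metric).  The diagonal is 1.
    """
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    tools = list(tool_vectors)
    lengths = {len(v) for v in tool_vectors.values()}
    if len(lengths) > 1:
        raise ValueError("all tools must report the same number of cases")
    if lengths and next(iter(lengths)) < 5:
        raise ValueError("need at least 5 paired cases")
    alternative = "less" if direction == "lower" else "greater"
    k = len(tools)
    p = np.ones((k, k))
    for ai, a in enumerate(tools):
        for bi, b in enumerate(tools):
            if ai == bi:
                continue
            p[ai, bi] = wilcoxon_pvalue(
                tool_vectors[a], tool_vectors[b], alternative
            )
    return ComparisonMatrix(tools, p)


# ---------------------------------------------------------------------------
# candidate selection (Boltzmann-sampler post-processing)


def target_probability(e_target: float, ensemble_energy: float, rt: float = RT_37C) -> float:
    """Boltzmann probability of a target structure: exp((EE - E_t) / RT)."""
    if rt <= 0:
        raise ValueError("RT must be positive")
    return math.exp((ensemble_energy - e_target) / rt)


def select_candidate(candidates: Sequence[CandidateEnergetics]) -> CandidateEnergetics:
    """Pick the candidate with the highest Psum, ties broken by lowest MFE.

    Remaining ties resolve to the earliest candidate in input order.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.psum > best.psum or (cand.psum == best.psum and cand.mfe < best.mfe):
            best = cand
    return best


# ---------------------------------------------------------------------------
# ViennaRNA subprocess wrappers


def _require(exe: str) -> str:
    path = shutil.which(exe)
    if path is None:
        raise RuntimeError(f"backend unavailable: {exe} not found on PATH")
    return path


def fold_wrapper(sequence: str) -> tuple[SecondaryStructure, float, float]:
    """Fold a sequence with RNAfold -p: (MFE structure, MFE, ensemble energy)."""
    if not sequence:
        raise ValueError("empty sequence")
    exe = _require("RNAfold")
    with tempfile.TemporaryDirectory() as tmp:
        proc = subprocess.run(
            [exe, "--noPS", "-p"],
            input=sequence + "\n",
            capture_output=True,
            text=True,
            cwd=tmp,
        )
    if proc.returncode != 0:
        raise RuntimeError(f"RNAfold failed: {proc.stderr.strip()}")
    lines = proc.stdout.splitlines()
    m_mfe = re.match(r"([.()]+)\s+\(\s*(-?\d+\.?\d*)\)", lines[1])
    if not m_mfe:
        raise RuntimeError(f"unparseable RNAfold output: {lines[1]!r}")
    structure = parse_dotbracket(m_mfe.group(1))
    mfe = float(m_mfe.group(2))
    m_ee = re.search(r"\[\s*(-?\d+\.?\d*)\]", lines[2])
    if not m_ee:
        raise RuntimeError(f"unparseable RNAfold ensemble line: {lines[2]!r}")
    return (
        SecondaryStructure(structure.length, structure.pairs, sequence.upper()),
        mfe,
        float(m_ee.group(1)),
    )


def constrained_fold(sequence: str, constraint_db: str) -> SecondaryStructure:
    """Refold a sequence with RNAfold, enforcing pairs as hard constraints."""
    if len(sequence) != len(constraint_db):
        raise ValueError("sequence/constraint length mismatch")
    exe = _require("RNAfold")
    with tempfile.TemporaryDirectory() as tmp:
        proc = subprocess.run(
            [exe, "--noPS", "-C", "--enforceConstraint"],
            input=f"{sequence}\n{constraint_db}\n",
            capture_output=True,
            text=True,
            cwd=tmp,
        )
    if proc.returncode != 0:
        raise RuntimeError(f"RNAfold -C failed: {proc.stderr.strip()}")
    m = re.match(r"([.()]+)", proc.stdout.splitlines()[1])
    if not m:
        raise RuntimeError("unparseable RNAfold -C output")
    ss = parse_dotbracket(m.group(1))
    return SecondaryStructure(ss.length, ss.pairs, sequence.upper())


def pdist_wrapper(seq_a: str, seq_b: str) -> float:
    """Ensemble (base-pair-probability profile) distance via RNApdist."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    exe = _require("RNApdist")
    with tempfile.TemporaryDirectory() as tmp:
        proc = subprocess.run(
            [exe],
            input=f"{seq_a}\n{seq_b}\n",
            capture_output=True,
            text=True,
            cwd=tmp,
        )
    if proc.returncode != 0:
        raise RuntimeError(f"RNApdist failed: {proc.stderr.strip()}")
    for token in proc.stdout.split():
        try:
            return float(token)
        except ValueError:
            continue
    raise RuntimeError(f"unparseable RNApdist output: {proc.stdout!r}")


def rnadistance_wrapper(db_a: str, db_b: str) -> float:
    """Full-structure tree edit distance via the RNAdistance binary."""
    exe = _require("RNAdistance")
    proc = subprocess.run(
        [exe],
        input=f"{db_a}\n{db_b}\n",
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise RuntimeError(f"RNAdistance failed: {proc.stderr.strip()}")
    m = re.search(r"f:\s*(-?\d+\.?\d*)", proc.stdout)
    if not m:
        raise RuntimeError(f"unparseable RNAdistance output: {proc.stdout!r}")
    return float(m.group(1))
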
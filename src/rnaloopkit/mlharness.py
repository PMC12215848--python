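"""Riboswitch-recognition demonstration harness.

Builds a junction-feature table (the unpaired-residue counts of the three
strands of every 3-way junction, labelled positive when the record belongs
to a chosen family) and evaluates standard classifiers under stratified
k-fold cross-validation with macro-averaged F1 — the appropriate summary
for a heavily imbalanced two-class problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureTable",
    "build_feature_table",
    "default_classifiers",
    "stratified_kfold_eval",
    "group_split",
]


@dataclass
class FeatureTable:
    """Strand-length feature rows with binary labels for one target family."""

    table: pd.DataFrame  # columns u1, u2, u3, label
    positive_family: str
    usable: bool = True

    @property
    def X(self) -> np.ndarray:
        return self.table[["u1", "u2", "u3"]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray | None:
        if "family" in self.table.columns:
            return self.table["family"].to_numpy()
        return None


def build_feature_table(
    records: Sequence[Mapping] | pd.DataFrame, positive_family: str
) -> FeatureTable:
    """Extract (u1, u2, u3, label) rows from all 3-way junction records.

    Strand lengths are recovered from the loop instance's dot-bracket: the
    three unpaired runs between the closing pair and the two child pairs.
    Records of any other loop order are skipped.  If the positive family is
    absent the table is flagged unusable (a one-class problem cannot be
    cross-validated).
    """
    df = pd.DataFrame(records)
    rows = []
    for rec in df.itertuples(index=False):
        if rec.loop_order != 3:
            continue
        strands = _strand_lengths_from_loop_db(rec.loop_db)
        rows.append(
            {
                "u1": strands[0],
                "u2": strands[1],
                "u3": strands[2],
                "label": int(rec.family_or_pdb == positive_family),
                "family": rec.family_or_pdb,
            }
        )
    table = pd.DataFrame(rows, columns=["u1", "u2", "u3", "label", "family"])
    usable = bool((table["label"] == 1).any()) and bool((table["label"] == 0).any())
    if not usable:
        warnings.warn(
            f"family {positive_family!r} yields a one-class table; unusable for CV",
            stacklevel=2,
        )
    return FeatureTable(table, positive_family, usable)


def _strand_lengths_from_loop_db(loop_db: str) -> tuple[int, ...]:
    """Unpaired-run lengths of an isolated-loop dot-bracket.

    In the loop instance every child helix appears as a single pair whose
    interior is a splice cap, so the loop's strands are the unpaired runs
    at depth 1 (between the closing pair and the child pairs).
    """
    depth = 0
    strands: list[int] = []
    run = 0
    inside_child = False
    for ch in loop_db:
        if ch == "(":
            depth += 1
            if depth == 2:
                strands.append(run)
                run = 0
                inside_child = True
        elif ch == ")":
            depth -= 1
            if depth == 1:
                inside_child = False
        elif depth == 1 and not inside_child:
            run += 1
    strands.append(run)
    return tuple(strands)


def default_classifiers(seed: int = 0) -> dict[str, object]:
    """The three baseline classifiers: kNN (k=3), decision tree, naive Bayes."""
    return {
        "knn": KNeighborsClassifier(n_neighbors=3),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "naive_bayes": GaussianNB(),
    }


def stratified_kfold_eval(
    table: FeatureTable,
    k: int = 5,
    classifiers: Mapping[str, object] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold macro-F1 evaluation of the feature table.

    Folds preserve class proportions to within one row and are fully
    determined by the seed.  Returns a tidy frame with one row per
    (classifier, fold) plus min/max/median/mean summary rows per
    classifier.
    """
    if not table.usable:
        raise ValueError("feature table has a single class; cannot cross-validate")
    y = table.y
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than {k} rows")
    classifiers = classifiers or default_classifiers(seed)
    X = table.X
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    for name, clf in classifiers.items():
        scores = []
        for fold, (train, test) in enumerate(splits, start=1):
            from sklearn.base import clone

            model = clone(clf)
            model.fit(X[train], y[train])
            score = f1_score(y[test], model.predict(X[test]), average="macro")
            scores.append(score)
            rows.append({"classifier": name, "fold": str(fold), "macro_f1": score})
        arr = np.array(scores)
        for stat, val in [
            ("min", arr.min()),
            ("max", arr.max()),
            ("median", float(np.median(arr))),
            ("mean", arr.mean()),
        ]:
            rows.append({"classifier": name, "fold": stat, "macro_f1": float(val)})
    return pd.DataFrame(rows)


def group_split(
    table: FeatureTable, test_size: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Group-aware train/test split: no family straddles the two sets."""
    groups = table.groups
    if groups is None:
        raise ValueError("feature table carries no family/group column")
    splitter = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
    train, test = next(splitter.split(table.X, table.y, groups))
    return train, test
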
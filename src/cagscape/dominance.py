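"""Single-CAG-dominated sample selection and separability check.

A sample is dominated by a CAG when that CAG's abundance is at or above
the CAG's 95th percentile across the whole cohort, and by no other CAG.
Samples exceeding two or more thresholds are excluded (the strict "one and
only one" reading) and reported.  Separability of the dominated groups is
quantified by the out-of-bag accuracy of a bagged decision-tree ensemble
on the OTU profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core_io import AbundanceTable


@dataclass
class DominanceSelection:
    thresholds: pd.Series  # CAG -> 95th-percentile threshold
    dominated_by: pd.Series  # sample -> CAG label or NaN
    selected: list[str]
    excluded_multi: list[str]  # samples above >= 2 thresholds
    percentile: float


def select_dominated(profile: pd.DataFrame, percentile: float = 95) -> DominanceSelection:
    """Apply the >= percentile rule per CAG column (type-7 interpolation)."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be inside (0, 100)")
    if profile.shape[1] < 2:
        raise ValueError("need at least 2 CAGs")
    if profile.shape[0] < 20:
        raise ValueError("need at least 20 samples")
    values = profile.to_numpy(dtype=float)
    thresholds = pd.Series(
        np.percentile(values, percentile, axis=0, method="linear"),
        index=profile.columns,
        name="threshold",
    )
    exceeds = values >= thresholds.to_numpy()[None, :]
    n_exceeded = exceeds.sum(axis=1)
    dominated = pd.Series(np.nan, index=profile.index, dtype=object, name="dominated_by")
    single = n_exceeded == 1
    dominated[single] = profile.columns.to_numpy()[np.argmax(exceeds[single], axis=1)]
    return DominanceSelection(
        thresholds=thresholds,
        dominated_by=dominated,
        selected=list(profile.index[single]),
        excluded_multi=list(profile.index[n_exceeded >= 2]),
        percentile=float(percentile),
    )


@dataclass
class ReclassificationReport:
    n_trees: int
    oob_accuracy: float
    resubstitution_accuracy: float
    confusion: pd.DataFrame  # rows: true CAG, cols: OOB-predicted CAG
    seed: int


def reclassify(
    t: AbundanceTable,
    selection: DominanceSelection,
    n_trees: int = 1000,
    seed: int = 0,
) -> ReclassificationReport:
    """Out-of-bag accuracy of a bagged tree ensemble on dominated samples.

    Per-tree bootstrap of samples, sqrt(p) feature candidates per split,
    Gini criterion, trees grown to purity.
    """
    labels = selection.dominated_by.dropna()
    if labels.nunique() < 2:
        raise ValueError("need at least 2 nonempty dominated groups")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    x = t.data.loc[labels.index].to_numpy(dtype=float)
    y = labels.to_numpy(dtype=object).astype(str)
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(x, y)
    oob_votes = clf.oob_decision_function_
    oob_pred = clf.classes_[np.argmax(oob_votes, axis=1)]
    covered = oob_votes.sum(axis=1) > 0  # samples in-bag everywhere get no vote
    oob_acc = float(np.mean(oob_pred[covered] == y[covered]))
    resub = float(np.mean(clf.predict(x) == y))
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(oob_pred, name="oob_predicted")
    )
    classes = sorted(set(y))
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)
    return ReclassificationReport(
        n_trees=n_trees,
        oob_accuracy=oob_acc,
        resubstitution_accuracy=resub,
        confusion=confusion,
        seed=seed,
    )
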
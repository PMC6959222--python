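"""Bayesian-like multi-label activity model with Pa/Pi calibration.

For every activity (mechanism of action) the model stores how often each
MNA descriptor occurs among molecules known to be active versus
non-active.  A molecule's raw score for an activity is

    B = mean over its distinct descriptors d of
        log[ (f_active(d) + s) / (f_nonactive(d) + s) ]

where f_class(d) is the fraction of that class's training molecules
containing d, and s is a symmetric smoothing constant (so descriptors
never seen in training contribute 0).  B is calibrated against the
model's own leave-one-out score distributions:

    Pa = fraction of actives' LOO scores <= B
    Pi = fraction of non-actives' LOO scores >= B

making Pa non-decreasing and Pi non-increasing in B by construction.
Model quality per activity is summarized by the AUC of the LOO scores
(ties counted half).

This is an openly specified variant of the substructure-Bayesian
approach used by activity-spectrum predictors; it shares the interface
(descriptors -> B -> Pa/Pi -> LOO AUC), not any proprietary training
corpus or scoring constants.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from netprev.revpharm.descriptors import mna_profile
from netprev.revpharm.molecules import Molecule

DEFAULT_LEVEL = 2
DEFAULT_SMOOTHING = 1.0


@dataclass
class ActivityStats:
    """Per-activity descriptor counts and LOO calibration scores."""

    n_active: int
    n_nonactive: int
    active_counts: dict[str, int]
    nonactive_counts: dict[str, int]
    loo_scores_active: list[float]
    loo_scores_nonactive: list[float]


@dataclass
class ActivityModel:
    level: int
    smoothing: float
    activities: dict[str, ActivityStats] = field(default_factory=dict)

    def activity_names(self) -> list[str]:
        return sorted(self.activities)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "netprev-activity-model",
            "version": 1,
            "level": self.level,
            "smoothing": self.smoothing,
            "activities": {
                name: {
                    "n_active": st.n_active,
                    "n_nonactive": st.n_nonactive,
                    "active_counts": st.active_counts,
                    "nonactive_counts": st.nonactive_counts,
                    "loo_scores_active": st.loo_scores_active,
                    "loo_scores_nonactive": st.loo_scores_nonactive,
                }
                for name, st in self.activities.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ActivityModel":
        d = json.loads(Path(path).read_text())
        model = cls(level=d["level"], smoothing=d["smoothing"])
        for name, st in d["activities"].items():
            model.activities[name] = ActivityStats(
                n_active=st["n_active"],
                n_nonactive=st["n_nonactive"],
                active_counts=dict(st["active_counts"]),
                nonactive_counts=dict(st["nonactive_counts"]),
                loo_scores_active=list(st["loo_scores_active"]),
                loo_scores_nonactive=list(st["loo_scores_nonactive"]),
            )
        return model


@dataclass(frozen=True)
class Prediction:
    mol_id: str
    activity: str
    score_B: float
    Pa: float
    Pi: float


def _descriptor_sets(
    molecules: Sequence[Molecule], level: int
) -> list[frozenset[str]]:
    return [mna_profile(m, level) for m in molecules]


def _score_from_counts(
    descriptors: frozenset[str],
    active_counts: Mapping[str, int],
    nonactive_counts: Mapping[str, int],
    n_active: int,
    n_nonactive: int,
    smoothing: float,
) -> float:
    if not descriptors:
        return 0.0
    total = 0.0
    for d in descriptors:
        fa = active_counts.get(d, 0) / n_active if n_active else 0.0
        fi = nonactive_counts.get(d, 0) / n_nonactive if n_nonactive else 0.0
        total += math.log((fa + smoothing) / (fi + smoothing))
    return total / len(descriptors)


def train(
    training_molecules: Sequence[Molecule],
    labels: pd.DataFrame,
    level: int = DEFAULT_LEVEL,
    smoothing: float = DEFAULT_SMOOTHING,
) -> ActivityModel:
    """Fit descriptor statistics and LOO calibration for every activity.

    ``labels`` is a 0/1 matrix indexed by molecule id with one column per
    activity.  Activities lacking either class (or entirely unlabeled)
    are skipped with a warning.  Duplicate molecules simply weigh in with
    their multiplicity.
    """
    desc_sets = _descriptor_sets(training_molecules, level)
    descs = {
        m.mol_id: ds
        for m, ds in zip(training_molecules, desc_sets)
        if m.mol_id in labels.index
    }
    model = ActivityModel(level=level, smoothing=smoothing)
    for activity in labels.columns:
        col = labels[activity].dropna()
        col = col[[i for i in col.index if i in descs]]
        active_ids = [i for i in col.index if col[i] == 1]
        nonactive_ids = [i for i in col.index if col[i] == 0]
        if not active_ids or not nonactive_ids:
            warnings.warn(
                f"activity {activity!r}: needs at least one active and one "
                "non-active training molecule; skipped"
            )
            continue
        active_counts: dict[str, int] = {}
        nonactive_counts: dict[str, int] = {}
        for i in active_ids:
            for d in descs[i]:
                active_counts[d] = active_counts.get(d, 0) + 1
        for i in nonactive_ids:
            for d in descs[i]:
                nonactive_counts[d] = nonactive_counts.get(d, 0) + 1
        stats = ActivityStats(
            n_active=len(active_ids),
            n_nonactive=len(nonactive_ids),
            active_counts=active_counts,
            nonactive_counts=nonactive_counts,
            loo_scores_active=[],
            loo_scores_nonactive=[],
        )
        # Leave-one-out scores: remove each molecule from its own class
        # counts before scoring it.
        for i in active_ids:
            held = {d: active_counts[d] - 1 for d in descs[i]}
            counts = {**active_counts, **held}
            stats.loo_scores_active.append(
                _score_from_counts(
                    descs[i], counts, nonactive_counts,
                    len(active_ids) - 1, len(nonactive_ids), smoothing,
                )
            )
        for i in nonactive_ids:
            held = {d: nonactive_counts[d] - 1 for d in descs[i]}
            counts = {**nonactive_counts, **held}
            stats.loo_scores_nonactive.append(
                _score_from_counts(
                    descs[i], active_counts, counts,
                    len(active_ids), len(nonactive_ids) - 1, smoothing,
                )
            )
        model.activities[activity] = stats
    return model


def score(model: ActivityModel, molecule: Molecule, activity: str) -> float:
    """Raw log-likelihood-ratio style score B for one activity."""
    if activity not in model.activities:
        raise KeyError(f"model has no trained activity {activity!r}")
    st = model.activities[activity]
    descriptors = mna_profile(molecule, model.level)
    return _score_from_counts(
        descriptors,
        st.active_counts,
        st.nonactive_counts,
        st.n_active,
        st.n_nonactive,
        model.smoothing,
    )


def predict(model: ActivityModel, molecule: Molecule) -> list[Prediction]:
    """Pa/Pi for every trained activity, calibrated on LOO distributions."""
    out = []
    descriptors = mna_profile(molecule, model.level)
    for activity in model.activity_names():
        st = model.activities[activity]
        b = _score_from_counts(
            descriptors, st.active_counts, st.nonactive_counts,
            st.n_active, st.n_nonactive, model.smoothing,
        )
        pa = float(np.mean([s <= b for s in st.loo_scores_active]))
        pi = float(np.mean([s >= b for s in st.loo_scores_nonactive]))
        out.append(Prediction(mol_id=molecule.mol_id, activity=activity, score_B=b, Pa=pa, Pi=pi))
    return out


def predict_all(model: ActivityModel, molecules: Sequence[Molecule]) -> list[Prediction]:
    preds: list[Prediction] = []
    for m in molecules:
        preds.extend(predict(model, m))
    return preds


def predictions_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.mol_id, p.activity, p.score_B, p.Pa, p.Pi) for p in predictions],
        columns=["mol_id", "activity", "B", "Pa", "Pi"],
    )


def loo_auc(
    training_molecules: Sequence[Molecule],
    labels: pd.DataFrame,
    activity: str,
    level: int = DEFAULT_LEVEL,
    smoothing: float = DEFAULT_SMOOTHING,
) -> float:
    """Leave-one-out AUC of the raw scores for one activity."""
    col = labels[activity].dropna()
    n_active = int((col == 1).sum())
    n_nonactive = int((col == 0).sum())
    if n_active < 2 or n_nonactive < 2:
        raise ValueError(
            f"activity {activity!r}: need >= 2 molecules per class, "
            f"got {n_active} active / {n_nonactive} non-active"
        )
    model = train(training_molecules, labels[[activity]], level=level, smoothing=smoothing)
    st = model.activities[activity]
    scores = np.array(st.loo_scores_active + st.loo_scores_nonactive)
    truth = np.array([1] * len(st.loo_scores_active) + [0] * len(st.loo_scores_nonactive))
    return float(roc_auc_score(truth, scores))
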
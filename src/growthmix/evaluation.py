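"""Evaluation of fitted mixtures against the simulated truth.

A mixture likelihood is invariant to class relabeling, so before any
parameter can be compared with its generating value the estimated classes
must be linked to the simulated ones. Linking here is membership-based:
subjects are assigned to their modal posterior class, the K x K confusion
matrix of (simulated, estimated) labels is built, and the one-to-one
matching maximizing the total matched count is taken. The classes count as
*recovered* only when every simulated class hands a strict majority of its
members to its matched estimated class; otherwise the simulated classes were
dispersed over several estimated ones and bias/accuracy are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .parameters import GMMParameters

#: majority-capture threshold of the recovery rule (strict inequality)
RECOVERY_THRESHOLD = 0.5


class NotRecoveredError(ValueError):
    """Raised when bias or accuracy is requested for a replication whose
    simulated classes were not recovered (the quantity is undefined)."""


@dataclass
class ClassLinking:
    """Injective map simulated-class -> estimated-class plus diagnostics."""

    mapping: np.ndarray  # mapping[j] = estimated class index matched to true class j
    recovered: bool
    confusion: np.ndarray  # K_true x K_est modal-assignment counts


def modal_assignment(posteriors: np.ndarray) -> np.ndarray:
    """Modal class per subject (ties broken toward the lowest index)."""
    return np.argmax(posteriors, axis=1)


def link_classes(
    true_labels: np.ndarray,
    posteriors: np.ndarray,
    threshold: float = RECOVERY_THRESHOLD,
) -> ClassLinking:
    """Match estimated to simulated classes by maximum membership overlap.

    ``true_labels`` are coded 1..K. The optimal one-to-one matching on the
    confusion matrix is found by linear assignment; ``recovered`` is True
    iff every simulated class places strictly more than ``threshold`` of its
    members in its matched estimated class. Degenerate posteriors (NaN)
    yield ``recovered=False``.
    """
    true_labels = np.asarray(true_labels, dtype=int)
    K = posteriors.shape[1]
    if true_labels.min() < 1 or true_labels.max() > K:
        raise ValueError("true labels must be coded 1..K with K = posterior columns")
    if not np.isfinite(posteriors).all():
        return ClassLinking(np.arange(K), False, np.zeros((K, K), dtype=int))
    modal = modal_assignment(posteriors)
    confusion = np.zeros((K, K), dtype=int)
    np.add.at(confusion, (true_labels - 1, modal), 1)
    rows, cols = linear_sum_assignment(-confusion)
    mapping = np.empty(K, dtype=int)
    mapping[rows] = cols
    row_tot = confusion.sum(axis=1)
    recovered = bool(
        (row_tot > 0).all()
        and (confusion[np.arange(K), mapping] > threshold * row_tot).all()
    )
    return ClassLinking(mapping, recovered, confusion)


def relative_bias(
    pop: GMMParameters, fitted: GMMParameters, linking: ClassLinking
) -> pd.DataFrame:
    """Relative bias of the growth-mean parameters per linked class.

    Each row holds the signed relative bias ``(est - true) / true`` for one
    (class, parameter) together with its absolute value; when the generating
    value is exactly zero the entry is the plain bias ``est - true``
    (flagged in the ``relative`` column). The study-level summary averages
    the *signed* per-replication bias and reports its absolute value, which
    is the quantity a Monte-Carlo bias table prints (sampling noise cancels
    across replications; a systematic offset does not).
    Undefined without recovery: raises :class:`NotRecoveredError`.
    """
    if not linking.recovered:
        raise NotRecoveredError("bias undefined: simulated classes were not recovered")
    rows = []
    names = ["intercept", "slope", "quadratic", "cubic"][: pop.n_growth_terms]
    for j in range(pop.n_classes):
        est_class = linking.mapping[j]
        for p, name in enumerate(names):
            true = pop.fixed_effects[j, p]
            est = fitted.fixed_effects[est_class, p]
            rel = true != 0.0
            bias = (est - true) / true if rel else est - true
            rows.append(
                {
                    "class": j + 1,
                    "parameter": name,
                    "true": true,
                    "estimated": est,
                    "bias": bias,
                    "abs_bias": abs(bias),
                    "relative": rel,
                }
            )
    return pd.DataFrame(rows)


def classification_accuracy(
    true_labels: np.ndarray, posteriors: np.ndarray, linking: ClassLinking
) -> float:
    """Share of subjects whose modal class is the linked image of their
    simulated class. Undefined (raises) without recovery."""
    if not linking.recovered:
        raise NotRecoveredError("accuracy undefined: simulated classes were not recovered")
    modal = modal_assignment(posteriors)
    mapped = linking.mapping[np.asarray(true_labels, dtype=int) - 1]
    return float((modal == mapped).mean())


_LOWER_IS_BETTER = {"AIC": True, "BIC": True, "aBIC": True, "entropy": False}


def select_best_model(fits, criterion: str):
    """Scheme id winning on a fit criterion among converged fits.

    Lowest value wins for AIC/BIC/aBIC, highest for entropy. Ties go to the
    model with fewer free parameters, then to the lexicographically smaller
    scheme id. Returns ``None`` when no fit converged.
    """
    if criterion not in _LOWER_IS_BETTER:
        raise ValueError(f"unknown criterion {criterion!r}")
    lower = _LOWER_IS_BETTER[criterion]
    candidates = [
        f
        for f in fits
        if f.converged and np.isfinite(f.indices.get(criterion, np.nan))
    ]
    if not candidates:
        return None
    def key(f):
        v = f.indices[criterion]
        return (v if lower else -v, f.n_params, f.scheme.id)
    return min(candidates, key=key).scheme.id
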
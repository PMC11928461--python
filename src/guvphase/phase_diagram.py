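"""Condensed/dispersed classification and SVM phase-boundary fitting.

A field of view is called *condensed* when the detected condensates are
both large and numerous: mean condensate area > 0.4 µm² AND more than 20
condensates per 90 µm² reference region. The count is normalised to the
90 µm² reference so fields of any size are comparable, and the decision
is invariant to subdividing the field. Over a two-concentration grid of
such calls, the phase boundary is fitted with a support-vector machine
(linear or 2nd-degree polynomial kernel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateLabelsError, ParameterError
from .imaging import Condensate

__all__ = [
    "PhasePoint",
    "PhaseBoundary",
    "classify_phase_state",
    "fit_phase_boundary",
    "AREA_CUT_UM2",
    "COUNT_CUT_PER_90UM2",
    "REFERENCE_AREA_UM2",
]

#: Condensed-state thresholds: mean area and count per reference region.
AREA_CUT_UM2 = 0.4
COUNT_CUT_PER_90UM2 = 20.0
REFERENCE_AREA_UM2 = 90.0


@dataclass
class PhasePoint:
    """One observation on the two-concentration phase diagram."""

    conc_x_uM: float
    conc_y_uM: float
    mean_area_um2: float
    count_per_90um2: float
    state: str  # {"condensed", "dispersed"}

    def __post_init__(self) -> None:
        if self.conc_x_uM < 0 or self.conc_y_uM < 0:
            raise ParameterError("concentrations must be non-negative")
        if self.count_per_90um2 < 0:
            raise ParameterError("count density must be non-negative")
        if self.state not in ("condensed", "dispersed"):
            raise ParameterError("state must be 'condensed' or 'dispersed'")


@dataclass
class PhaseBoundary:
    """Fitted condensed/dispersed decision surface."""

    kernel: str
    model: Pipeline
    training_accuracy: float
    regularization: float

    def classify(self, conc_x_uM: float, conc_y_uM: float) -> str:
        """State predicted for a (non-negative) concentration pair."""
        if conc_x_uM < 0 or conc_y_uM < 0:
            raise ParameterError("concentrations must be non-negative")
        label = self.model.predict(np.array([[conc_x_uM, conc_y_uM]]))[0]
        return "condensed" if label == 1 else "dispersed"

    def decision_map(self, conc_x: Sequence[float], conc_y: Sequence[float]) -> np.ndarray:
        """Rasterised state grid (1 = condensed) over the outer product of
        the two concentration axes; rows follow ``conc_y``."""
        xx, yy = np.meshgrid(np.asarray(conc_x, float), np.asarray(conc_y, float))
        pred = self.model.predict(np.column_stack([xx.ravel(), yy.ravel()]))
        return pred.reshape(xx.shape)


def classify_phase_state(
    condensates: Sequence[Condensate],
    field_area_um2: float,
    area_cut_um2: float = AREA_CUT_UM2,
    count_cut: float = COUNT_CUT_PER_90UM2,
) -> dict:
    """Call the phase state of a field from its detected condensates.

    Returns a dict with ``mean_area_um2``, ``count_per_90um2`` and
    ``state``. An empty condensate list is dispersed with mean area
    reported as 0, so the classifier is total.
    """
    if field_area_um2 <= 0:
        raise ParameterError("field_area_um2 must be positive")
    n = len(condensates)
    mean_area = float(np.mean([c.area_um2 for c in condensates])) if n else 0.0
    count_per_90 = n * REFERENCE_AREA_UM2 / field_area_um2
    condensed = mean_area > area_cut_um2 and count_per_90 > count_cut
    return {
        "mean_area_um2": mean_area,
        "count_per_90um2": count_per_90,
        "state": "condensed" if condensed else "dispersed",
    }


def fit_phase_boundary(
    points: Sequence[PhasePoint],
    kernel: str = "linear",
    regularization: float = 1.0,
    seed: int = 0,
) -> PhaseBoundary:
    """Fit the condensed/dispersed boundary over concentration space with
    an SVM (``linear`` or ``poly2`` kernel).

    Features are the two concentrations (standardised before the SVM);
    the fit is deterministic for a given point set and invariant to point
    order. Raises :class:`DegenerateLabelsError` when all points share
    one state.
    """
    if kernel not in ("linear", "poly2"):
        raise ParameterError("kernel must be 'linear' or 'poly2'")
    if regularization <= 0:
        raise ParameterError("regularization must be positive")
    X = np.array([[p.conc_x_uM, p.conc_y_uM] for p in points], dtype=float)
    y = np.array([1 if p.state == "condensed" else 0 for p in points])
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("need at least one point of each state")
    if kernel == "linear":
        svc = SVC(kernel="linear", C=regularization, random_state=seed)
    else:
        svc = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale",
                  C=regularization, random_state=seed)
    model = Pipeline([("scale", StandardScaler()), ("svm", svc)])
    # fit on a canonical ordering so permuted inputs give identical models
    order = np.lexsort((y, X[:, 1], X[:, 0]))
    model.fit(X[order], y[order])
    accuracy = float((model.predict(X) == y).mean())
    return PhaseBoundary(kernel=kernel, model=model,
                         training_accuracy=accuracy, regularization=regularization)
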
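"""Dual-trait specificity analysis.

Partitions the features explaining one trait against those explaining
another (shared vs trait-specific sets) and validates the specificity by
cross-prediction: a trait-specific feature set should carry no predictive
signal for the other trait, operationalized as the first latent
component's cross-validated Q^2 falling below the component-entry
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .pls import assign_folds, choose_ncomp

__all__ = ["OverlapResult", "CrossPrediction", "partition_sets", "cross_predict"]


@dataclass
class OverlapResult:
    """Set partition of two feature selections."""

    set_a: list[str]
    set_b: list[str]
    shared: list[str]
    a_specific: list[str]
    b_specific: list[str]

    def to_dict(self) -> dict:
        return {
            "set_a": self.set_a,
            "set_b": self.set_b,
            "shared": self.shared,
            "a_specific": self.a_specific,
            "b_specific": self.b_specific,
            "counts": {
                "a": len(self.set_a),
                "b": len(self.set_b),
                "shared": len(self.shared),
                "a_specific": len(self.a_specific),
                "b_specific": len(self.b_specific),
            },
        }


def partition_sets(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapResult:
    """Exact set algebra: shared and trait-specific feature sets."""
    a = set(map(str, set_a))
    b = set(map(str, set_b))
    return OverlapResult(
        set_a=sorted(a),
        set_b=sorted(b),
        shared=sorted(a & b),
        a_specific=sorted(a - b),
        b_specific=sorted(b - a),
    )


@dataclass
class CrossPrediction:
    """Cross-prediction verdict for one direction."""

    n_features: int
    q2_first_component: float
    q2: float  # at the CV-chosen component count
    n_components: int
    verdict: str  # "predictive" | "no predictive component" | "vacuous"


def cross_predict(
    x: pd.DataFrame,
    specific_features: list[str],
    other_trait: np.ndarray,
    folds: int = 7,
    seed: int = 0,
    eps_comp: float = 0.01,
) -> CrossPrediction:
    """Predict the *other* trait from one trait's specific features.

    Components are chosen by the usual cross-validation; the verdict is
    "no predictive component" when the *first* component's cross-validated
    Q^2 already falls below ``eps_comp`` (the threshold that gates
    component entry during model building), and "vacuous" when the
    specific set is empty. The reported Q^2 is at the chosen component
    count.
    """
    if len(specific_features) == 0:
        return CrossPrediction(0, float("nan"), float("nan"), 0, "vacuous")
    other_trait = np.asarray(other_trait, dtype=float)
    xr = x[specific_features].to_numpy(dtype=float)
    fold_assign = assign_folds(len(other_trait), folds, seed)
    report = choose_ncomp(
        xr, other_trait, eps_comp=eps_comp, fold_assign=fold_assign
    )
    q2_first = report.q2_per_component[0]
    q2_chosen = report.q2_per_component[report.chosen_components - 1]
    verdict = "predictive" if q2_first >= eps_comp else "no predictive component"
    return CrossPrediction(
        len(specific_features),
        float(q2_first),
        float(q2_chosen),
        report.chosen_components,
        verdict,
    )
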
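"""Iterative variable selection for PLS-DA (line) and PLS (trait) models.

The loop mirrors the study design for finding features with a correlated
response to selection: fit the model on the current feature set, mark
features with VIP > 0.8 or a jackknife 95% CI excluding zero, drop a batch
of unmarked features (lowest VIP first), and accept the step only if the
cross-validated prediction ability did not decrease; once no unmarked
features remain, single lowest-VIP removals are attempted until one hurts
prediction. Prediction ability is cross-validated misclassification in
discriminant mode (Q^2 as tie-break) and Q^2 in regression mode.

``run_dual_selection`` composes the full chain — reference search, alr
transform, DMOD outlier screening, both selection loops on shared folds —
and intersects the two final sets; ``compare_transforms`` repeats it on
raw relative abundances to quantify how much the compositional transform
changes the answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositional import (
    AbundanceTable,
    alr_transform,
    evaluate_reference_candidates,
    select_reference,
    to_relative,
)
from .pls import (
    assign_folds,
    choose_ncomp,
    dmod,
    fit_pls,
    jackknife_ci,
    misclassification,
    q_squared,
    vip,
)

__all__ = [
    "SelectionSettings",
    "SelectionResult",
    "DualSelectionResult",
    "TransformComparison",
    "select_features",
    "run_dual_selection",
    "compare_transforms",
]


@dataclass
class SelectionSettings:
    """Tunable constants of the selection loop."""

    vip_threshold: float = 0.8
    jackknife_level: float = 0.95
    eps_comp: float = 0.01  # minimum cumulative-Q2 gain to add a component
    eps_stop: float = 0.005  # tolerated ability decrease per accepted step
    batch_frac: float = 0.2  # at most this fraction of features removed per step
    max_components: int = 10
    folds: int = 7
    min_features: int = 2


@dataclass
class IterationRecord:
    n_features: int
    n_components: int
    ability: float  # cv-misclassification (discriminant) or Q2 (regression)
    q2: float


@dataclass
class SelectionResult:
    """Outcome of one selection loop."""

    mode: str  # "discriminant" | "regression"
    transform: str  # "alr" | "relative"
    iterations: list[IterationRecord]
    final_features: list[str]
    stop_reason: str
    seed: int

    @property
    def final_ability(self) -> float:
        return self.iterations[-1].ability

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "transform": self.transform,
            "final_features": self.final_features,
            "stop_reason": self.stop_reason,
            "seed": self.seed,
            "iterations": [
                {
                    "n_features": it.n_features,
                    "n_components": it.n_components,
                    "ability": it.ability,
                    "q2": it.q2,
                }
                for it in self.iterations
            ],
        }


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    """Two-class +1/-1 dummy coding; 'obese' maps to +1 when present."""
    labels = np.asarray(labels)
    uniq = list(pd.unique(pd.Series(labels)))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    if "obese" in uniq and "lean" in uniq:
        pos = "obese"
    else:
        pos = uniq[0]
    return np.where(labels == pos, 1.0, -1.0)


def _evaluate(
    x: np.ndarray,
    y: np.ndarray,
    mode: str,
    settings: SelectionSettings,
    fold_assign: np.ndarray,
) -> tuple[int, float, float]:
    """(chosen A, ability, Q2) for a feature subset on fixed folds."""
    report = choose_ncomp(
        x,
        y,
        max_components=settings.max_components,
        eps_comp=settings.eps_comp,
        mode=mode,
        fold_assign=fold_assign,
    )
    a = report.chosen_components
    q2 = report.q2_per_component[a - 1]
    if mode == "discriminant":
        _, cv_mis = misclassification(x, y, a, fold_assign=fold_assign)
        return a, cv_mis, q2
    return a, q2, q2


def _is_acceptable(
    new: tuple[float, float], old: tuple[float, float], mode: str, eps_stop: float
) -> bool:
    """Did ability not decrease by more than eps_stop?

    Discriminant mode compares misclassification (lower better) first and
    breaks exact ties on Q2; regression mode compares Q2 (higher better).
    """
    if mode == "discriminant":
        if new[0] < old[0] - eps_stop:
            return True
        if new[0] > old[0] + eps_stop:
            return False
        if new[0] == old[0]:
            return new[1] >= old[1] - eps_stop
        return True
    return new[0] >= old[0] - eps_stop


def select_features(
    x: pd.DataFrame,
    y_or_labels: np.ndarray,
    mode: str,
    settings: SelectionSettings | None = None,
    seed: int = 0,
    transform: str = "alr",
    fold_assign: np.ndarray | None = None,
) -> SelectionResult:
    """Run the iterative VIP / jackknife selection loop.

    ``x`` is a samples x features DataFrame (alr values or relative
    abundances); ``y_or_labels`` is a continuous trait (regression) or a
    two-class label vector (discriminant). Deterministic given the seed:
    fold assignment is fixed once and reused for every refit.
    """
    if mode not in ("discriminant", "regression"):
        raise ValueError("mode must be 'discriminant' or 'regression'")
    settings = settings or SelectionSettings()
    y = (
        _encode_labels(y_or_labels)
        if mode == "discriminant"
        else np.asarray(y_or_labels, dtype=float)
    )
    if fold_assign is None:
        labels = y if mode == "discriminant" else None
        fold_assign = assign_folds(len(y), settings.folds, seed, labels)

    features = list(x.columns)
    xv = x.to_numpy(dtype=float)
    a, ability, q2 = _evaluate(xv, y, mode, settings, fold_assign)
    iterations = [IterationRecord(len(features), a, ability, q2)]
    stop_reason = "converged"

    while True:
        if len(features) <= settings.min_features:
            stop_reason = "floor"
            break
        model = fit_pls(xv, y, a, mode=mode)
        vips = np.zeros(xv.shape[1])
        vips[model.kept] = vip(model).values
        ci = jackknife_ci(xv, y, a, fold_assign=fold_assign, mode=mode,
                          level=settings.jackknife_level)
        marked = (vips > settings.vip_threshold) | ci.excludes_zero

        order = np.argsort(vips, kind="stable")
        candidates = [j for j in order if not marked[j]]
        single_trial = False
        if candidates:
            batch = max(1, int(settings.batch_frac * len(features)))
            batch = min(batch, len(candidates), len(features) - settings.min_features)
        else:
            # every remaining feature is selected by the VIP/jackknife
            # rule; still test the stopping condition by trying to remove
            # one more feature (the least important) — if that degrades
            # prediction, the loop has converged
            candidates = [order[0]]
            batch = 1
            single_trial = True

        def _try(drop: set[int]) -> tuple | None:
            keep = [j for j in range(len(features)) if j not in drop]
            xv_new = xv[:, keep]
            a_n, ab_n, q2_n = _evaluate(xv_new, y, mode, settings, fold_assign)
            if _is_acceptable((ab_n, q2_n), (ability, q2), mode, settings.eps_stop):
                return keep, xv_new, a_n, ab_n, q2_n
            return None

        # shrink the batch on rejection; once at single removals, try each
        # candidate in turn — the loop ends only when no single-feature
        # removal survives
        accepted = None
        while batch > 1 and accepted is None:
            accepted = _try(set(candidates[:batch]))
            if accepted is None:
                batch //= 2
        if accepted is None:
            for j in candidates:
                accepted = _try({j})
                if accepted is not None:
                    break
        if accepted is None:
            stop_reason = "converged" if single_trial else "no_improvement"
            break
        keep, xv, a, ability, q2 = accepted
        features = [features[j] for j in keep]
        iterations.append(IterationRecord(len(features), a, ability, q2))

    return SelectionResult(
        mode=mode,
        transform=transform,
        iterations=iterations,
        final_features=features,
        stop_reason=stop_reason,
        seed=seed,
    )


@dataclass
class DualSelectionResult:
    """Full chain output: both selection loops plus shared preprocessing."""

    line_result: SelectionResult
    imf_result: SelectionResult
    intersection: list[str]
    reference_id: str | None
    outlier_ids: list[str]
    dmod_critical: float
    transform: str
    seed: int


def _design_matrix(
    counts: AbundanceTable,
    trait: np.ndarray,
    transform: str,
    reference: str,
) -> tuple[pd.DataFrame, str | None]:
    rel = to_relative(counts)
    if transform == "alr":
        if reference == "auto":
            report = evaluate_reference_candidates(rel, trait)
            try:
                reference = select_reference(report).reference_id
            except ValueError:
                # no candidate clears the trait-decorrelation filter (its
                # error advises relaxation): fall back to geometry and
                # variance only
                reference = select_reference(
                    report, trait_corr_se_mult=float("inf")
                ).reference_id
        alr = alr_transform(rel, reference)
        return alr.to_frame(), reference
    if transform == "relative":
        return rel.to_frame(), None
    raise ValueError("transform must be 'alr' or 'relative'")


def run_dual_selection(
    counts: AbundanceTable,
    metadata: pd.DataFrame,
    transform: str = "alr",
    reference: str = "auto",
    settings: SelectionSettings | None = None,
    seed: int = 0,
    trait_column: str = "imf",
    screen_outliers: bool = True,
) -> DualSelectionResult:
    """Reference search, alr transform, DMOD screening, dual selection.

    Runs the discriminant (line) and regression (trait) selection loops on
    identical samples and fold assignment and returns both results with
    the intersection of their final feature sets.
    """
    settings = settings or SelectionSettings()
    metadata = metadata.loc[counts.sample_ids]
    trait = metadata[trait_column].to_numpy(dtype=float)
    x, ref_id = _design_matrix(counts, trait, transform, reference)
    labels = metadata["line"].to_numpy()
    y_da = _encode_labels(labels)

    outlier_ids: list[str] = []
    dmod_crit = float("nan")
    if screen_outliers:
        rep = choose_ncomp(
            x.to_numpy(), y_da,
            max_components=settings.max_components, folds=settings.folds,
            seed=seed, eps_comp=settings.eps_comp, mode="discriminant",
        )
        model = fit_pls(x.to_numpy(), y_da, rep.chosen_components, mode="discriminant")
        dm = dmod(model, x.to_numpy())
        dmod_crit = dm.critical_value
        outlier_ids = [x.index[i] for i in np.nonzero(dm.outliers)[0]]
        if outlier_ids:
            keep_mask = ~np.isin(x.index.to_numpy(), outlier_ids)
            x = x.loc[keep_mask]
            metadata = metadata.loc[keep_mask]
            labels = metadata["line"].to_numpy()
            trait = metadata[trait_column].to_numpy(dtype=float)

    fold_assign = assign_folds(len(x), settings.folds, seed, _encode_labels(labels))
    line_res = select_features(
        x, labels, "discriminant", settings, seed=seed, transform=transform,
        fold_assign=fold_assign,
    )
    imf_res = select_features(
        x, trait, "regression", settings, seed=seed, transform=transform,
        fold_assign=fold_assign,
    )
    inter = sorted(set(line_res.final_features) & set(imf_res.final_features))
    return DualSelectionResult(
        line_result=line_res,
        imf_result=imf_res,
        intersection=inter,
        reference_id=ref_id,
        outlier_ids=outlier_ids,
        dmod_critical=dmod_crit,
        transform=transform,
        seed=seed,
    )


@dataclass
class TransformComparison:
    """alr-based vs relative-abundance-based final sets."""

    alr_run: DualSelectionResult
    relative_run: DualSelectionResult
    jaccard: float
    shared: list[str]
    alr_only: list[str]
    relative_only: list[str]


def compare_transforms(
    counts: AbundanceTable,
    metadata: pd.DataFrame,
    settings: SelectionSettings | None = None,
    seed: int = 0,
    reference: str = "auto",
    trait_column: str = "imf",
) -> TransformComparison:
    """Run the dual selection under both transforms and compare the
    intersection sets (Jaccard index and discordant features)."""
    run_alr = run_dual_selection(
        counts, metadata, transform="alr", reference=reference,
        settings=settings, seed=seed, trait_column=trait_column,
    )
    run_rel = run_dual_selection(
        counts, metadata, transform="relative",
        settings=settings, seed=seed, trait_column=trait_column,
    )
    a = set(run_alr.intersection)
    b = set(run_rel.intersection)
    union = a | b
    return TransformComparison(
        alr_run=run_alr,
        relative_run=run_rel,
        jaccard=(len(a & b) / len(union)) if union else 1.0,
        shared=sorted(a & b),
        alr_only=sorted(a - b),
        relative_only=sorted(b - a),
    )
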
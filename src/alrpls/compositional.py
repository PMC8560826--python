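"""Compositional transforms and alr reference selection.

Shotgun functional profiles are compositional: read counts are constrained
by sequencing depth, so only ratios between features carry sample-level
information. This module provides closure to relative abundances, the
additive log-ratio (alr) and centered log-ratio (clr) transforms, a
Procrustes correlation between point configurations, and the four-criterion
search for an alr reference feature:

1. the alr geometry almost perfectly reproduces the full log-ratio
   (Aitchison) geometry, measured by Procrustes correlation;
2. the reference's log relative abundance has very low variance;
3. its relative abundance is uncorrelated with the trait of interest;
4. it is highly abundant.

All logs are natural logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "AlrTable",
    "to_relative",
    "alr_transform",
    "alr_inverse",
    "clr_coordinates",
    "procrustes_correlation",
    "evaluate_reference_candidates",
    "select_reference",
]


@dataclass
class AbundanceTable:
    """Samples x features abundance matrix.

    ``kind`` distinguishes raw counts from closed relative abundances;
    log-ratio operations require strictly positive entries.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    kind: Literal["counts", "relative"] = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, j = self.values.shape
        if n != len(self.sample_ids) or j != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != j:
            raise ValueError("duplicate feature ids")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("abundances must be finite and non-negative")
        if self.kind == "relative":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative table rows must sum to 1 within 1e-9")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = "counts") -> "AbundanceTable":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(i) for i in frame.index],
            feature_ids=[str(c) for c in frame.columns],
            kind=kind,  # type: ignore[arg-type]
        )

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(str(feature_id))
        except ValueError:
            raise KeyError(f"unknown feature id: {feature_id}") from None


@dataclass
class AlrTable:
    """Samples x (J-1) matrix of ln(x_j / x_ref) values.

    The reference feature is excluded from the numerators; together with a
    reference row the table reconstructs the relative table up to closure.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.reference_id = str(self.reference_id)
        if self.reference_id in self.feature_ids:
            raise ValueError("reference feature must be excluded from numerators")
        n, j1 = self.values.shape
        if n != len(self.sample_ids) or j1 != len(self.feature_ids):
            raise ValueError("shape mismatch in AlrTable")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each row to relative abundances (counts / row total).

    Idempotent on already-relative tables. Raises on any zero-sum row.
    """
    sums = table.values.sum(axis=1)
    if np.any(sums <= 0):
        bad = [table.sample_ids[i] for i in np.nonzero(sums <= 0)[0]]
        raise ValueError(f"zero or negative row sum for samples: {bad}")
    return AbundanceTable(
        values=table.values / sums[:, None],
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        kind="relative",
    )


def _require_positive(values: np.ndarray, what: str) -> None:
    if np.any(values <= 0):
        raise ValueError(f"{what} requires strictly positive entries")


def alr_transform(rel: AbundanceTable, reference_id: str) -> AlrTable:
    """Additive log-ratio transform: ln(x_j) - ln(x_ref) for j != ref.

    Invariant to positive row rescaling, hence identical on counts and on
    the closed relative table; subcompositionally coherent (a ratio does
    not change when uninvolved features are dropped and the table
    re-closed).
    """
    _require_positive(rel.values, "alr transform")
    ref_idx = rel.feature_index(reference_id)
    log_x = np.log(rel.values)
    alr = log_x - log_x[:, ref_idx][:, None]
    keep = [j for j in range(rel.n_features) if j != ref_idx]
    return AlrTable(
        values=alr[:, keep],
        sample_ids=list(rel.sample_ids),
        feature_ids=[rel.feature_ids[j] for j in keep],
        reference_id=rel.feature_ids[ref_idx],
    )


def alr_inverse(alr: AlrTable) -> AbundanceTable:
    """Invert the alr transform back to a closed relative table.

    Appends a zero log-ratio column for the reference and applies the
    softmax closure row-wise.
    """
    n = alr.n_samples
    full = np.column_stack([alr.values, np.zeros(n)])
    full -= full.max(axis=1, keepdims=True)  # overflow guard
    expd = np.exp(full)
    rel = expd / expd.sum(axis=1, keepdims=True)
    return AbundanceTable(
        values=rel,
        sample_ids=list(alr.sample_ids),
        feature_ids=list(alr.feature_ids) + [alr.reference_id],
        kind="relative",
    )


def clr_coordinates(rel: AbundanceTable) -> np.ndarray:
    """Centered log-ratio coordinates: per-row log values centered to mean 0.

    The Euclidean geometry of clr rows equals the full pairwise-log-ratio
    (Aitchison) geometry up to a 1/sqrt(J) scaling, which makes clr the
    tractable stand-in for "the geometry of the full set of ratios" at
    thousands of features.
    """
    _require_positive(rel.values, "clr transform")
    log_x = np.log(rel.values)
    return log_x - log_x.mean(axis=1, keepdims=True)


def _center_and_pad(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"row counts differ: {a.shape[0]} vs {b.shape[0]}")
    width = max(a.shape[1], b.shape[1], 2)
    if a.shape[1] < width:
        a = np.column_stack([a, np.zeros((a.shape[0], width - a.shape[1]))])
    if b.shape[1] < width:
        b = np.column_stack([b, np.zeros((b.shape[0], width - b.shape[1]))])
    return a - a.mean(axis=0), b - b.mean(axis=0)


def _reduce_config(x: np.ndarray, var_kept: float = 0.999) -> np.ndarray:
    """Project a centered configuration onto principal axes keeping >= var_kept.

    Rigid-motion invariant, so Procrustes correlation is unchanged up to the
    discarded variance; used to keep the candidate scan tractable when the
    number of columns is large.
    """
    if x.shape[1] <= x.shape[0]:
        return x
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return x[:, : min(x.shape)]
    keep = int(np.searchsorted(np.cumsum(var) / total, var_kept) + 1)
    keep = max(keep, 2)
    return u[:, :keep] * s[:keep]


def procrustes_correlation(config_a: np.ndarray, config_b: np.ndarray) -> float:
    """Procrustes correlation between two point configurations, in [0, 1].

    Both configurations are centered and scaled to unit Frobenius norm;
    config_b is then optimally rotated/reflected and isotropically scaled
    onto config_a. With the minimized normalized residual m^2 the
    correlation is sqrt(1 - m^2), which reduces in closed form to the sum
    of singular values of the cross-product of the two normalized centered
    configurations. Equals 1 exactly when the configurations differ only by
    translation, rotation/reflection and uniform scaling.
    """
    a, b = _center_and_pad(config_a, config_b)
    norm_a = np.linalg.norm(a)
    norm_b = np.linalg.norm(b)
    if norm_a == 0 or norm_b == 0:
        raise ValueError("degenerate configuration: all points identical")
    a = _reduce_config(a / norm_a)
    b = _reduce_config(b / norm_b)
    s = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(min(s.sum(), 1.0))


def _pearson_with_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0 or n < 3:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    se = float(np.sqrt((1 - r**2) / (n - 2)))
    return r, se


def evaluate_reference_candidates(
    rel: AbundanceTable,
    trait: np.ndarray | Sequence[float],
    candidates: Sequence[str] | Literal["all"] = "all",
) -> pd.DataFrame:
    """Score candidate alr reference features on the four selection criteria.

    Returns one row per candidate with columns:

    - ``procrustes_corr``: Procrustes correlation between the candidate's
      alr configuration and the full clr (Aitchison) geometry;
    - ``logrel_variance`` / ``logrel_cv_pct``: variance and coefficient of
      variation (100*sd/|mean|) of ln(relative abundance);
    - ``lr_min``..``lr_max``: five-point summary of ln(relative abundance);
    - ``trait_corr`` / ``trait_corr_se``: Pearson correlation of relative
      abundance with the trait, with its large-sample standard error (NaN
      and flagged when the trait is constant);
    - ``mean_rel_abund``: mean relative abundance.
    """
    rel = to_relative(rel) if rel.kind == "counts" else rel
    _require_positive(rel.values, "reference evaluation")
    trait = np.asarray(trait, dtype=float)
    if trait.shape != (rel.n_samples,):
        raise ValueError("trait length must equal the number of samples")

    if isinstance(candidates, str) and candidates == "all":
        cand_ids = list(rel.feature_ids)
    else:
        cand_ids = [str(c) for c in candidates]

    log_x = np.log(rel.values)
    clr = log_x - log_x.mean(axis=1, keepdims=True)
    clr_c = clr - clr.mean(axis=0)
    # alr w.r.t. feature r is clr minus the r-th clr column (dropping it);
    # precompute the clr SVD once so each candidate costs one small SVD.
    clr_norm = np.linalg.norm(clr_c)
    u_c, s_c, _ = np.linalg.svd(clr_c, full_matrices=False)
    clr_scores = u_c * s_c  # n x r, same geometry as clr_c

    rows = []
    trait_constant = trait.std(ddof=1) == 0 if len(trait) > 1 else True
    for fid in cand_ids:
        j = rel.feature_index(fid)
        alr_c = (log_x - log_x[:, j][:, None]) - (log_x - log_x[:, j][:, None]).mean(axis=0)
        alr_c = np.delete(alr_c, j, axis=1)
        norm_a = np.linalg.norm(alr_c)
        if norm_a == 0 or clr_norm == 0:
            pcorr = np.nan
        else:
            # project the alr configuration into the clr row space: both
            # live in the n-sample space, so singular values of the
            # cross-product are computed on n x r matrices.
            u_a, s_a, _ = np.linalg.svd(alr_c, full_matrices=False)
            cross = (u_a * s_a).T @ clr_scores / (norm_a * clr_norm)
            pcorr = float(min(np.linalg.svd(cross, compute_uv=False).sum(), 1.0))

        lr = log_x[:, j]
        lr_var = float(lr.var(ddof=1))
        lr_mean = float(lr.mean())
        lr_cv = float(100.0 * lr.std(ddof=1) / abs(lr_mean)) if lr_mean != 0 else np.inf
        q1, med, q3 = np.percentile(lr, [25, 50, 75])
        r, se = (np.nan, np.nan) if trait_constant else _pearson_with_se(rel.values[:, j], trait)
        rows.append(
            {
                "feature_id": fid,
                "procrustes_corr": pcorr,
                "logrel_variance": lr_var,
                "logrel_cv_pct": lr_cv,
                "lr_min": float(lr.min()),
                "lr_q1": float(q1),
                "lr_median": float(med),
                "lr_q3": float(q3),
                "lr_max": float(lr.max()),
                "trait_corr": r,
                "trait_corr_se": se,
                "trait_constant": trait_constant,
                "mean_rel_abund": float(rel.values[:, j].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


@dataclass
class ReferenceSelection:
    """Outcome of the reference search: winner plus full audit trail."""

    reference_id: str
    report: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    def audit_json(self) -> str:
        passing = self.report[self.report["passes_filters"]]
        return json.dumps(
            {
                "reference_id": self.reference_id,
                "thresholds": self.thresholds,
                "n_candidates": int(len(self.report)),
                "n_passing": int(len(passing)),
                "ranking": passing.index.tolist(),
                "winner_metrics": {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in self.report.loc[self.reference_id]
                    .drop("passes_filters")
                    .drop("trait_constant")
                    .items()
                },
            },
            indent=2,
        )


def select_reference(
    report: pd.DataFrame,
    min_procrustes: float = 0.99,
    trait_corr_se_mult: float = 2.0,
) -> ReferenceSelection:
    """Pick the alr reference from a candidate report.

    Filters candidates to ``procrustes_corr >= min_procrustes`` and
    ``|trait_corr| <= trait_corr_se_mult * SE`` (the trait filter is waived
    when the trait was constant), then ranks survivors by ascending log
    relative-abundance variance with mean relative abundance (descending)
    as tie-break. Raises if no candidate survives.
    """
    if report.empty:
        raise ValueError("empty candidate report")
    rep = report.copy()
    ok_geom = rep["procrustes_corr"] >= min_procrustes
    if rep["trait_constant"].all():
        ok_trait = pd.Series(True, index=rep.index)
    else:
        ok_trait = rep["trait_corr"].abs() <= trait_corr_se_mult * rep["trait_corr_se"]
    rep["passes_filters"] = ok_geom & ok_trait
    survivors = rep[rep["passes_filters"]]
    if survivors.empty:
        raise ValueError(
            "no candidate passes the reference filters "
            f"(procrustes >= {min_procrustes}, |trait corr| <= "
            f"{trait_corr_se_mult}*SE); relax the thresholds or supply an "
            "explicit reference"
        )
    ranked = survivors.sort_values(
        ["logrel_variance", "mean_rel_abund"], ascending=[True, False]
    )
    rep = pd.concat([ranked, rep[~rep["passes_filters"]]])
    return ReferenceSelection(
        reference_id=str(ranked.index[0]),
        report=rep,
        thresholds={
            "min_procrustes": min_procrustes,
            "trait_corr_se_mult": trait_corr_se_mult,
        },
    )
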
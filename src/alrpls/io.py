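"""Formats, run configuration and the end-to-end pipeline.

Canonical exchange formats are plain text: counts and metadata as TSV
(samples as rows; first column = sample id), selection results and audit
trails as JSON, summary tables as TSV. A run is fully described by a
``RunConfig`` (loadable from YAML); ``run_pipeline`` executes the whole
chain — reference search, alr transform, DMOD screening, dual selection,
Bayesian line contrasts, body-fat overlap and cross-prediction — and
writes every artifact plus a machine-readable manifest that reproduces
the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import batch_contrasts
from .compositional import AbundanceTable, alr_transform, to_relative
from .overlap import cross_predict, partition_sets
from .selection import (
    SelectionSettings,
    run_dual_selection,
    select_features,
)
from .simulate import SimConfig, export_truth, generate_dataset
from .pls import assign_folds

logger = logging.getLogger("alrpls")

__all__ = [
    "RunConfig",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "run_pipeline",
]

METADATA_COLUMNS = ("line", "imf", "bodyfat_pct")


def read_abundance_tsv(path: str | Path, kind: str = "counts") -> AbundanceTable:
    """Read a samples x features TSV (first column = sample id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dup}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dup}")
    bad = frame.columns[~frame.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"non-numeric columns in {path}: {bad.tolist()}")
    return AbundanceTable.from_frame(frame, kind=kind)


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: sample_id, line (obese/lean), imf, bodyfat_pct."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata {path} lacks columns: {missing}")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    for col in ("imf", "bodyfat_pct"):
        if not pd.api.types.is_numeric_dtype(meta[col]):
            raise ValueError(f"metadata column {col} must be numeric")
    return meta


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def align_samples(table: AbundanceTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Check table and metadata describe the same samples; return metadata
    reindexed to the table's sample order."""
    t_ids = set(table.sample_ids)
    m_ids = set(map(str, metadata.index))
    extra_meta = sorted(m_ids - t_ids)
    extra_table = sorted(t_ids - m_ids)
    if extra_meta or extra_table:
        raise ValueError(
            "sample mismatch between table and metadata; "
            f"metadata-only: {extra_meta}; table-only: {extra_table}"
        )
    return metadata.loc[table.sample_ids]


def check_positive_for_alr(table: AbundanceTable) -> None:
    """Actionable error naming the first zero cell when alr is requested."""
    zeros = np.argwhere(table.values <= 0)
    if len(zeros):
        i, j = zeros[0]
        raise ValueError(
            f"zero abundance for feature {table.feature_ids[j]} in sample "
            f"{table.sample_ids[i]}: the alr transform needs strictly "
            "positive values (use a core table or a pseudocount upstream)"
        )


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "results/run"
    transform: str = "alr"  # "alr" | "relative"
    reference: str = "auto"
    seed: int = 0
    trait_column: str = "imf"
    second_trait_column: str = "bodyfat_pct"
    p0_thresholds: tuple[float, ...] = (0.90, 0.95)
    selection: SelectionSettings = field(default_factory=SelectionSettings)
    simulation: SimConfig | None = None

    def validate(self) -> None:
        s = self.selection
        if not (0 < s.vip_threshold):
            raise ValueError("vip_threshold must be positive")
        if not (0 < s.jackknife_level < 1):
            raise ValueError("jackknife_level must be in (0, 1)")
        if not (0 < s.batch_frac <= 1):
            raise ValueError("batch_frac must be in (0, 1]")
        if s.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.transform not in ("alr", "relative"):
            raise ValueError("transform must be 'alr' or 'relative'")
        for thr in self.p0_thresholds:
            if not (0.5 <= thr <= 1):
                raise ValueError("p0 thresholds must be in [0.5, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sel = SelectionSettings(**raw.pop("selection", {}))
        sim_raw = raw.pop("simulation", None)
        sim = None
        if sim_raw is not None:
            for key in ("line_effect_sd_range", "logsd_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimConfig(**sim_raw)
        if "p0_thresholds" in raw:
            raw["p0_thresholds"] = tuple(raw["p0_thresholds"])
        cfg = cls(selection=sel, simulation=sim, **raw)
        cfg.validate()
        return cfg

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_inputs(config: RunConfig) -> tuple[AbundanceTable, pd.DataFrame]:
    if config.counts_path is not None:
        counts = read_abundance_tsv(config.counts_path)
        metadata = align_samples(counts, read_metadata_tsv(config.metadata_path))
        return counts, metadata
    if config.simulation is None:
        raise ValueError("config needs counts/metadata paths or a simulation block")
    counts, metadata, truth = generate_dataset(config.simulation)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    export_truth(truth, out / "sim_truth.json")
    return counts, metadata


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full inference chain and write all artifacts.

    Returns a result bundle (also serialized under ``config.output_dir``):
    reference audit, both selection results, line contrasts on the
    intersection, body-fat selection, overlap partition and both
    cross-prediction verdicts, plus the run manifest.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        counts, metadata = _load_inputs(config)
        if config.transform == "alr":
            check_positive_for_alr(counts)
        logger.info(
            "inputs: %d samples x %d features", counts.n_samples, counts.n_features
        )

        dual = run_dual_selection(
            counts,
            metadata,
            transform=config.transform,
            reference=config.reference,
            settings=config.selection,
            seed=config.seed,
            trait_column=config.trait_column,
        )
        logger.info(
            "reference=%s outliers=%s line:%d features imf:%d features shared:%d",
            dual.reference_id, dual.outlier_ids,
            len(dual.line_result.final_features),
            len(dual.imf_result.final_features),
            len(dual.intersection),
        )

        # contrasts and the second-trait analysis reuse the screened samples
        keep = [s for s in counts.sample_ids if s not in set(dual.outlier_ids)]
        keep_idx = [counts.sample_ids.index(s) for s in keep]
        screened = AbundanceTable(
            counts.values[keep_idx], keep, list(counts.feature_ids), kind=counts.kind
        )
        meta_s = metadata.loc[keep]
        rel = to_relative(screened)
        if config.transform == "alr":
            x_frame = alr_transform(rel, dual.reference_id).to_frame()
        else:
            x_frame = rel.to_frame()

        lines = meta_s["line"].to_numpy()
        contrasts = None
        p0_counts: dict[float, int] = {thr: 0 for thr in config.p0_thresholds}
        if dual.intersection:
            if config.transform == "alr":
                alr_tab = alr_transform(rel, dual.reference_id)
            else:
                # contrasts are defined on log ratios; fall back to log
                # relative abundance when no reference exists
                alr_tab = None
            if alr_tab is not None:
                contrasts, p0_counts = batch_contrasts(
                    alr_tab, lines, features=dual.intersection,
                    p0_thresholds=config.p0_thresholds,
                )
                contrasts.to_csv(out / "line_contrasts.tsv", sep="\t")

        # second trait: PLS selection with the same folds, then overlap
        from .selection import _encode_labels  # shared coding

        fold_assign = assign_folds(
            len(meta_s), config.selection.folds, config.seed, _encode_labels(lines)
        )
        bf = meta_s[config.second_trait_column].to_numpy(dtype=float)
        bf_result = select_features(
            x_frame, bf, "regression", config.selection, seed=config.seed,
            transform=config.transform, fold_assign=fold_assign,
        )
        part = partition_sets(bf_result.final_features, dual.intersection)
        cross_bf_specific = cross_predict(
            x_frame, part.a_specific, meta_s[config.trait_column].to_numpy(dtype=float),
            folds=config.selection.folds, seed=config.seed,
            eps_comp=config.selection.eps_comp,
        )
        cross_imf_specific = cross_predict(
            x_frame, part.b_specific, bf,
            folds=config.selection.folds, seed=config.seed,
            eps_comp=config.selection.eps_comp,
        )

        bundle = {
            "manifest": config.to_manifest(),
            "reference_id": dual.reference_id,
            "outliers": dual.outlier_ids,
            "dmod_critical": dual.dmod_critical,
            "line_selection": dual.line_result.to_dict(),
            "imf_selection": dual.imf_result.to_dict(),
            "intersection": dual.intersection,
            "p0_counts": {str(k): v for k, v in p0_counts.items()},
            "bodyfat_selection": bf_result.to_dict(),
            "overlap": part.to_dict(),
            "cross_prediction": {
                "bodyfat_specific_to_imf": dataclasses.asdict(cross_bf_specific),
                "imf_specific_to_bodyfat": dataclasses.asdict(cross_imf_specific),
            },
        }
        (out / "run_bundle.json").write_text(json.dumps(bundle, indent=2))
        (out / "manifest.json").write_text(json.dumps(config.to_manifest(), indent=2))
        for name, res in (
            ("line_selection", dual.line_result),
            ("imf_selection", dual.imf_result),
            ("bodyfat_selection", bf_result),
        ):
            pd.DataFrame(
                [dataclasses.asdict(it) for it in res.iterations]
            ).to_csv(out / f"{name}_trace.tsv", sep="\t", index=False)
        if contrasts is not None:
            bundle["line_contrasts"] = contrasts
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()
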
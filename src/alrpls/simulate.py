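"""Synthetic compositional functional-metagenome datasets with ground truth.

The generator emulates the statistical structure of a shotgun functional
profile from a two-line divergent-selection design: a "core" gene table
(every feature present in every sample), heavy-tailed relative abundances
spanning ~4 orders of magnitude, a planted housekeeping-like feature whose
log relative abundance is near-constant across samples (the natural alr
reference), line effects planted on a subset of features in units of the
feature's log-abundance SD, and two continuous traits (intramuscular fat
and body-fat percentage) driven by overlapping subsets of true alr values
plus Gaussian noise. Counts are multinomial draws at a sample-specific
sequencing depth; any zero count is replaced by 1 (and logged) so the core
property holds by construction.

Desk-scale defaults (J = 500 features, depth 50,000) keep runtimes at
minutes while preserving the structure; the study-scale shape (~3,937
features, ~45 samples per line, depth in the millions) is reachable through
the same config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compositional import AbundanceTable

__all__ = ["SimConfig", "SimTruth", "generate_dataset", "export_truth", "read_truth"]


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Effects are expressed in units of the affected feature's log-abundance
    SD, mirroring how between-line differences are reported downstream.
    ``line_driver_overlap`` controls how many intramuscular-fat drivers are
    also line-affected (default: all that can be), emulating a trait whose
    microbial drivers respond to selection; set it to 0 for specificity
    experiments.
    """

    n_samples_per_group: int = 45
    n_features: int = 500
    n_line_affected: int = 30
    line_effect_sd_range: tuple[float, float] = (0.5, 1.0)
    n_imf_drivers: int = 30
    n_bodyfat_drivers: int = 30
    n_shared_drivers: int = 15
    line_driver_overlap: int | None = None
    trait_noise_sd: float = 0.5
    depth_mean: int = 50_000
    depth_min: int = 25_000
    stable_feature_cv: float = 0.01
    seed: int = 0

    # log-scale baseline shape: feature means ~ N(0, logmean_sd); at the
    # default the realized min-max span over hundreds of features is about
    # four orders of magnitude with the top feature near a few percent of
    # reads. Per-feature sample SDs are uniform on logsd_range.
    logmean_sd: float = 1.6
    logsd_range: tuple[float, float] = (0.3, 0.8)
    # None: place the reference-like feature at ~5.6x the mean feature
    # abundance (the ratio typical of a highly abundant ribosomal-protein
    # housekeeping gene), capped so it never dominates the composition
    stable_target_rel: float | None = None

    def resolved_stable_target_rel(self) -> float:
        if self.stable_target_rel is not None:
            return self.stable_target_rel
        return min(5.6 / self.n_features, 0.05)

    def validate(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_features < 10:
            raise ValueError("need at least 10 features")
        if not (0 <= self.n_line_affected <= self.n_features):
            raise ValueError("n_line_affected must be in [0, n_features]")
        if self.depth_mean <= 0 or self.depth_min <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.depth_min > self.depth_mean:
            raise ValueError("depth_min must not exceed depth_mean")
        if self.n_shared_drivers > min(self.n_imf_drivers, self.n_bodyfat_drivers):
            raise ValueError("n_shared_drivers exceeds a driver set size")
        # planted sets live among non-reference features
        needed = self.n_line_affected
        n_trait = self.n_imf_drivers + self.n_bodyfat_drivers - self.n_shared_drivers
        if max(needed, n_trait) > self.n_features - 1:
            raise ValueError("planted sets do not fit among the features")
        if self.line_effect_sd_range[0] < 0 or (
            self.line_effect_sd_range[0] > self.line_effect_sd_range[1]
        ):
            raise ValueError("line_effect_sd_range must be 0 <= lo <= hi")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be >= 0")
        if self.stable_feature_cv <= 0:
            raise ValueError("stable_feature_cv must be positive")


@dataclass
class SimTruth:
    """Ground truth of the planted structure, for recovery testing."""

    line_affected: dict[str, float]  # feature id -> signed effect (SD units)
    imf_drivers: dict[str, float]  # feature id -> weight on its true alr
    bodyfat_drivers: dict[str, float]
    stable_feature_id: str
    n_zero_replaced: int = 0

    def validate_against(self, table: AbundanceTable) -> None:
        ids = set(table.feature_ids)
        listed = (
            set(self.line_affected)
            | set(self.imf_drivers)
            | set(self.bodyfat_drivers)
            | {self.stable_feature_id}
        )
        missing = listed - ids
        if missing:
            raise ValueError(f"truth lists unknown features: {sorted(missing)}")


def _draw_depths(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    # mean ~ depth_mean with spread such that the floor depth_min is the
    # observed minimum rather than a hard truncation wall
    sd = max((cfg.depth_mean - cfg.depth_min) / 2.0, 1.0)
    depths = rng.normal(cfg.depth_mean, sd, size=n).round().astype(int)
    return np.maximum(depths, cfg.depth_min)


def generate_dataset(
    config: SimConfig,
) -> tuple[AbundanceTable, pd.DataFrame, SimTruth]:
    """Generate (count table, sample metadata, ground truth).

    Deterministic given ``config.seed``. Metadata columns: ``sample_id``
    (index), ``line`` (obese/lean), ``imf`` (intramuscular fat, g/100 g)
    and ``bodyfat_pct``. Traits are linear combinations of the true alr
    values (w.r.t. the planted stable feature) of their driver features,
    standardized to unit signal SD, plus N(0, trait_noise_sd^2) noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_per = config.n_samples_per_group
    n = 2 * n_per
    j = config.n_features

    feature_ids = [f"MG{k:04d}" for k in range(j)]
    sample_ids = [f"S{k:03d}" for k in range(n)]
    line = np.array(["obese"] * n_per + ["lean"] * n_per)

    # the stable reference-like feature is handled separately; planted sets
    # are drawn from the remaining features
    stable_idx = int(rng.integers(j))
    others = np.setdiff1d(np.arange(j), [stable_idx])
    perm = rng.permutation(others)

    line_idx = perm[: config.n_line_affected]
    overlap = (
        min(config.n_line_affected, config.n_imf_drivers)
        if config.line_driver_overlap is None
        else config.line_driver_overlap
    )
    overlap = min(overlap, config.n_line_affected, config.n_imf_drivers)
    imf_idx = np.concatenate(
        [line_idx[:overlap], perm[config.n_line_affected :][: config.n_imf_drivers - overlap]]
    )
    pool_after = perm[config.n_line_affected + config.n_imf_drivers - overlap :]
    shared_idx = imf_idx[rng.permutation(len(imf_idx))[: config.n_shared_drivers]]
    bf_extra = pool_after[: config.n_bodyfat_drivers - config.n_shared_drivers]
    bodyfat_idx = np.concatenate([shared_idx, bf_extra])

    # baseline log abundances: feature-specific means and SDs
    mu = rng.normal(0.0, config.logmean_sd, size=j)
    tau = rng.uniform(*config.logsd_range, size=j)
    z = mu[None, :] + rng.normal(0.0, 1.0, size=(n, j)) * tau[None, :]

    # planted line effects, applied to the obese group with random sign.
    # Effects are stated in the reporting convention: units of the
    # feature's *observed* overall log-abundance SD. The latent shift
    # therefore (a) converts overall-SD to within-group-SD units (the
    # group separation inflates the overall SD) and (b) budgets the
    # multinomial counting noise, which dominates the observed SD for
    # rare features.
    lo, hi = config.line_effect_sd_range
    effect_sd = rng.uniform(lo, hi, size=len(line_idx)) * rng.choice(
        [-1.0, 1.0], size=len(line_idx)
    )
    mean_rel = np.exp(mu + tau**2 / 2)
    mean_rel /= mean_rel.sum()
    count_var = 1.0 / (mean_rel * config.depth_mean)
    sd_within = np.sqrt(tau[line_idx] ** 2 + count_var[line_idx])
    d_within = effect_sd / np.sqrt(1.0 - np.minimum(effect_sd**2, 2.0) / 4.0)
    z[:n_per, line_idx] += d_within * sd_within

    # stable feature: a constant log-abundance level placed so its mean
    # relative abundance hits the target. Holding the *level* constant
    # (rather than tracking each sample's realized total) keeps every log
    # ratio against it free of a shared log-total term, the way a
    # housekeeping gene scales with biomass; its observed relative
    # abundance then varies only with the (small) total fluctuation.
    log_other_total = np.log(np.exp(z[:, others]).sum(axis=1))
    target_rel = config.resolved_stable_target_rel()
    kappa = target_rel / (1.0 - target_rel)
    log_rel_target = np.log(target_rel)
    # the target CV is for the *observed* log relative abundance, which
    # also carries multinomial counting noise (var ~ 1/(p * depth)) and
    # the log-total fluctuation; budget for both so the empirical CV
    # lands near target
    target_var = (config.stable_feature_cv * abs(log_rel_target)) ** 2
    count_var = 1.0 / (target_rel * config.depth_mean)
    total_var = float(log_other_total.var(ddof=1))
    noise_sd = np.sqrt(max(target_var - count_var - total_var, 0.05 * target_var))
    z[:, stable_idx] = (
        np.log(kappa) + log_other_total.mean() + rng.normal(0.0, noise_sd, size=n)
    )

    # traits from true alr values w.r.t. the stable feature
    alr_true = z - z[:, stable_idx][:, None]

    effect_by_idx = dict(zip(line_idx, effect_sd))

    def _trait(driver_idx: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
        # weights act on SD-standardized driver alrs so every driver gets
        # its nominal effect size regardless of the feature's own log SD
        # (mirroring line effects, which are planted in per-feature SD
        # units). For drivers that also carry a line effect the weight sign
        # follows the effect sign: under divergent selection a feature
        # responds to the line *because* it pushes the trait, so feature
        # and trait move together (a correlated response); drivers outside
        # the line-affected set get random signs.
        wts = rng.uniform(0.5, 1.0, size=len(driver_idx))
        signs = np.array(
            [
                np.sign(effect_by_idx[k]) if k in effect_by_idx else rng.choice([-1.0, 1.0])
                for k in driver_idx
            ]
        )
        wts = wts * signs
        drv = alr_true[:, driver_idx]
        drv = (drv - drv.mean(axis=0)) / drv.std(axis=0, ddof=1)
        signal = drv @ wts
        ssd = signal.std(ddof=1)
        if ssd > 0:
            signal = signal / ssd
            wts = wts / ssd
        noisy = signal + rng.normal(0.0, config.trait_noise_sd, size=n)
        weights = {feature_ids[k]: float(w) for k, w in zip(driver_idx, wts)}
        return noisy, weights

    imf_std, imf_weights = _trait(imf_idx)
    bf_std, bf_weights = _trait(bodyfat_idx)
    # realistic measurement scales: IMF ~ 1.5 +- 0.4 g/100 g muscle,
    # body fat ~ 12 +- 2.5 % for 9-week rabbits
    imf = 1.5 + 0.4 * imf_std
    bodyfat = 12.0 + 2.5 * bf_std

    # multinomial counts at sample-specific depth; zeros replaced by 1 to
    # keep the core property
    depths = _draw_depths(rng, config, n)
    probs = np.exp(z - z.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((n, j), dtype=float)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])
    n_zero = int((counts == 0).sum())
    counts[counts == 0] = 1.0

    table = AbundanceTable(
        values=counts, sample_ids=sample_ids, feature_ids=feature_ids, kind="counts"
    )
    metadata = pd.DataFrame(
        {"line": line, "imf": imf, "bodyfat_pct": bodyfat},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SimTruth(
        line_affected={
            feature_ids[k]: float(e) for k, e in zip(line_idx, effect_sd)
        },
        imf_drivers=imf_weights,
        bodyfat_drivers=bf_weights,
        stable_feature_id=feature_ids[stable_idx],
        n_zero_replaced=n_zero,
    )
    truth.validate_against(table)
    return table, metadata, truth


def export_truth(truth: SimTruth, path: str | Path) -> None:
    """Write the ground truth as JSON (lossless round-trip)."""
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2))


def read_truth(path: str | Path) -> SimTruth:
    return SimTruth(**json.loads(Path(path).read_text()))
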
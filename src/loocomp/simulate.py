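"""Synthetic paired longitudinal microbiome cohorts with known ground truth.

The generator emulates the statistical structure of a small bariatric-
surgery cohort: 13 subjects sampled at baseline, 12 at 3 months and 8 at
1 year; compositional relative abundances with an unannotated fraction; a
bimodally distributed dominant taxon (Prevotella-like: high in some
subjects, near-absent in others); and persistent multiplicative "spike"
effects on a subset of taxa from 3 months onward.

Absolute abundances are log-normal with additive subject random effects:

    A_ijt = exp(mu_j + b_i + e_ijt) * delta_j ** [t affected]

with b_i ~ N(0, subject_effect_sd^2) and e_ijt ~ N(0, noise_sd^2).
Closure is applied either exactly (read_depth = 0 reports proportions) or
by a per-sample multinomial draw of ``read_depth`` reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import (
    AbundanceTable,
    FeatureGroupMap,
    SampleMetadata,
    TIMEPOINT_MONTHS,
    TIMEPOINTS,
    ValidationError,
    aggregate,
)

__all__ = [
    "SimulationConfig",
    "CovariateTrend",
    "GroundTruth",
    "simulate_cohort",
    "simulate_functional_profiles",
    "simulate_clinical",
    "default_trend_specs",
    "concat_timepoints",
]

CONTRASTS = (("baseline", "3MO"), ("baseline", "1Y"), ("3MO", "1Y"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults mirror the emulated study: 13/12/8 subjects over the three
    time points, 100 taxa, ~20% unannotated read mass, and a bimodal
    dominant taxon present at high abundance in roughly a third of
    subjects.
    """

    n_subjects: int = 13
    dropout: tuple[int, int, int] = (13, 12, 8)  # baseline / 3MO / 1Y
    n_taxa: int = 100
    taxon_log_mean_sd: float = 2.0  # spread of per-taxon locations mu_j
    subject_effect_sd: float = 0.5  # between-subject log-scale sd
    noise_sd: float = 0.3  # within-subject log-scale sd
    spike_taxa: tuple[str, ...] = ()
    spike_delta: float = 4.0
    spike_persistent: bool = True  # effect from 3MO onward; else 3MO only
    bimodal_taxon: str | None = "taxon_000"
    bimodal_high_fraction: float = 0.3
    bimodal_high_shift: float = 4.0  # natural-log boost for high-mode subjects
    read_depth: int = 0  # 0 = report exact proportions
    unannotated_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_delta <= 0:
            raise ValidationError("spike effect delta must be > 0")
        for name in ("taxon_log_mean_sd", "subject_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.unannotated_fraction < 1):
            raise ValidationError("unannotated_fraction must lie in [0, 1)")
        n_b, n_3, n_1 = self.dropout
        if not (self.n_subjects >= n_b >= n_3 >= n_1 >= 1):
            raise ValidationError(
                "dropout must be nested: n_subjects >= baseline >= 3MO >= 1Y >= 1"
            )
        unknown = set(self.spike_taxa) - set(self.taxon_ids)
        if unknown:
            raise ValidationError(f"spike taxa not simulated: {sorted(unknown)}")
        if self.bimodal_taxon is not None and self.bimodal_taxon not in self.taxon_ids:
            raise ValidationError(f"bimodal taxon {self.bimodal_taxon!r} not simulated")

    @property
    def taxon_ids(self) -> list[str]:
        return [f"taxon_{i:03d}" for i in range(self.n_taxa)]

    @property
    def subject_ids(self) -> list[str]:
        return [f"subj_{i:02d}" for i in range(1, self.n_subjects + 1)]


@dataclass(frozen=True)
class CovariateTrend:
    """Piecewise-linear clinical trajectory: slopes per month for months
    0-3 and 3-12, around a subject-specific baseline."""

    baseline_mean: float
    slope_0_3: float
    slope_3_12: float
    baseline_sd: float = 0.0
    noise_sd: float = 0.0


@dataclass
class GroundTruth:
    """True per-taxon effects and pre-closure absolute abundances."""

    effects: pd.DataFrame  # taxa x contrast labels, multiplicative effect
    absolute: dict[str, pd.DataFrame]  # timepoint -> samples x taxa
    spiked: tuple[str, ...]

    def effect(self, taxon: str, contrast: str) -> float:
        return float(self.effects.loc[taxon, contrast])


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, AbundanceTable], SampleMetadata, GroundTruth]:
    """Draw one synthetic cohort.

    Returns a raw abundance table per time point, sample metadata, and the
    ground truth (true multiplicative effect per contrast; non-spiked taxa
    have effect exactly 1).  Bit-reproducible for a given config seed.
    """
    rng_mu, rng_subj, rng_noise, rng_bimodal, rng_drop, rng_counts = _substreams(
        config.seed, 6
    )
    taxa = config.taxon_ids
    subjects = config.subject_ids
    n_t = config.n_taxa

    mu = rng_mu.normal(0.0, config.taxon_log_mean_sd, size=n_t)
    b = rng_subj.normal(0.0, config.subject_effect_sd, size=config.n_subjects)

    # bimodal dominant taxon: high mode in a fixed subject subset
    if config.bimodal_taxon is not None:
        j_bi = taxa.index(config.bimodal_taxon)
        high = rng_bimodal.random(config.n_subjects) < config.bimodal_high_fraction
    else:
        j_bi, high = None, None

    # nested missing-at-random dropout
    n_b, n_3, n_1 = config.dropout
    at_baseline = sorted(rng_drop.choice(config.n_subjects, n_b, replace=False))
    at_3mo = sorted(rng_drop.choice(at_baseline, n_3, replace=False))
    at_1y = sorted(rng_drop.choice(at_3mo, n_1, replace=False))
    present = {"baseline": at_baseline, "3MO": at_3mo, "1Y": at_1y}

    delta = np.ones(n_t)
    spike_idx = [taxa.index(t) for t in config.spike_taxa]
    delta[spike_idx] = config.spike_delta
    affected = {
        "baseline": np.zeros(n_t),
        "3MO": np.where(np.isin(np.arange(n_t), spike_idx), 1.0, 0.0),
        "1Y": np.where(np.isin(np.arange(n_t), spike_idx), 1.0, 0.0)
        if config.spike_persistent
        else np.zeros(n_t),
    }

    tables: dict[str, AbundanceTable] = {}
    absolute: dict[str, pd.DataFrame] = {}
    meta_rows = []
    f = config.unannotated_fraction
    for tp in TIMEPOINTS:
        rows, sample_ids = [], []
        for i in present[tp]:
            eps = rng_noise.normal(0.0, config.noise_sd, size=n_t)
            log_a = mu + b[i] + eps
            if j_bi is not None and high[i]:
                log_a[j_bi] += config.bimodal_high_shift
            a = np.exp(log_a) * delta ** affected[tp]
            rows.append(a)
            sid = f"{subjects[i]}_{tp}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "subject_id": subjects[i], "timepoint": tp}
            )
        a_mat = np.array(rows)
        abs_df = pd.DataFrame(a_mat, index=sample_ids, columns=taxa)
        absolute[tp] = abs_df
        totals = a_mat.sum(axis=1)
        unannot = totals * f / (1.0 - f)  # feature share is exactly 1 - f
        if config.read_depth > 0:
            p = np.column_stack([a_mat, unannot])
            p = p / p.sum(axis=1, keepdims=True)
            counts = np.array(
                [rng_counts.multinomial(config.read_depth, pi) for pi in p]
            )
            table = AbundanceTable(
                pd.DataFrame(counts[:, :-1], index=sample_ids, columns=taxa),
                pd.Series(counts[:, -1].astype(float), index=sample_ids),
                "raw",
            )
        else:
            table = AbundanceTable(
                abs_df.copy(), pd.Series(unannot, index=sample_ids), "raw"
            )
        tables[tp] = table

    effects = pd.DataFrame(1.0, index=taxa, columns=[f"{a}->{b_}" for a, b_ in CONTRASTS])
    for t1, t2 in CONTRASTS:
        ratio = delta ** (affected[t2] - affected[t1])
        effects[f"{t1}->{t2}"] = ratio
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    truth = GroundTruth(effects=effects, absolute=absolute, spiked=config.spike_taxa)
    return tables, metadata, truth


def concat_timepoints(tables: dict[str, AbundanceTable]) -> AbundanceTable:
    """Stack the per-time-point tables into one table over all samples."""
    frames = [tables[tp].data for tp in TIMEPOINTS if tp in tables]
    unannot = [tables[tp].unannotated for tp in TIMEPOINTS if tp in tables]
    kinds = {tables[tp].kind for tp in tables}
    if len(kinds) != 1:
        raise ValidationError("cannot concatenate tables of mixed kind")
    return AbundanceTable(pd.concat(frames), pd.concat(unannot), kinds.pop())


def simulate_functional_profiles(
    taxa_table: AbundanceTable,
    ko_per_taxon: dict[str, dict[str, float]],
    group_map: FeatureGroupMap | None = None,
) -> AbundanceTable:
    """Gene-family (KO) profiles as copy-weighted sums over taxa.

    Each taxon carries a fixed KO repertoire with per-KO copy weights;
    KO abundance = sum over taxa of (taxon abundance x copy weight).
    Module/pathway abundances follow by :func:`~loocomp.profiles.aggregate`
    with ``group_map``.
    """
    if not ko_per_taxon or all(len(v) == 0 for v in ko_per_taxon.values()):
        raise ValidationError("empty KO repertoire")
    kos = sorted({ko for rep in ko_per_taxon.values() for ko in rep})
    weights = pd.DataFrame(0.0, index=taxa_table.feature_ids, columns=kos)
    for taxon, rep in ko_per_taxon.items():
        if taxon not in weights.index:
            raise ValidationError(f"repertoire references unknown taxon {taxon!r}")
        for ko, w in rep.items():
            weights.loc[taxon, ko] = w
    ko_data = taxa_table.data @ weights
    ko_table = AbundanceTable(ko_data, taxa_table.unannotated.copy(), "raw")
    if group_map is not None:
        return aggregate(ko_table, group_map)
    return ko_table


def default_trend_specs() -> dict[str, CovariateTrend]:
    """Clinical trajectories of a cohort improving after bariatric surgery.

    BMI (kg/m^2) and fasting glucose (mmol/L) fall steeply in the first 3
    months and slowly thereafter; postprandial GLP-1 AUC (pmol/L x min)
    rises on the same schedule.
    """
    return {
        "bmi": CovariateTrend(42.0, -3.0, -0.25, baseline_sd=4.0, noise_sd=0.5),
        "fasting_glucose": CovariateTrend(7.5, -0.5, -0.02, baseline_sd=1.2, noise_sd=0.3),
        "glp1_auc": CovariateTrend(2000.0, 500.0, 20.0, baseline_sd=300.0, noise_sd=100.0),
    }


def simulate_clinical(
    metadata: SampleMetadata,
    trend_specs: dict[str, CovariateTrend] | None = None,
    seed: int = 0,
) -> SampleMetadata:
    """Attach piecewise-linear clinical covariates to the metadata.

    covariate_i(t) = baseline_i + slope_0_3 * min(t, 3)
                     + slope_3_12 * max(t - 3, 0) + noise.
    """
    if trend_specs is None:
        trend_specs = default_trend_specs()
    reserved = {"sample_id", "subject_id", "timepoint"}
    bad = reserved & set(trend_specs)
    if bad:
        raise ValidationError(f"covariate names collide with metadata: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    frame = metadata.frame.copy()
    subjects = sorted(frame["subject_id"].unique())
    months = frame["timepoint"].map(TIMEPOINT_MONTHS).to_numpy(dtype=float)
    for name, spec in trend_specs.items():
        base = {
            s: spec.baseline_mean + rng.normal(0.0, spec.baseline_sd)
            if spec.baseline_sd > 0
            else spec.baseline_mean
            for s in subjects
        }
        values = (
            frame["subject_id"].map(base).to_numpy()
            + spec.slope_0_3 * np.minimum(months, 3.0)
            + spec.slope_3_12 * np.maximum(months - 3.0, 0.0)
        )
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=len(frame))
        frame[name] = values
    return SampleMetadata(frame)
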
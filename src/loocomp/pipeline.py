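"""End-to-end orchestration: simulate/load -> filter -> test -> report.

A single :class:`RunConfig` drives the full analysis: relative-abundance
transform, feature filtering, diversity summaries, the paired differential
contrasts, the leave-one-out compositionality test on the significant
features, and the community-level PCA and PERMANOVA screen.  Every output
is a TSV; a JSON manifest records parameters, seed and per-stage counts,
and two runs with identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community import canberra_matrix, log10_transform, pca, permanova_screen
from .compositionality import loo_test, reports_to_frames
from .differential import run_contrast
from .diversity import diversity_summary
from .profiles import (
    AbundanceTable,
    FoldChangeSpec,
    SampleMetadata,
    TIMEPOINTS,
    ValidationError,
    filter_features,
    read_abundance_table,
    read_metadata,
    to_relative,
    write_abundance_table,
    write_metadata,
)
from .simulate import (
    SimulationConfig,
    concat_timepoints,
    simulate_clinical,
    simulate_cohort,
)

__all__ = ["RunConfig", "run_all", "load_config"]

log = logging.getLogger("loocomp")

DEFAULT_CONTRASTS = (("baseline", "3MO"), ("baseline", "1Y"), ("3MO", "1Y"))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (from YAML/JSON or constructed)."""

    outdir: str = "loocomp_run"
    table_path: str | None = None  # user data; None -> simulate
    metadata_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    alpha: float = 0.05
    min_prevalence: float = 0.10
    min_mean_abund: float = 0.01  # taxa-level default; 0.001 for functional units
    permanova_covariates: tuple[str, ...] = ()
    n_perm: int = 10000
    seed: int = 0

    def validate_against(self, metadata: SampleMetadata) -> None:
        present = set(metadata.frame["timepoint"])
        for t1, t2 in self.contrasts:
            if t1 not in present or t2 not in present:
                raise ValidationError(
                    f"contrast {t1}->{t2} references a timepoint absent "
                    f"from the metadata ({sorted(present)})"
                )


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("simulation", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "contrasts"})
    if "contrasts" in raw:
        cfg.contrasts = tuple(tuple(c) for c in raw["contrasts"])
    if sim is not None:
        if "dropout" in sim:
            sim["dropout"] = tuple(sim["dropout"])
        if "spike_taxa" in sim:
            sim["spike_taxa"] = tuple(sim["spike_taxa"])
        cfg.simulation = SimulationConfig(**sim)
    return cfg


def _load_or_simulate(config: RunConfig) -> tuple[AbundanceTable, SampleMetadata]:
    if config.table_path is not None:
        metadata = read_metadata(config.metadata_path)
        table = read_abundance_table(config.table_path, metadata=metadata)
        return table, metadata
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    tables, metadata, _ = simulate_cohort(sim)
    metadata = simulate_clinical(metadata, seed=config.seed)
    return concat_timepoints(tables), metadata


def run_all(config: RunConfig) -> dict:
    """Execute every stage in fixed order and write the outputs.

    Stage order: load/simulate -> to_relative -> filter -> diversity ->
    per-contrast differential -> compositionality on significant features
    -> PCA + PERMANOVA.  Any stage error aborts with the stage name; a
    FAILED marker file is left next to any partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "min_prevalence": config.min_prevalence,
        "min_mean_abund": config.min_mean_abund,
        "n_perm": config.n_perm,
        "contrasts": ["->".join(c) for c in config.contrasts],
        "stages": {},
    }
    stage = "configure"
    try:
        stage = "load"
        table, metadata = _load_or_simulate(config)
        config.validate_against(metadata)
        write_metadata(metadata, outdir / "metadata.tsv")
        manifest["stages"]["load"] = {
            "n_samples": table.n_samples,
            "n_features": table.n_features,
        }
        log.info("loaded %d samples x %d features", table.n_samples, table.n_features)

        stage = "to_relative"
        rel = to_relative(table)
        write_abundance_table(rel, outdir / "relative.tsv")

        stage = "filter"
        filtered = filter_features(
            rel, config.min_prevalence, config.min_mean_abund
        )
        manifest["stages"]["filter"] = {
            "n_features_in": rel.n_features,
            "n_features_kept": filtered.n_features,
        }
        log.info(
            "filtering kept %d of %d features", filtered.n_features, rel.n_features
        )
        spec = FoldChangeSpec.from_table(rel)
        manifest["pseudo_count"] = spec.pseudo_count

        stage = "diversity"
        div = diversity_summary(rel)
        div.to_csv(outdir / "diversity.tsv", sep="\t")
        manifest["stages"]["diversity"] = {"n_samples": len(div)}

        diff_results = {}
        for t1, t2 in config.contrasts:
            label = f"{t1}->{t2}"
            fname = f"{t1}_{t2}"
            stage = f"differential[{label}]"
            res = run_contrast(filtered, metadata, t1, t2, spec, config.alpha)
            res.to_csv(outdir / f"diff_{fname}.tsv", sep="\t", index=False)
            diff_results[label] = res
            n_sig = int(res["significant"].sum())
            manifest["stages"][stage] = {
                "n_features": len(res),
                "n_significant": n_sig,
                "n_pairs": int(res["n_pairs"].iloc[0]) if len(res) else 0,
            }
            log.info("%s: %d/%d features significant", label, n_sig, len(res))

            stage = f"compositionality[{label}]"
            focal = res.loc[res["significant"], "feature_id"].tolist()
            reports = loo_test(
                filtered, metadata, t1, t2, focal, spec, config.alpha
            )
            long_df, summary_df = reports_to_frames(reports)
            long_df.to_csv(outdir / f"compo_{fname}.tsv", sep="\t", index=False)
            summary_df.to_csv(
                outdir / f"compo_{fname}_summary.tsv", sep="\t", index=False
            )
            manifest["stages"][stage] = {
                "n_focal": len(reports),
                "n_robust": int(sum(r.robust for r in reports)),
            }

        stage = "pca"
        ord_res = pca(log10_transform(rel, spec.pseudo_count))
        coords = ord_res.coordinates.copy()
        coords.index.name = "sample_id"
        coords.to_csv(outdir / "pca.tsv", sep="\t")
        manifest["stages"]["pca"] = {
            "explained_variance_ratio": [
                round(float(v), 6) for v in ord_res.explained_variance_ratio[:5]
            ]
        }

        stage = "permanova"
        meta = metadata.frame.copy()
        if "surgery" not in meta.columns:
            meta["surgery"] = (meta["timepoint"] != "baseline").map(
                {True: "after", False: "before"}
            )
        metadata_aug = SampleMetadata(meta)
        covariates = list(config.permanova_covariates) or (
            ["surgery"] + metadata.covariate_names
        )
        dist = canberra_matrix(rel)
        perm = permanova_screen(
            dist, metadata_aug, covariates, n_perm=config.n_perm, seed=config.seed
        )
        perm.to_csv(outdir / "permanova.tsv", sep="\t", index=False)
        manifest["stages"]["permanova"] = {"n_covariates": len(perm)}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
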
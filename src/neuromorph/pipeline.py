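"""End-to-end experiment driver.

Mirrors the study design: several biological replicates per condition, a
batch of acquisitions per replicate, per-acquisition morphometry, then
one-way ANOVA with post-hoc comparisons per metric. Works either on
simulated cohorts (with ground truth) or on a directory of acquisitions
listed in a manifest CSV. Fully reproducible under a master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .image import Acquisition, load_image
from .masking import MaskingParams
from .skeleton import measure_acquisition
from .stats import anova_multicompare
from .synthetic import GeneratorParams, generate_cohort

FIGURE_METRICS = [
    "n_somata",
    "n_branches",
    "n_junctions",
    "total_branch_length_um",
    "avg_branch_length_um",
]


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Simulation-or-measurement study configuration.

    ``groups`` maps group name to generator-parameter overrides (relative to
    :class:`GeneratorParams` defaults). ``input_dir`` switches to measuring
    on-disk acquisitions via their manifest instead of simulating.
    """

    groups: dict = dc_field(
        default_factory=lambda: {"WT": {}, "KO": {"branching_prob": 0.175}}
    )
    n_images_per_replicate: int = 10
    n_replicates: int = 3
    master_seed: int = 0
    masking: dict = dc_field(default_factory=dict)
    posthoc: str = "tukey"
    metrics: list = dc_field(default_factory=lambda: list(FIGURE_METRICS))
    input_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def generator_params(self) -> dict[str, GeneratorParams]:
        return {name: GeneratorParams(**ov) for name, ov in self.groups.items()}

    def masking_params(self) -> MaskingParams:
        return MaskingParams(**self.masking)


@dataclass
class ExperimentReport:
    metrics: pd.DataFrame
    report: dict

    def to_json(self) -> str:
        return json.dumps(self.report, indent=1, sort_keys=True)


def measure_cohort(
    acquisitions: list[Acquisition], params: MaskingParams
) -> pd.DataFrame:
    records = [measure_acquisition(a, params) for a in acquisitions]
    return pd.DataFrame([r.as_dict() for r in records])


def load_manifest(input_dir: str | Path) -> list[Acquisition]:
    """Acquisitions from a directory holding ``manifest.csv`` + TIFF pairs."""
    input_dir = Path(input_dir)
    manifest = input_dir / "manifest.csv"
    if not manifest.exists():
        raise ConfigError(f"missing manifest: {manifest}")
    table = pd.read_csv(manifest)
    missing = [
        str(input_dir / row[col])
        for _, row in table.iterrows()
        for col in ("dapi_path", "map2_path")
        if not (input_dir / row[col]).exists()
    ]
    if missing:
        raise ConfigError(f"manifest references absent files: {missing}")
    acqs = []
    for _, row in table.iterrows():
        px = float(row["pixel_size_um"])
        acqs.append(
            Acquisition(
                dapi=load_image(input_dir / row["dapi_path"], px),
                map2=load_image(input_dir / row["map2_path"], px),
                pixel_size_um=px,
                image_id=str(row["image_id"]),
                group=str(row["group"]),
                replicate=int(row["replicate"]),
            )
        )
    return acqs


def report_from_metrics(metrics: pd.DataFrame, config: ExperimentConfig) -> dict:
    """Statistical report from a metrics table; pure, hence bit-reproducible."""
    comparisons = {}
    for metric in config.metrics:
        try:
            comparisons[metric] = anova_multicompare(
                metrics, metric, posthoc=config.posthoc
            ).as_dict()
        except ValueError as exc:  # e.g. a constant metric such as exact soma counts
            comparisons[metric] = {"metric": metric, "error": str(exc)}
    return {
        "software": {"name": "neuromorph", "version": __version__},
        "config": dataclasses.asdict(config),
        "n_acquisitions": int(len(metrics)),
        "comparisons": comparisons,
    }


def run_experiment(
    config: ExperimentConfig,
    metrics_csv: str | Path | None = None,
    report_json: str | Path | None = None,
    plots_dir: str | Path | None = None,
) -> ExperimentReport:
    """Simulate (or load) acquisitions, measure them, and compare groups."""
    n_per_group = config.n_images_per_replicate * config.n_replicates
    if config.input_dir is None and n_per_group < 2:
        raise ConfigError(
            f"each group would have {n_per_group} acquisition(s); "
            "group comparison requires at least 2"
        )
    if config.input_dir is not None:
        acqs = load_manifest(config.input_dir)
        counts = pd.Series([a.group for a in acqs]).value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ConfigError(f"groups with fewer than 2 acquisitions: {bad}")
    else:
        items = generate_cohort(
            config.generator_params(),
            config.n_images_per_replicate,
            config.n_replicates,
            config.master_seed,
        )
        acqs = [it.acquisition for it in items]
    metrics = measure_cohort(acqs, config.masking_params())
    report = report_from_metrics(metrics, config)
    out = ExperimentReport(metrics=metrics, report=report)
    if metrics_csv is not None:
        metrics.to_csv(metrics_csv, index=False)
    if report_json is not None:
        Path(report_json).write_text(out.to_json())
    if plots_dir is not None:
        save_boxplots(metrics, config.metrics, plots_dir)
    return out


def save_boxplots(metrics: pd.DataFrame, metric_names: list[str],
                  plots_dir: str | Path) -> list[Path]:
    """Per-metric boxplots in the figures' convention (median line, IQR box,
    outlier dots)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots_dir = Path(plots_dir)
    plots_dir.mkdir(parents=True, exist_ok=True)
    written = []
    groups = list(dict.fromkeys(metrics["group"]))
    for metric in metric_names:
        fig, ax = plt.subplots(figsize=(3.2, 3.6))
        data = [metrics.loc[metrics["group"] == g, metric] for g in groups]
        ax.boxplot(
            data,
            tick_labels=groups,
            whis=1.5,
            flierprops={"marker": "o", "markerfacecolor": "black", "markersize": 3},
            medianprops={"color": "black"},
        )
        ax.set_ylabel(metric)
        fig.tight_layout()
        path = plots_dir / f"{metric}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
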
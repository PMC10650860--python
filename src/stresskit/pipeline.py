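"""End-to-end report pipeline.

Drives the whole analysis from one config: a trial CSV or a named
simulation preset in, a bundle of CSV tables and a Markdown report out
(per-stress index tables, correlation panels, PCA summaries, labelled
clusters, cluster trait profiles, ANOVA and heritability summaries).

Every output file carries the seed and a config hash in a ``#`` header
comment; reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .data_model import (
    TREATMENT_CLASS,
    IndexTable,
    TrialTable,
    ValidationError,
    YieldPairTable,
    pair_yields,
    write_table,
)
from .inference import broad_sense_heritability, pearson_matrix, percent_change, two_way_anova
from .classification import (
    cluster_profile,
    dendrogram_newick,
    label_clusters,
    pca_indices,
    standardize,
    ward_cluster,
)
from .stress_indices import compute_indices
from .synthetic import PRESETS, TrialSimConfig, get_preset, simulate_trial, simulate_yield_pairs

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Inconsistent pipeline configuration, raised before any computation."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one of ``trial_csv`` or ``preset`` names the input.  For a
    trial input, each stress environment is paired with ``normal_env``
    on ``pair_trait``; stress environments absent from the data are
    skipped with a logged notice.
    """

    outdir: str = "stresskit_report"
    trial_csv: str | None = None
    preset: str | None = None
    normal_env: str = "N2"
    stress_envs: tuple[str, ...] = ("SI", "SNI")
    pair_trait: str = "GY"
    k: int = 4
    seed: int = 0
    dry_run: bool = False

    def __post_init__(self) -> None:
        if (self.trial_csv is None) == (self.preset is None):
            raise PipelineConfigError("config must name exactly one of trial_csv or preset")
        if self.preset is not None and self.preset not in PRESETS:
            raise PipelineConfigError(
                f"unknown preset {self.preset!r}; available: {', '.join(sorted(PRESETS))}"
            )
        if TREATMENT_CLASS.get(self.normal_env) != "normal":
            raise PipelineConfigError(f"{self.normal_env!r} is not a normal environment")
        for env in self.stress_envs:
            if TREATMENT_CLASS.get(env) in (None, "normal"):
                raise PipelineConfigError(
                    f"stress environment {env!r} invalid (must be SI or SNI)"
                )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "stress_envs" in raw:
            raw["stress_envs"] = tuple(raw["stress_envs"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")
        payload.pop("dry_run")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """In-memory results plus the paths of every file written."""

    config: PipelineConfig
    indices: dict[str, IndexTable] = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)
    report_lines: list[str] = field(default_factory=list)


def _round(df: pd.DataFrame, digits: int = 6) -> pd.DataFrame:
    return df.round(digits)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis described by ``config`` and write the bundle.

    With ``dry_run`` set, the validated plan is logged and returned and
    no file is written.
    """
    from . import __version__

    header = f"stresskit {__version__} seed={config.seed} config={config.config_hash()}"
    outdir = Path(config.outdir)
    bundle = ReportBundle(config=config)
    report = bundle.report_lines
    report += [
        "# stresskit report",
        "",
        f"- version: {__version__}",
        f"- seed: {config.seed}",
        f"- config hash: {config.config_hash()}",
        f"- input: {config.trial_csv or 'preset ' + str(config.preset)}",
        "",
    ]

    # -- resolve inputs ----------------------------------------------------
    trial: TrialTable | None = None
    pairs_by_stress: dict[str, YieldPairTable] = {}
    if config.trial_csv is not None:
        trial = TrialTable.from_csv(config.trial_csv)
    else:
        preset_cfg = get_preset(config.preset, seed=config.seed)
        if isinstance(preset_cfg, TrialSimConfig):
            trial = simulate_trial(preset_cfg)
        else:
            pairs_by_stress[preset_cfg.stress] = simulate_yield_pairs(preset_cfg)

    plan: list[str] = []
    if trial is not None:
        for env in config.stress_envs:
            if env not in trial.environments:
                logger.warning("stress environment %s absent from input; outputs skipped", env)
                report.append(f"- note: stress environment {env} absent; outputs skipped")
                continue
            if config.pair_trait not in trial.traits:
                logger.warning(
                    "pairing trait %r absent; index/classification outputs skipped",
                    config.pair_trait,
                )
                report.append(
                    f"- note: trait {config.pair_trait} absent; index outputs skipped"
                )
                break
            pairs_by_stress[TREATMENT_CLASS[env]] = pair_yields(
                trial, config.normal_env, env, config.pair_trait
            )
        plan += [f"anova+heritability on traits: {', '.join(trial.traits)}"]
    plan += [f"index/classification chain for: {', '.join(pairs_by_stress) or 'none'}"]

    if config.dry_run:
        logger.info("dry run; plan: %s", "; ".join(plan))
        report += ["", "## Plan (dry run)", *[f"- {p}" for p in plan]]
        return bundle

    outdir.mkdir(parents=True, exist_ok=True)

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        out = df.reset_index() if index else df
        write_table(_round(out), path, header_comment=header)
        bundle.files.append(path)

    # -- index / classification chain, one pass per stress episode ---------
    for stress, pairs in sorted(pairs_by_stress.items()):
        idx = compute_indices(pairs)
        bundle.indices[stress] = idx
        emit(idx.data, f"indices_{stress}.csv")
        report += [f"## {stress.capitalize()} stress", "",
                   f"- genotypes: {len(idx.data)}",
                   f"- stress intensity SI = {idx.si:.4f}", ""]

        corr = pearson_matrix(idx.matrix())
        emit(corr.formatted(), f"corr_{stress}.csv", index=True)

        z = standardize(idx)
        pca = pca_indices(z)
        emit(pca.summary(3), f"pca_{stress}.csv", index=True)
        report.append(
            f"- PC1+PC2 cumulative variance: {pca.cumulative_variance[1]:.2f} %"
        )

        clusters = label_clusters(ward_cluster(z, k=config.k), idx) if config.k == 4 \
            else ward_cluster(z, k=config.k)
        emit(clusters.to_frame(), f"clusters_{stress}.csv")
        (outdir / f"dendrogram_{stress}.nwk").write_text(
            dendrogram_newick(clusters) + "\n", encoding="utf-8"
        )
        bundle.files.append(outdir / f"dendrogram_{stress}.nwk")
        if clusters.labels:
            sizes = clusters.to_frame().groupby("label").size()
            report += [f"- cluster sizes: {sizes.to_dict()}", ""]
            if trial is not None:
                env = {"heat": "SI", "combined": "SNI"}[stress]
                profile = cluster_profile(clusters, trial, trial.traits, env)
                emit(profile.formatted(), f"profile_{stress}.csv", index=True)

    # -- classical trial statistics ----------------------------------------
    if trial is not None:
        herit_rows = []
        for trait in trial.traits:
            try:
                aov = two_way_anova(trial, trait)
                emit(aov.table, f"anova_{trait}.csv", index=True)
            except ValidationError as exc:
                logger.warning("anova skipped for %s: %s", trait, exc)
            for env in trial.environments:
                try:
                    h = broad_sense_heritability(trial, env, trait)
                except ValidationError:
                    continue
                herit_rows.append(
                    {"environment": env, "trait": trait, "sigma2_g": h.sigma2_g,
                     "sigma2_e": h.sigma2_e, "r": h.n_replicates, "H2": h.h2}
                )
        if herit_rows:
            emit(pd.DataFrame(herit_rows), "heritability.csv")

        if config.normal_env in trial.environments:
            pc_rows = []
            for trait in trial.traits:
                base = trial.subset(config.normal_env, trait)["value"].mean()
                for env in config.stress_envs:
                    if env not in trial.environments or base == 0:
                        continue
                    stress_mean = trial.subset(env, trait)["value"].mean()
                    pc_rows.append(
                        {"trait": trait, "stress_env": env,
                         "mean_normal": base, "mean_stress": stress_mean,
                         "percent_change": percent_change(base, stress_mean)}
                    )
            if pc_rows:
                emit(pd.DataFrame(pc_rows), "percent_change.csv")

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(report) + "\n", encoding="utf-8")
    bundle.files.append(report_path)
    return bundle
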
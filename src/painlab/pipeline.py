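"""End-to-end orchestration: synth → QC → preprocess → features → MRMR →
classification → statistics, driven by one YAML-style configuration.

Subjects are processed one at a time (generate, QC, preprocess, epoch,
featurise) so cohort-scale runs never hold the full raw data in memory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import default_spec, ClassifierSpec, CVReport, losocv
from .core import ConfigError, PipelineError
from .features import build_feature_table, feature_columns
from .io import write_cv_report, write_feature_table, write_qc_reports
from .preprocess import (
    FilterSpec,
    balance_baseline,
    preprocess_to_series,
    segment_epochs,
)
from .qc import select_channels
from .stats import feature_class_screen, posthoc_table
from .synth import (
    ArtifactModel,
    HemodynamicModel,
    ProtocolConfig,
    SubjectData,
    iter_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """One configuration covering every pipeline stage."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    hemo: HemodynamicModel = field(default_factory=HemodynamicModel)
    artifacts: ArtifactModel = field(default_factory=ArtifactModel)
    input_dir: str | None = None  # read a stored cohort instead of generating
    rr_threshold: float = 0.1
    max_removed_fraction: float = 0.70
    qc_measure: str = "hbo2"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    epoch_duration: float = 10.0
    strict_paper_order: bool = False
    feature_mode: str = "fused"
    mrmr_k: int | None = 15
    ranking_mode: str = "per_fold"
    classifier_family: str = "svm"
    classifier_overrides: dict = field(default_factory=dict)
    alpha: float = 0.05
    output_dir: str = "painlab_out"
    seed: int | None = None  # overrides protocol seeds when set

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cohort = dict(raw.get("cohort", {}))
        protocol = ProtocolConfig(**cohort.get("protocol", {}))
        hemo_kwargs = dict(cohort.get("hemodynamics", {}))
        if "response_amplitude" in hemo_kwargs:
            hemo_kwargs["response_amplitude"] = {
                k: tuple(v) for k, v in hemo_kwargs["response_amplitude"].items()
            }
        hemo = HemodynamicModel(**hemo_kwargs)
        art_kwargs = dict(cohort.get("artifacts", {}))
        if "faulty_channel_indices" in art_kwargs:
            art_kwargs["faulty_channel_indices"] = tuple(
                art_kwargs["faulty_channel_indices"]
            )
        art = ArtifactModel(**art_kwargs)
        qc = raw.get("qc", {})
        pre = raw.get("preprocess", {})
        fspec = FilterSpec(
            order=pre.get("order", 4),
            cutoff=pre.get("cutoff", 0.16),
            phase_mode=pre.get("phase_mode", "zero_phase"),
        )
        feat = raw.get("features", {})
        mr = raw.get("mrmr", {})
        cl = raw.get("classify", {})
        st = raw.get("stats", {})
        return cls(
            protocol=protocol,
            hemo=hemo,
            artifacts=art,
            input_dir=cohort.get("input_dir"),
            rr_threshold=qc.get("rr_threshold", 0.1),
            max_removed_fraction=qc.get("max_removed_fraction", 0.70),
            qc_measure=qc.get("measure", "hbo2"),
            filter_spec=fspec,
            epoch_duration=pre.get("epoch_duration", 10.0),
            strict_paper_order=pre.get("strict_paper_order", False),
            feature_mode=feat.get("mode", "fused"),
            mrmr_k=mr.get("k", 15),
            ranking_mode=mr.get("ranking_mode", "per_fold"),
            classifier_family=cl.get("family", "svm"),
            classifier_overrides=cl.get("overrides", {}),
            alpha=st.get("alpha", 0.05),
            output_dir=raw.get("output_dir", "painlab_out"),
            seed=raw.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def effective_protocol(self) -> ProtocolConfig:
        if self.seed is None:
            return self.protocol
        return ProtocolConfig(
            **{
                **self.protocol.__dict__,
                "rng_seed": int(self.seed),
                "counterbalance_seed": int(self.seed) + 1,
            }
        )

    def classifier_spec(self) -> ClassifierSpec:
        spec = default_spec(self.classifier_family, self.feature_mode)
        if self.classifier_overrides:
            hp = dict(spec.hyperparameters)
            hp.update(self.classifier_overrides)
            spec = ClassifierSpec(spec.family, hp)
        return spec


def validate_config(config: RunConfig) -> list[str]:
    """List every configuration violation; never mutates state."""
    violations: list[str] = []
    try:
        config.effective_protocol().validate()
    except ConfigError as exc:
        violations.append(f"protocol: {exc}")
    try:
        config.hemo.validate(config.protocol)
    except ConfigError as exc:
        violations.append(f"hemodynamics: {exc}")
    try:
        config.artifacts.validate(config.protocol)
    except ConfigError as exc:
        violations.append(f"artifacts: {exc}")
    try:
        config.filter_spec.validate(config.protocol.sampling_rate)
    except ConfigError as exc:
        violations.append(f"preprocess: {exc}")
    if not 0 <= config.rr_threshold:
        violations.append("qc: rr_threshold must be >= 0")
    if not 0 <= config.max_removed_fraction <= 1:
        violations.append("qc: max_removed_fraction must lie in [0, 1]")
    if config.feature_mode not in ("hbo2", "hhb", "fused"):
        violations.append(f"features: unknown mode {config.feature_mode!r}")
    else:
        n_feat = len(feature_columns(config.feature_mode))
        if config.mrmr_k is not None and not 1 <= config.mrmr_k <= n_feat:
            violations.append(
                f"mrmr: k={config.mrmr_k} outside 1..{n_feat} for mode "
                f"{config.feature_mode!r}"
            )
    if config.classifier_family not in ("discriminant", "knn", "svm"):
        violations.append(f"classify: unknown family {config.classifier_family!r}")
    if not 0 < config.alpha < 1:
        violations.append("stats: alpha must lie in (0, 1)")
    if config.epoch_duration <= 0:
        violations.append("preprocess: epoch_duration must be > 0")
    return violations


@dataclass
class RunReport:
    counts: dict
    cv: CVReport | None
    stats_features: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        out = {
            "counts": self.counts,
            "provenance": self.provenance,
            "stats_features": self.stats_features,
        }
        if self.cv is not None:
            out["cv"] = {
                "mean": self.cv.mean,
                "std": self.cv.std,
                "pooled_confusion": self.cv.pooled_confusion.tolist(),
            }
        return out


def process_subject(
    sub: SubjectData, config: RunConfig
) -> tuple[object, object, object] | None:
    """QC + preprocess + epoch one subject.

    Returns (qc_report, hbo2 EpochSet, hhb EpochSet); the epoch sets are
    None when the subject is excluded by the channel-loss rule.
    """
    qc_rec = sub.hbo2 if config.qc_measure == "hbo2" else sub.hhb
    report = select_channels(
        qc_rec,
        rr_threshold=config.rr_threshold,
        max_removed_fraction=config.max_removed_fraction,
    )
    if report.removed_fraction > config.max_removed_fraction:
        return report, None, None
    retained = report.retained_indices
    epochsets = []
    for rec in (sub.hbo2, sub.hhb):
        series = preprocess_to_series(
            rec, retained, config.filter_spec, config.strict_paper_order
        )
        eps = segment_epochs(
            series,
            rec.events,
            rec.sampling_rate,
            config.epoch_duration,
            subject_id=sub.subject_id,
        )
        eps = balance_baseline(eps, rec.events, series)
        epochsets.append(eps)
    return report, epochsets[0], epochsets[1]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and write per-stage artifacts."""
    violations = validate_config(config)
    if violations:
        raise PipelineError("config: " + "; ".join(violations))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    protocol = config.effective_protocol()
    if config.input_dir is not None:
        from .io import read_cohort

        subjects = read_cohort(config.input_dir)
    else:
        subjects = iter_cohort(protocol, config.hemo, config.artifacts)

    from .core import EpochSet

    qc_reports = []
    all_hbo2 = EpochSet(epoch_duration=config.epoch_duration,
                        sampling_rate=protocol.sampling_rate)
    all_hhb = EpochSet(epoch_duration=config.epoch_duration,
                       sampling_rate=protocol.sampling_rate)
    n_subjects_in = 0
    n_excluded = 0
    for sub in subjects:
        n_subjects_in += 1
        try:
            report, eps_hbo2, eps_hhb = process_subject(sub, config)
        except Exception as exc:  # stage context for debugging
            raise PipelineError(
                f"preprocess: subject {sub.subject_id} failed: {exc}"
            ) from exc
        qc_reports.append(report)
        if eps_hbo2 is None:
            n_excluded += 1
            logger.info(
                "qc: subject %s excluded (removed %.0f%% of channels)",
                sub.subject_id,
                100 * report.removed_fraction,
            )
            continue
        all_hbo2.epochs.extend(eps_hbo2.epochs)
        all_hhb.epochs.extend(eps_hhb.epochs)
    write_qc_reports(qc_reports, outdir)
    if n_excluded == n_subjects_in:
        raise PipelineError(
            "qc: all subjects excluded by the channel-loss rule; nothing to analyse"
        )
    logger.info(
        "qc: %d/%d subjects retained", n_subjects_in - n_excluded, n_subjects_in
    )

    table = build_feature_table(all_hbo2, all_hhb, mode=config.feature_mode)
    write_feature_table(table, outdir / "features.tsv")
    logger.info("features: %d rows x %d features", len(table), table.shape[1] - 2)

    cv = None
    if len(dict.fromkeys(table["subject"])) >= 2:
        cv = losocv(
            table,
            config.classifier_spec(),
            k_features=config.mrmr_k,
            ranking_mode=config.ranking_mode,
        )
        write_cv_report(cv, outdir)
        logger.info("classify: %s", cv.summary())

    screen = feature_class_screen(table, alpha=config.alpha)
    ptable = posthoc_table(screen)
    if not ptable.empty:
        ptable.to_csv(outdir / "posthoc.tsv", sep="\t", index=False)
    anova_rows = pd.DataFrame(
        [
            {
                "feature": feat,
                "F": res["anova"].F,
                "df_between": res["anova"].df_between,
                "df_within": res["anova"].df_within,
                "p": res["anova"].p,
            }
            for feat, res in screen.items()
        ]
    )
    if not anova_rows.empty:
        anova_rows.to_csv(outdir / "anova.tsv", sep="\t", index=False)

    counts = {
        "subjects_in": n_subjects_in,
        "subjects_excluded": n_excluded,
        "subjects_retained": n_subjects_in - n_excluded,
        "epochs": len(all_hbo2),
        "feature_rows": int(len(table)),
        "excluded_rows": len(all_hbo2) - int(len(table)),
        "n_features": int(table.shape[1] - 2),
        "class_counts": all_hbo2.class_counts(),
    }
    config_text = json.dumps(
        {k: str(v) for k, v in config.__dict__.items()}, sort_keys=True
    )
    provenance = {
        "seed": config.seed,
        "rng_seed": protocol.rng_seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "painlab_version": __version__,
        "numpy_version": np.__version__,
    }
    report = RunReport(
        counts=counts,
        cv=cv,
        stats_features=list(screen),
        provenance=provenance,
    )
    (outdir / "run_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    return report
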
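"""End-to-end orchestration: generate -> segment -> extract -> select ->
classify -> report, from one validated configuration.

The stage order follows the analysis design: nonlinear features are
extracted per channel and averaged across channels; per repetition of the
70/30 subject-wise split, the swarm optimizer learns selection weights on
*training rows only*, every subject's rows are projected onto them, the
per-segment mean of the selected column gives one value per feature
method (a 9-dimensional instance per segment), and the classifier battery
is scored per class.  Metrics are computed per repetition and then
averaged before tabulation.

Expensive stages (cohort simulation, feature extraction) are cached under
the output directory keyed by a configuration hash, so re-running after
deleting downstream artifacts only recomputes downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as szio
from .classify import CLASSIFIERS, ClassifierSpec, Dataset, SplitPlan, train_predict
from .exceptions import ConfigError, SzeegError
from .features import METHODS, default_variants, feature_matrix
from .metrics import (
    build_report_tables,
    canonical_correlation,
    classification_metrics,
    confusion_counts,
    moment_summary,
    mse,
    pearson_matrix,
    write_report_bundle,
)
from .swarm import OPTIMIZERS, select_feature_column
from .synthetic import CLASS_LABELS, EEGRecording, GeneratorConfig, segment_channel

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "load_config", "run_pipeline"]

log = logging.getLogger("szeeg")

__version__ = "0.1.0"

#: Modest optimizer budgets for the selection stage (the fitness is a cheap
#: 10-dimensional Fisher ratio; these budgets recover informative weights
#: without dominating the run time).  Benchmark-quality budgets are the
#: optimizer defaults in :mod:`szeeg.swarm`.
SELECTION_BUDGETS: dict[str, dict] = {
    "af": {"n_plants": 8, "branching": 4, "iterations": 25},
    "gso": {"n_glowworms": 20, "iterations": 120},
    "bh": {"n_stars": 15, "iterations": 120},
    "ms": {"n_monkeys": 6, "climb_iterations": 10, "watch_attempts": 3, "iterations": 6},
}


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    segment_length: int = 5000
    n_subwindows: int = 10
    methods: tuple[str, ...] = METHODS
    optimizers: tuple[str, ...] = ("af", "gso", "bh", "ms")
    classifiers: tuple[str, ...] = CLASSIFIERS
    split: SplitPlan = field(default_factory=SplitPlan)
    optimizer_params: Mapping[str, Mapping] = field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None
    input_cohort: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigError("methods: at least one feature method required")
        for m in self.methods:
            if m not in METHODS:
                raise ConfigError(f"methods: unknown method {m!r}")
        if not self.optimizers:
            raise ConfigError("optimizers: at least one optimizer required")
        for o in self.optimizers:
            if o not in OPTIMIZERS:
                raise ConfigError(f"optimizers: unknown optimizer {o!r}")
        if not self.classifiers:
            raise ConfigError("classifiers: at least one classifier required")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ConfigError(f"classifiers: unknown classifier {c!r}")
        if self.segment_length < self.n_subwindows:
            raise ConfigError("segment_length must be >= n_subwindows")


@dataclass
class RunManifest:
    config_hash: str
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, seconds: float,
               artifacts: Sequence[str] = (), detail: str = "") -> None:
        self.stages[stage] = {
            "status": status,
            "seconds": round(seconds, 3),
            "artifacts": list(artifacts),
            "detail": detail,
        }

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: RunManifest
    results: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    out_dir: str | None


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "generator", "segment_length", "n_subwindows", "methods", "optimizers",
    "classifiers", "split", "optimizer_params", "seed", "out_dir",
    "input_cohort", "log_level",
}
_GEN_KEYS = {f.name for f in dataclasses.fields(GeneratorConfig)}
_SPLIT_KEYS = {f.name for f in dataclasses.fields(SplitPlan)}


def config_from_dict(raw: Mapping | None) -> PipelineConfig:
    """Build a validated config from a (possibly empty) mapping.

    Unknown keys are rejected with a message naming the offending key;
    nested generator/split blocks are validated the same way.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    gen_raw = dict(raw.pop("generator", {}) or {})
    bad = set(gen_raw) - _GEN_KEYS
    if bad:
        raise ConfigError(f"generator: unknown key(s): {sorted(bad)}")
    split_raw = dict(raw.pop("split", {}) or {})
    bad = set(split_raw) - _SPLIT_KEYS
    if bad:
        raise ConfigError(f"split: unknown key(s): {sorted(bad)}")
    try:
        generator = GeneratorConfig(**gen_raw)
    except (TypeError, SzeegError) as exc:
        raise ConfigError(f"generator: {exc}") from exc
    try:
        split = SplitPlan(**split_raw)
    except (TypeError, SzeegError) as exc:
        raise ConfigError(f"split: {exc}") from exc
    for key in ("methods", "optimizers", "classifiers"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return PipelineConfig(generator=generator, split=split, **raw)
    except (TypeError, SzeegError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str) -> PipelineConfig:
    """Parse a YAML or JSON configuration file; an empty file means defaults."""
    import yaml

    if not os.path.exists(path):
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        text = fh.read()
    if path.endswith(".json"):
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the configuration (key order independent)."""
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {k: convert(v) for k, v in sorted(dataclasses.asdict(obj).items())}
        if isinstance(obj, Mapping):
            return {str(k): convert(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    blob = json.dumps(convert(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _derived_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_cohort(config: PipelineConfig, manifest: RunManifest,
                  cache_dir: str | None) -> list[EEGRecording]:
    t0 = time.time()
    if config.input_cohort:
        recs = szio.load_cohort(config.input_cohort)
        manifest.record("cohort", "loaded", time.time() - t0, [config.input_cohort])
        return recs
    gen = dataclasses.replace(config.generator, seed=_derived_seed(config.seed, 0))
    if cache_dir:
        marker = os.path.join(cache_dir, "cohort", ".complete")
        if os.path.exists(marker):
            recs = szio.load_cohort(os.path.join(cache_dir, "cohort"))
            manifest.record("cohort", "cached", time.time() - t0,
                            [os.path.join(cache_dir, "cohort")])
            return recs
    from .synthetic import generate_cohort

    recs = generate_cohort(gen)
    artifacts = []
    if cache_dir:
        cdir = os.path.join(cache_dir, "cohort")
        szio.save_cohort(recs, cdir)
        open(os.path.join(cdir, ".complete"), "w").close()
        artifacts.append(cdir)
    manifest.record("cohort", "computed", time.time() - t0, artifacts)
    return recs


def _extract_subject(rec: EEGRecording, config: PipelineConfig) -> dict[str, np.ndarray]:
    """Channel-averaged rows x 10 matrix per method, plus the segment tags."""
    seg_mats = [segment_channel(rec, c, config.segment_length) for c in range(rec.n_channels)]
    out: dict[str, np.ndarray] = {}
    for method in config.methods:
        variants = default_variants(method)
        acc = None
        seg_idx = None
        for sm in seg_mats:
            fm = feature_matrix(sm, method, variant_params=variants,
                                mode="subwindow", n_subwindows=config.n_subwindows)
            acc = fm.values if acc is None else acc + fm.values
            seg_idx = fm.segment_index
        out[method] = acc / len(seg_mats)
        out["_segment_index"] = seg_idx
    return out


def _stage_features(recs: list[EEGRecording], config: PipelineConfig,
                    manifest: RunManifest, cache_dir: str | None) -> dict:
    t0 = time.time()
    fdir = os.path.join(cache_dir, "features") if cache_dir else None
    if fdir:
        marker = os.path.join(fdir, ".complete")
        if os.path.exists(marker):
            feats = {}
            for rec in recs:
                per_method = {}
                for method in config.methods:
                    fm = szio.load_feature_matrix(os.path.join(fdir, f"{rec.subject_id}_{method}"))
                    per_method[method] = fm.values
                    per_method["_segment_index"] = fm.segment_index
                feats[rec.subject_id] = per_method
            manifest.record("features", "cached", time.time() - t0, [fdir])
            return feats
    feats = {}
    for rec in recs:
        feats[rec.subject_id] = _extract_subject(rec, config)
        log.info("features: subject %s done", rec.subject_id)
    if fdir:
        os.makedirs(fdir, exist_ok=True)
        from .features import FeatureMatrix

        for rec in recs:
            per_method = feats[rec.subject_id]
            for method in config.methods:
                fm = FeatureMatrix(
                    method=method, channel=-1, values=per_method[method],
                    variants=default_variants(method),
                    segment_index=per_method["_segment_index"],
                    mode="subwindow",
                )
                szio.save_feature_matrix(fm, os.path.join(fdir, f"{rec.subject_id}_{method}"))
        open(os.path.join(fdir, ".complete"), "w").close()
    manifest.record("features", "computed", time.time() - t0, [fdir] if fdir else [])
    return feats


def _project_instances(feats: Mapping, recs: list[EEGRecording],
                       weights: Mapping[str, np.ndarray],
                       methods: Sequence[str]) -> Dataset:
    """Per-segment mean of each method's selected column -> instance matrix."""
    rows = []
    labels = []
    groups = []
    for rec in recs:
        per_method = feats[rec.subject_id]
        seg_idx = per_method["_segment_index"]
        n_seg = int(seg_idx.max()) + 1
        cols = []
        for method in methods:
            proj = per_method[method] @ weights[method]
            seg_means = np.array([proj[seg_idx == k].mean() for k in range(n_seg)])
            cols.append(seg_means)
        block = np.column_stack(cols)
        rows.append(block)
        labels.extend([CLASS_LABELS.index(rec.class_label)] * n_seg)
        groups.extend([rec.subject_id] * n_seg)
    return Dataset(np.vstack(rows), np.array(labels), np.array(groups))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every requested (method x optimizer x classifier) combination.

    Selection weights are fitted per (optimizer, repetition) on the
    training subjects' rows only; any classifier failure is recorded in
    the manifest and the remaining combinations continue.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = RunManifest(config_hash=config_hash(config))
    cache_dir = config.out_dir
    if cache_dir:
        os.makedirs(cache_dir, exist_ok=True)
        # invalidate caches written under a different configuration
        hash_path = os.path.join(cache_dir, "config_hash.txt")
        if os.path.exists(hash_path):
            with open(hash_path) as fh:
                if fh.read().strip() != manifest.config_hash:
                    cache_dir = None
        if cache_dir:
            with open(hash_path, "w") as fh:
                fh.write(manifest.config_hash)

    recs = _stage_cohort(config, manifest, cache_dir)
    feats = _stage_features(recs, config, manifest, cache_dir)

    t0 = time.time()
    records = []
    summaries_acc: dict = {}
    failures = []
    full = Dataset(
        np.zeros((sum(int(feats[r.subject_id]["_segment_index"].max()) + 1 for r in recs), 1)),
        np.array([CLASS_LABELS.index(r.class_label)
                  for r in recs
                  for _ in range(int(feats[r.subject_id]["_segment_index"].max()) + 1)]),
        np.array([r.subject_id
                  for r in recs
                  for _ in range(int(feats[r.subject_id]["_segment_index"].max()) + 1)]),
    )
    for rep in range(config.split.repetitions):
        plan = SplitPlan(config.split.train_fraction, config.split.repetitions,
                         seed=_derived_seed(config.seed, 1))
        # split on the skeleton dataset once per repetition (group-aware)
        from .classify import split_train_test

        train_skel, test_skel = split_train_test(full, plan, rep)
        train_subjects = set(np.unique(train_skel.group_id).tolist())
        train_recs = [r for r in recs if r.subject_id in train_subjects]
        test_recs = [r for r in recs if r.subject_id not in train_subjects]
        for optimizer in config.optimizers:
            weights = {}
            for mi, method in enumerate(config.methods):
                m0 = np.vstack([feats[r.subject_id][method] for r in train_recs
                                if r.class_label == "normal"])
                m1 = np.vstack([feats[r.subject_id][method] for r in train_recs
                                if r.class_label == "schizophrenia"])
                opt_seed = _derived_seed(config.seed, 2, rep,
                                         list(OPTIMIZERS).index(optimizer), mi)
                params = dict(SELECTION_BUDGETS.get(optimizer, {}))
                params.update(config.optimizer_params.get(optimizer, {}))
                cfg_cls = OPTIMIZERS[optimizer][1]
                sel = select_feature_column(m0, m1, optimizer,
                                            config=cfg_cls(**params, seed=opt_seed))
                weights[method] = sel.weights
            dataset = _project_instances(feats, recs, weights, config.methods)
            train_rows = np.isin(dataset.group_id, list(train_subjects))
            train = dataset.subset(train_rows)
            test = dataset.subset(~train_rows)
            mu = train.instances.mean(axis=0)
            sd = train.instances.std(axis=0)
            sd[sd == 0] = 1.0
            train_z = Dataset((train.instances - mu) / sd, train.labels, train.group_id)
            test_z = Dataset((test.instances - mu) / sd, test.labels, test.group_id)

            _accumulate_summaries(summaries_acc, optimizer, config.methods, feats,
                                  recs, weights)

            for clf_name in config.classifiers:
                spec = ClassifierSpec(name=clf_name,
                                      seed=_derived_seed(config.seed, 3, rep))
                try:
                    pred, scores = train_predict(spec, train_z, test_z)
                except Exception as exc:  # noqa: BLE001 - stage isolation
                    failures.append(f"{optimizer}/{clf_name}/rep{rep}: {exc}")
                    continue
                overall = float(np.mean(pred == test_z.labels)) * 100.0
                err = mse(scores, test_z.labels.astype(float))
                for label_idx, cls in enumerate(CLASS_LABELS):
                    counts = confusion_counts(test_z.labels, pred, label_idx)
                    row = classification_metrics(counts)
                    records.append(
                        {
                            "optimizer": optimizer,
                            "classifier": clf_name,
                            "repetition": rep,
                            "target_class": cls,
                            "PC": counts.PC,
                            "MC": counts.MC,
                            "FA": counts.FA,
                            "n_target": counts.n_target,
                            "sensitivity": row.sensitivity,
                            "specificity": row.specificity,
                            "accuracy": row.accuracy,
                            "PI": row.PI,
                            "GDR": row.GDR,
                            "mse": err,
                            "overall_accuracy": overall,
                        }
                    )
        log.info("repetition %d done", rep)
    results = pd.DataFrame.from_records(records)
    manifest.record("select_classify", "computed", time.time() - t0,
                    detail="; ".join(failures))

    t0 = time.time()
    tables = build_report_tables(results, _finalize_summaries(summaries_acc, config.methods))
    artifacts = []
    if config.out_dir:
        report_dir = os.path.join(config.out_dir, "report")
        artifacts = write_report_bundle(tables, report_dir)
        results.to_csv(os.path.join(config.out_dir, "results.csv"), index=False)
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            fh.write(manifest.to_json())
    manifest.record("report", "computed", time.time() - t0, artifacts)
    return PipelineResult(manifest=manifest, results=results, tables=tables,
                          out_dir=config.out_dir)


# ---------------------------------------------------------------------------
# feature summary tables (moments, CCA, PCC)
# ---------------------------------------------------------------------------

def _accumulate_summaries(acc: dict, optimizer: str, methods: Sequence[str],
                          feats: Mapping, recs: list[EEGRecording],
                          weights: Mapping[str, np.ndarray]) -> None:
    cols = {0: {}, 1: {}}
    for method in methods:
        for label_idx, cls in enumerate(CLASS_LABELS):
            stacked = np.vstack([feats[r.subject_id][method] for r in recs
                                 if r.class_label == cls])
            cols[label_idx][method] = stacked @ weights[method]
    acc.setdefault(optimizer, []).append(cols)


def _finalize_summaries(acc: dict, methods: Sequence[str]) -> dict[str, pd.DataFrame]:
    if not acc:
        return {}
    moment_rows: dict[str, list] = {cls: [] for cls in CLASS_LABELS}
    cca_feat = {m: [] for m in methods}
    cca_opt: dict[str, list] = {}
    pcc_feat: dict[str, dict[str, list]] = {cls: {m: [] for m in methods} for cls in CLASS_LABELS}
    pcc_opt: dict[str, dict[str, list]] = {}
    for optimizer, reps in acc.items():
        for cols in reps:
            for label_idx, cls in enumerate(CLASS_LABELS):
                for method in methods:
                    s = moment_summary(cols[label_idx][method])
                    moment_rows[cls].append({"optimizer": optimizer, "method": method, **s})
            for method in methods:
                a, b = cols[0][method], cols[1][method]
                n = min(a.size, b.size)
                if n >= 3:
                    c = canonical_correlation(a[:n, None], b[:n, None])
                    cca_feat[method].append(c)
                    cca_opt.setdefault(optimizer, []).append(c)
            for label_idx, cls in enumerate(CLASS_LABELS):
                mat = np.column_stack([cols[label_idx][m] for m in methods])
                if mat.shape[1] >= 2:
                    corr = np.corrcoef(mat, rowvar=False)
                    for i, m in enumerate(methods):
                        off = np.delete(corr[i], i)
                        off = off[np.isfinite(off)]
                        if off.size:
                            pcc_feat[cls][m].append(float(off.mean()))
                    overall = pearson_matrix(mat)
                    pcc_opt.setdefault(optimizer, {}).setdefault(cls, []).append(overall)
    out: dict[str, pd.DataFrame] = {}
    for cls in CLASS_LABELS:
        df = pd.DataFrame(moment_rows[cls])
        slug = "normal" if cls == "normal" else "schizophrenia"
        out[f"moments_{slug}"] = (
            df.groupby(["optimizer", "method"]).mean().stack().unstack("method")
        )
    out["cca_features"] = pd.DataFrame(
        {m: [np.mean(v)] if v else [np.nan] for m, v in cca_feat.items()}, index=["CCA"]
    )
    out["cca_optimizers"] = pd.DataFrame(
        {"CCA": {o: np.mean(v) for o, v in cca_opt.items()}}
    )
    out["pcc_features"] = pd.DataFrame(
        {m: {cls: (np.mean(v) if v else np.nan) for cls, v in
             ((c, pcc_feat[c][m]) for c in CLASS_LABELS)} for m in methods}
    )
    out["pcc_optimizers"] = pd.DataFrame(
        {cls: {o: np.mean(d.get(cls, [np.nan])) for o, d in pcc_opt.items()}
         for cls in CLASS_LABELS}
    )
    return out
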
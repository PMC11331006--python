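"""End-to-end orchestration of the stacked fusion pipeline.

Per cross-validation fold: rank features on the training patients only,
fuse the selected views into a patient similarity network over the whole
cohort, train the graph branch transductively (loss masked to training
patients) and one convolutional branch per view on training rows, stack
the four hidden representations, and fit the boosted random forest on the
training rows. Variants used by the ablation study drop the graph block
(``-ResGCN``), the convolutional blocks (``-CNNs``) or replace the boosted
forest with a one-hidden-layer perceptron head (``-RF``).
"""

from __future__ import annotations

import dataclasses
import json
import os
import platform
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnn import CNNConfig, extract_cnn_features, train_cnn
from .datatypes import SOURCE_ORDER, FeatureBlock, LabelVector, OmicsBlock, StackedFeatures
from .ensemble import EnsembleConfig, predict, stack_features, train_adaboost_rf
from .evaluate import METRIC_NAMES, MetricsReport, km_logrank, metrics_row, plot_km, stratified_folds, embed_2d
from .features import mrmr_rank
from .preprocess import align_patients, derive_labels, preprocess_view, read_omics_tsv, read_survival_tsv
from .resgcn import GraphInput, ResGCNConfig, extract_psn_features, train_resgcn
from .snf import _sym_row_stochastic, default_k, pairwise_affinity, row_normalize, snf_fuse
from .synthetic import CohortConfig, generate_cohort


@dataclass
class SNFConfig:
    lambda_param: float = 0.5
    k: int | None = None  # default: n // 10, at least 3
    n_iter: int = 20


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run from its manifest."""

    data_paths: dict[str, str] | None = None  # clinical/expression/cnv/survival
    synthetic: CohortConfig | None = None
    n_select: dict[str, int] = field(
        default_factory=lambda: {"expression": 400, "cnv": 200}  # clinical: all
    )
    snf: SNFConfig = field(default_factory=SNFConfig)
    resgcn: ResGCNConfig = field(default_factory=ResGCNConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    cv_folds: int = 10
    stratified: bool = True
    variant: str = "full"
    seed: int = 0
    out_dir: str = "msfn_out"

    def __post_init__(self) -> None:
        if (self.data_paths is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of data_paths or synthetic config")


def config_from_yaml(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a config from a plain mapping (YAML file or run manifest)."""
    kwargs: dict = {}
    for key in ("data_paths", "n_select", "cv_folds", "stratified", "variant", "seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    if "synthetic" in raw:
        kwargs["synthetic"] = CohortConfig(**raw["synthetic"])
    for key, cls in (
        ("snf", SNFConfig), ("resgcn", ResGCNConfig),
        ("cnn", CNNConfig), ("ensemble", EnsembleConfig),
    ):
        if key in raw:
            kwargs[key] = cls(**raw[key])
    return PipelineConfig(**kwargs)


def _config_to_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


# ---------------------------------------------------------------------------
# per-fold fit / predict

def _single_view_network(block: OmicsBlock, lambda_param: float, k: int | None) -> np.ndarray:
    """Patient network from one view alone: full-kernel transition matrix
    projected to the symmetric row-stochastic set (no fusion possible)."""
    if k is None:
        k = default_k(block.n_patients)
    aff = pairwise_affinity(block, lambda_param, k)
    return _sym_row_stochastic(row_normalize(aff).P)


def _concat_blocks(blocks: list[FeatureBlock]) -> StackedFeatures:
    """Stacking that tolerates missing sources (for ablation variants)."""
    present = {b.source for b in blocks}
    if present == set(SOURCE_ORDER):
        return stack_features(blocks)
    by_source = {b.source: b for b in blocks}
    order = [s for s in SOURCE_ORDER if s in by_source]
    ids = by_source[order[0]].patient_ids
    boundaries, pieces, offset = {}, [], 0
    for source in order:
        v = by_source[source].values
        boundaries[source] = (offset, offset + v.shape[1])
        offset += v.shape[1]
        pieces.append(v)
    return StackedFeatures(
        values=np.concatenate(pieces, axis=1), patient_ids=ids, block_boundaries=boundaries
    )


def build_stacked_features(
    views: Mapping[str, OmicsBlock],
    labels: LabelVector,
    train_mask: np.ndarray,
    seed: int,
    n_select: Mapping[str, int] | None = None,
    snf_config: SNFConfig | None = None,
    resgcn_config: ResGCNConfig | None = None,
    cnn_config: CNNConfig | None = None,
    variant: str = "full",
) -> StackedFeatures:
    """Feature selection + both branch families for one train/test split."""
    snf_config = snf_config or SNFConfig()
    resgcn_config = resgcn_config or ResGCNConfig()
    cnn_config = cnn_config or CNNConfig()
    n_select = {} if n_select is None else dict(n_select)

    train_ids = labels.patient_ids[train_mask]
    train_labels = LabelVector(patient_ids=train_ids, label=labels.label[train_mask])

    selected: dict[str, OmicsBlock] = {}
    for view in sorted(views):
        block = views[view]
        n_top = n_select.get(view)
        if n_top is not None and n_top < block.n_features:
            ranking = mrmr_rank(block.subset_patients(train_ids), train_labels, n_top)
            block = block.subset_features(ranking.feature_names)
        selected[view] = block

    blocks: list[FeatureBlock] = []
    if variant != "-CNNs":
        for i, view in enumerate(sorted(selected)):
            block = selected[view]
            cfg = replace(cnn_config, seed=seed + 17 * (i + 1))
            model = train_cnn(block.subset_patients(train_ids), train_labels, cfg)
            blocks.append(extract_cnn_features(model, block))

    if variant != "-ResGCN":
        view_list = [selected[v] for v in sorted(selected)]
        if len(view_list) >= 2:
            fused = snf_fuse(
                view_list, snf_config.lambda_param, snf_config.k, snf_config.n_iter
            )
            adjacency = fused.S.copy()
        else:
            adjacency = _single_view_network(
                view_list[0], snf_config.lambda_param, snf_config.k
            ).copy()
        # the graph layer adds its own self-loops; feed it pure between-patient
        # edges or the dominant self-similarity drowns out neighbourhood mixing
        np.fill_diagonal(adjacency, 0.0)
        adjacency = adjacency / adjacency.sum(axis=1, keepdims=True)
        adjacency = (adjacency + adjacency.T) / 2.0
        node_features = np.concatenate([b.values for b in view_list], axis=1)
        # carve a validation fifth out of the training patients so the graph
        # branch early-stops instead of memorizing the training mask
        rng = np.random.default_rng(seed)
        tr_idx = np.flatnonzero(train_mask)
        val_idx = rng.choice(tr_idx, size=max(len(tr_idx) // 5, 1), replace=False)
        fit_mask = train_mask.copy()
        fit_mask[val_idx] = False
        val_mask = np.zeros_like(train_mask)
        val_mask[val_idx] = True
        graph = GraphInput(
            adjacency=adjacency,
            node_features=node_features,
            patient_ids=labels.patient_ids,
            train_mask=fit_mask,
            val_mask=val_mask,
        )
        model = train_resgcn(graph, labels, replace(resgcn_config, seed=seed))
        blocks.append(extract_psn_features(model, graph))

    if not blocks:
        raise ValueError("variant removed every feature block")
    return _concat_blocks(blocks)


def make_fit_predict(
    variant: str = "full",
    n_select: Mapping[str, int] | None = None,
    snf_config: SNFConfig | None = None,
    resgcn_config: ResGCNConfig | None = None,
    cnn_config: CNNConfig | None = None,
    ensemble_config: EnsembleConfig | None = None,
):
    """Closure implementing one fold of the pipeline for the CV driver."""
    ensemble_config = ensemble_config or EnsembleConfig()

    def fit_predict(
        views: Mapping[str, OmicsBlock],
        labels: LabelVector,
        train_mask: np.ndarray,
        fold_seed: int,
    ) -> tuple[np.ndarray, np.ndarray]:
        stacked = build_stacked_features(
            views, labels, train_mask, fold_seed,
            n_select=n_select, snf_config=snf_config,
            resgcn_config=resgcn_config, cnn_config=cnn_config,
            variant=variant,
        )
        train_stacked = StackedFeatures(
            values=stacked.values[train_mask],
            patient_ids=stacked.patient_ids[train_mask],
            block_boundaries=stacked.block_boundaries,
        )
        train_labels = LabelVector(
            patient_ids=labels.patient_ids[train_mask], label=labels.label[train_mask]
        )
        if variant == "-RF":
            from sklearn.neural_network import MLPClassifier

            head = MLPClassifier(
                hidden_layer_sizes=(64,), max_iter=500, random_state=fold_seed % (2**31)
            )
            head.fit(train_stacked.values, train_labels.label)
            scores = head.predict_proba(stacked.values)[:, 1]
            preds = (scores >= 0.5).astype(int)
        else:
            cfg = replace(ensemble_config, seed=fold_seed % (2**31))
            model = train_adaboost_rf(train_stacked, train_labels, cfg)
            scores, preds = predict(model, stacked)
        return scores, preds

    return fit_predict


# ---------------------------------------------------------------------------
# harnesses

def single_view_harness(
    views: Mapping[str, OmicsBlock],
    labels: LabelVector,
    k: int = 10,
    seed: int = 0,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Pipeline on each view alone versus all views together."""
    from .evaluate import run_cross_validation

    rows = []
    for name in sorted(views) + ["multi-omics"]:
        subset = views if name == "multi-omics" else {name: views[name]}
        fp = make_fit_predict(**pipeline_kwargs)
        report = run_cross_validation(subset, labels, fp, k=k, seed=seed)
        rows.append({"data": name, **report.mean})
    return pd.DataFrame(rows)


def sweep_layers(
    views: Mapping[str, OmicsBlock],
    labels: LabelVector,
    min_layers: int = 1,
    max_layers: int = 8,
    k: int = 10,
    seed: int = 0,
    resgcn_config: ResGCNConfig | None = None,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Graph-branch depth sweep: one cross-validated row per layer count."""
    from .evaluate import run_cross_validation

    base = resgcn_config or ResGCNConfig()
    rows = []
    for n_layers in range(min_layers, max_layers + 1):
        fp = make_fit_predict(
            resgcn_config=replace(base, n_layers=n_layers), **pipeline_kwargs
        )
        report = run_cross_validation(views, labels, fp, k=k, seed=seed)
        rows.append({"n_layers": n_layers, **report.mean})
    return pd.DataFrame(rows)


def sweep_features(
    views: Mapping[str, OmicsBlock],
    labels: LabelVector,
    grid: Mapping[str, list[int]],
    k: int = 10,
    seed: int = 0,
    **pipeline_kwargs,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Incremental per-view feature-count search over a grid."""
    from .evaluate import run_cross_validation
    from .features import incremental_search

    def cv_runner(counts: Mapping[str, int]) -> Mapping[str, float]:
        fp = make_fit_predict(n_select=dict(counts), **pipeline_kwargs)
        return run_cross_validation(views, labels, fp, k=k, seed=seed).mean

    return incremental_search(cv_runner, grid)


# ---------------------------------------------------------------------------
# full run

def load_inputs(config: PipelineConfig):
    """Load (or simulate) raw views and survival, preprocess and align."""
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        raw_views = cohort.views
        survival = cohort.survival
    else:
        paths = dict(config.data_paths)
        if "survival" not in paths:
            raise FileNotFoundError("config names no survival table")
        for name, path in paths.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")
        survival = read_survival_tsv(paths.pop("survival"))
        raw_views = {
            name: read_omics_tsv(path, view_kind=name) for name, path in paths.items()
        }
    views = {name: preprocess_view(block) for name, block in raw_views.items()}
    labels = derive_labels(survival)
    views, labels = align_patients(views, labels)
    keep = np.isin(survival.patient_ids, labels.patient_ids)
    surv_order = np.argsort(survival.patient_ids[keep])
    times = survival.time_months[keep][surv_order]
    events = survival.event[keep][surv_order]
    return views, labels, times, events


def run_pipeline(config: PipelineConfig) -> MetricsReport:
    """Full cross-validated run; writes metrics, predictions, plots and a
    reproducibility manifest into ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    views, labels, times, events = load_inputs(config)
    y = labels.label

    fit_predict = make_fit_predict(
        variant=config.variant,
        n_select=config.n_select,
        snf_config=config.snf,
        resgcn_config=config.resgcn,
        cnn_config=config.cnn,
        ensemble_config=config.ensemble,
    )
    folds = stratified_folds(y, k=config.cv_folds, seed=config.seed, stratified=config.stratified)
    oof_scores = np.full(len(y), np.nan)
    oof_preds = np.zeros(len(y), dtype=int)
    rows = []
    for fold in range(config.cv_folds):
        test = folds == fold
        scores, preds = fit_predict(views, labels, ~test, config.seed * 1000 + fold)
        oof_scores[test] = scores[test]
        oof_preds[test] = preds[test]
        rows.append(metrics_row(y[test], scores[test], preds[test]))
    per_fold = pd.DataFrame(rows, index=[f"fold{f}" for f in range(config.cv_folds)])
    report = MetricsReport(
        per_fold=per_fold, mean={m: float(per_fold[m].mean()) for m in METRIC_NAMES}
    )

    out = config.out_dir
    report.to_frame().to_csv(os.path.join(out, "metrics.tsv"), sep="\t")
    pd.DataFrame(
        {"patient_id": labels.patient_ids, "label": y, "score": oof_scores, "pred": oof_preds}
    ).to_csv(os.path.join(out, "predictions.tsv"), sep="\t", index=False)

    # survival analysis of the pooled out-of-fold predictions
    if len(np.unique(oof_preds)) == 2:
        curves, stat, pval = km_logrank(times, events, oof_preds)
        plot_km(curves, os.path.join(out, "km_curves.png"))
        with open(os.path.join(out, "logrank.json"), "w") as fh:
            json.dump({"chi_square": stat, "p_value": pval}, fh, indent=2)

    # stacked features fitted on the full cohort, for the 2-D embedding
    stacked = build_stacked_features(
        views, labels, np.ones(len(y), dtype=bool), config.seed,
        n_select=config.n_select, snf_config=config.snf,
        resgcn_config=config.resgcn, cnn_config=config.cnn, variant=config.variant,
    )
    embed_2d(stacked, y, seed=config.seed, path=os.path.join(out, "tsne.png"))

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": _config_to_dict(config),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
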
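"""Cross-species model transfer and disagreement-based label filtering.

The transfer procedure: train an ensemble in a well-annotated source species
on the features shared between species, apply it (with the source-learned
threshold) to the harmonized target-species features, and remove target
training genes whose database annotation contradicts the cross-species call
(annotated GM but called SM, or annotated SM but called GM) — on the premise
that such genes are likely mis-annotated.  A retrained target model on the
filtered data is compared against models trained on randomly-thinned
training sets of the same size (the control that distinguishes informed
filtering from mere data removal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from smtransfer.ensemble import (
    GM,
    SM,
    EnsembleModel,
    precision_recall_f,
    sm_score,
    split_train_test,
    train_model,
)
from smtransfer.features import FeatureTable, harmonize_shared_features

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Partition of the annotated SM/GM genes into kept vs removed.

    Removed genes are split by disagreement direction: ``gm_to_sm`` are
    annotated GM but cross-predicted SM; ``sm_to_gm`` the converse.
    """

    kept: pd.Index
    removed_gm_to_sm: pd.Index
    removed_sm_to_gm: pd.Index
    cross_scores: pd.DataFrame

    @property
    def removed(self) -> pd.Index:
        return self.removed_gm_to_sm.append(self.removed_sm_to_gm)

    @property
    def counts(self) -> dict:
        return {
            "kept": len(self.kept),
            "removed_gm_to_sm": len(self.removed_gm_to_sm),
            "removed_sm_to_gm": len(self.removed_sm_to_gm),
            "removed_total": len(self.removed),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "kept") for g in self.kept]
            + [(g, "removed_gm_to_sm") for g in self.removed_gm_to_sm]
            + [(g, "removed_sm_to_gm") for g in self.removed_sm_to_gm]
        )
        return pd.DataFrame(rows, columns=["gene_id", "status"])


@dataclass
class ExperimentReport:
    """Per-model-variant metrics plus the filter report of one experiment."""

    metrics: dict[str, dict[str, dict]]  # variant -> eval set -> metric map
    filter_report: FilterReport | None = None
    score_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    filter_mode: str = "filter-all"
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for variant, sets in self.metrics.items():
            for eval_set, m in sets.items():
                rows.append({"variant": variant, "eval_set": eval_set, **m})
        return pd.DataFrame(rows)


def apply_cross_species(
    source_model: EnsembleModel,
    target_features: pd.DataFrame,
    require_harmonized: bool = True,
) -> pd.DataFrame:
    """Score target-species genes with a source-species model.

    Uses the source model's own F-max threshold for the SM/GM call
    (re-thresholding on target annotations would partially defeat the
    filter's independence from those annotations).  When the model was
    trained on harmonized features, the target input must carry the
    harmonization tag set by :func:`harmonize_shared_features`.
    """
    if source_model.threshold is None:
        raise ValueError("source model has no threshold; train it first")
    if (
        require_harmonized
        and source_model.trained_on_harmonized
        and not target_features.attrs.get("harmonized", False)
    ):
        raise ValueError(
            "target features are not harmonized; pass them through "
            "harmonize_shared_features before cross-species application"
        )
    return sm_score(source_model, target_features, mode="all")


def disagreement_filter(labels: pd.Series, cross_calls: pd.DataFrame) -> FilterReport:
    """Remove annotated genes whose annotation contradicts the cross call.

    ``labels``: observed annotations; only SM/GM genes participate (DF and
    unannotated genes are untouched and appear in neither partition).
    ``cross_calls``: SM-score table with a ``call`` column covering every
    annotated SM/GM gene.
    """
    ann = labels[labels.isin([SM, GM])]
    missing = ann.index.difference(cross_calls.index)
    if len(missing):
        raise ValueError(f"annotated genes missing a cross-species call: {list(missing[:5])}...")
    calls = cross_calls.loc[ann.index, "call"]
    gm_to_sm = ann.index[(ann == GM) & (calls == SM)]
    sm_to_gm = ann.index[(ann == SM) & (calls == GM)]
    removed = gm_to_sm.append(sm_to_gm)
    kept = ann.index.difference(removed, sort=False)
    return FilterReport(
        kept=kept,
        removed_gm_to_sm=gm_to_sm,
        removed_sm_to_gm=sm_to_gm,
        cross_scores=cross_calls.loc[ann.index].copy(),
    )


def random_removal_control(
    labels: pd.Series,
    genes: pd.Index,
    n_remove_sm: int,
    n_remove_gm: int,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[pd.Index]:
    """Training sets with the same per-class removal counts, applied randomly.

    Each repeat removes exactly ``n_remove_sm`` SM and ``n_remove_gm`` GM
    genes uniformly without replacement from ``genes``; repeats are
    independent and the whole list is deterministic given the seed.
    """
    sub = labels.loc[genes]
    sm = sub.index[sub == SM].to_numpy()
    gm = sub.index[sub == GM].to_numpy()
    if n_remove_sm > len(sm) or n_remove_gm > len(gm):
        raise ValueError(
            f"cannot remove {n_remove_sm} SM / {n_remove_gm} GM from "
            f"{len(sm)} SM / {len(gm)} GM genes"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_repeats):
        drop_sm = rng.choice(sm, size=n_remove_sm, replace=False)
        drop_gm = rng.choice(gm, size=n_remove_gm, replace=False)
        keep = pd.Index(genes).difference(pd.Index(np.concatenate([drop_sm, drop_gm])), sort=False)
        out.append(keep)
    return out


def _evaluate(scores: pd.DataFrame, labels: pd.Series, genes: pd.Index) -> dict:
    genes = pd.Index(genes).intersection(scores.index).intersection(labels.index)
    if len(genes) == 0:
        return {}
    return precision_recall_f(
        scores.loc[genes, "call"].to_numpy(), labels.loc[genes].to_numpy()
    )


@dataclass
class TransferConfig:
    """Knobs of the two-species experiment.

    Reduced-scale defaults (25 draws, 5 folds) keep a full replica at desk
    scale; ``n_draws=100, folds=10`` is the full-scale configuration.
    """

    n_draws: int = 25
    per_class: int = 500
    folds: int = 5
    test_fraction: float = 0.1
    algorithm: str = "random_forest"
    grid: dict | None = None
    do_grid_search: bool = False
    control_repeats: int = 10
    filter_mode: str = "filter-all"  # or "filter-train-only"
    benchmark_override: bool = False  # replace observed labels with benchmark truth
    variants: tuple[str, ...] = (
        "unfiltered_full",
        "source_shared",
        "source_on_target",
        "unfiltered_shared",
        "filtered_shared",
        "filtered_full",
        "random_removal",
    )
    seed: int = 0


def _eval_model(
    name: str,
    model: EnsembleModel,
    train_scores: pd.DataFrame,
    features: pd.DataFrame,
    observed: pd.Series,
    true_labels: pd.Series | None,
    benchmark: pd.Series | None,
    train_genes: pd.Index,
    test_genes: pd.Index,
    metrics: dict,
    score_tables: dict,
) -> pd.DataFrame:
    """Score train/test/benchmark sets for one model variant."""
    test_scores = sm_score(model, features.loc[test_genes]) if len(test_genes) else pd.DataFrame()
    sets = {"train": (train_scores, train_genes), "test": (test_scores, test_genes)}
    out: dict[str, dict] = {}
    for eval_name, (scores, genes) in sets.items():
        if len(genes) == 0:
            continue
        m = _evaluate(scores, observed, genes)
        if m:
            out[eval_name] = m
        if true_labels is not None:
            m_true = _evaluate(scores, true_labels, genes)
            if m_true:
                out[f"{eval_name}_true"] = m_true
    if benchmark is not None and len(benchmark):
        bench_genes = benchmark.index.intersection(features.index)
        bench_scores = sm_score(model, features.loc[bench_genes])
        m = _evaluate(bench_scores, benchmark, bench_genes)
        if m:
            out["benchmark"] = m
    metrics[name] = out
    score_tables[name] = pd.concat([train_scores, test_scores]) if len(test_scores) else train_scores
    return test_scores


def run_transfer_experiment(
    source_features: FeatureTable,
    source_labels: pd.Series,
    target_features: FeatureTable,
    target_labels: pd.Series,
    shared_names,
    config: TransferConfig | None = None,
    source_true: pd.Series | None = None,
    target_true: pd.Series | None = None,
    target_benchmark: pd.Series | None = None,
) -> ExperimentReport:
    """Run the full two-species experiment.

    Stages: (a) target full-feature model; (b) source shared-feature model,
    self-evaluated; (c) source model applied to target shared features;
    (d) target shared-feature model; (e) disagreement filter and retrain on
    the filtered target data (shared- and full-feature variants);
    (f) random-removal control retrains.  Every variant is evaluated on its
    training genes (out-of-draw scores), the held-out test set, and the
    benchmark subset; when true labels are supplied (synthetic worlds),
    metrics against truth are reported alongside observed-label metrics.
    Metrics against truth on the *original, unfiltered* test set make the
    variants directly comparable.
    """
    cfg = config or TransferConfig()
    if cfg.benchmark_override and target_benchmark is not None:
        target_labels = target_labels.copy()
        target_labels.loc[target_benchmark.index] = target_benchmark
    metrics: dict[str, dict] = {}
    score_tables: dict[str, pd.DataFrame] = {}

    seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2**31)
    tgt_split = split_train_test(target_labels, cfg.test_fraction, seed=int(seeds[0]))
    src_split = split_train_test(source_labels, cfg.test_fraction, seed=int(seeds[1]))

    def train_and_eval(name, features, labels, train_genes, test_genes, truth, bench, seed):
        logger.info("training variant %s (%d train genes)", name, len(train_genes))
        model, train_scores = train_model(
            features,
            labels,
            train_genes,
            n_draws=cfg.n_draws,
            per_class=cfg.per_class,
            algorithm=cfg.algorithm,
            grid=cfg.grid,
            folds=cfg.folds,
            seed=seed,
            do_grid_search=cfg.do_grid_search,
        )
        _eval_model(
            name, model, train_scores, features, labels, truth, bench,
            train_genes, test_genes, metrics, score_tables,
        )
        return model

    # (a) target, full feature set
    if "unfiltered_full" in cfg.variants:
        train_and_eval(
            "unfiltered_full",
            target_features.values,
            target_labels,
            tgt_split.train,
            tgt_split.test,
            target_true,
            target_benchmark,
            int(seeds[2]),
        )

    # shared-feature harmonization
    src_shared, tgt_shared = harmonize_shared_features(
        source_features, target_features, shared_names
    )

    # (b) source model on shared features
    source_model = None
    if {"source_shared", "source_on_target", "filtered_shared", "filtered_full",
        "random_removal"} & set(cfg.variants):
        source_model, src_train_scores = train_model(
            src_shared.values,
            source_labels,
            src_split.train,
            n_draws=cfg.n_draws,
            per_class=cfg.per_class,
            algorithm=cfg.algorithm,
            grid=cfg.grid,
            folds=cfg.folds,
            seed=int(seeds[3]),
            do_grid_search=cfg.do_grid_search,
        )
        if "source_shared" in cfg.variants:
            _eval_model(
                "source_shared", source_model, src_train_scores, src_shared.values,
                source_labels, source_true, None, src_split.train, src_split.test,
                metrics, score_tables,
            )

    # (c) cross-species application with the source-learned threshold
    filter_report = None
    if source_model is not None:
        cross = apply_cross_species(source_model, tgt_shared.values)
        score_tables["source_on_target"] = cross
        if "source_on_target" in cfg.variants:
            out: dict[str, dict] = {}
            for eval_name, genes in (("train", tgt_split.train), ("test", tgt_split.test)):
                out[eval_name] = _evaluate(cross, target_labels, genes)
                if target_true is not None:
                    out[f"{eval_name}_true"] = _evaluate(cross, target_true, genes)
            if target_benchmark is not None and len(target_benchmark):
                out["benchmark"] = _evaluate(cross, target_benchmark, target_benchmark.index)
            metrics["source_on_target"] = out
        filter_report = disagreement_filter(target_labels, cross)

    # (d) target, shared features, unfiltered
    if "unfiltered_shared" in cfg.variants:
        train_and_eval(
            "unfiltered_shared",
            tgt_shared.values,
            target_labels,
            tgt_split.train,
            tgt_split.test,
            target_true,
            target_benchmark,
            int(seeds[4]),
        )

    # (e) disagreement filter + retrain
    filtered_train = filtered_test = None
    if filter_report is not None:
        filtered_train = tgt_split.train.intersection(filter_report.kept, sort=False)
        if cfg.filter_mode == "filter-all":
            filtered_test = tgt_split.test.intersection(filter_report.kept, sort=False)
        else:
            filtered_test = tgt_split.test
        for offset, (name, feats) in enumerate(
            (
                ("filtered_shared", tgt_shared.values),
                ("filtered_full", target_features.values),
            )
        ):
            if name not in cfg.variants:
                continue
            model = train_and_eval(
                name, feats, target_labels, filtered_train, filtered_test,
                target_true, target_benchmark, int(seeds[5]) + offset,
            )
            # comparability: truth-based metrics on the ORIGINAL test set
            if target_true is not None and cfg.filter_mode == "filter-all":
                full_test_scores = sm_score(model, feats.loc[tgt_split.test])
                metrics[name]["test_true_unfiltered"] = _evaluate(
                    full_test_scores, target_true, tgt_split.test
                )

    # (f) random-removal controls
    if "random_removal" in cfg.variants and filter_report is not None:
        obs_train = target_labels.loc[tgt_split.train]
        n_rm_sm = len(
            filter_report.removed_sm_to_gm.intersection(tgt_split.train, sort=False)
        )
        n_rm_gm = len(
            filter_report.removed_gm_to_sm.intersection(tgt_split.train, sort=False)
        )
        controls = random_removal_control(
            target_labels, tgt_split.train, n_rm_sm, n_rm_gm,
            n_repeats=cfg.control_repeats, seed=int(seeds[6]),
        )
        for r, keep in enumerate(controls):
            train_and_eval(
                f"random_removal_{r:02d}",
                tgt_shared.values,
                target_labels,
                keep,
                tgt_split.test,
                target_true,
                target_benchmark,
                int(seeds[7]) + r,
            )

    return ExperimentReport(
        metrics=metrics,
        filter_report=filter_report,
        score_tables=score_tables,
        filter_mode=cfg.filter_mode,
        config={
            "n_draws": cfg.n_draws,
            "per_class": cfg.per_class,
            "folds": cfg.folds,
            "test_fraction": cfg.test_fraction,
            "algorithm": cfg.algorithm,
            "control_repeats": cfg.control_repeats,
            "filter_mode": cfg.filter_mode,
            "seed": cfg.seed,
        },
    )
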
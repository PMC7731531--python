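"""Readers and writers for the pipeline's tab-delimited interchange formats.

All tables are TSV, UTF-8, missing values as empty strings.  Feature tables
travel as a values TSV (genes x features, gene id first column) plus a
sidecar metadata TSV (feature, category, kind, shared).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from smtransfer.features import (
    DETable,
    ExpressionMatrix,
    FeatureTable,
    GeneCoordinates,
    HomologyTable,
    ParalogTable,
)


def read_feature_table(values_path, meta_path) -> FeatureTable:
    return FeatureTable.from_tsv(values_path, meta_path)


def write_feature_table(table: FeatureTable, values_path, meta_path) -> None:
    table.to_tsv(values_path, meta_path)


def read_labels(path) -> pd.DataFrame:
    """labels TSV: gene_id, observed_label[, true_label]."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "observed_label" not in df.columns:
        raise ValueError(f"{path}: expected an 'observed_label' column")
    return df


def read_expression_matrix(values_path, groups_path) -> ExpressionMatrix:
    """Expression TSV (genes x samples) + sample->group map TSV
    (columns: sample, group)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t").set_index("sample")["group"]
    return ExpressionMatrix(values=values, groups=groups)


def read_de_table(path, p_adjusted: bool = False) -> DETable:
    """Long-format DE TSV: gene, contrast, group, logFC, p."""
    return DETable(table=pd.read_csv(path, sep="\t"), p_adjusted=p_adjusted)


def read_coordinates(path, one_based: bool = False) -> GeneCoordinates:
    """BED-like TSV (chrom, start, end, gene_id; half-open 0-based) or a
    1-based inclusive TSV with the same columns (``one_based=True``).
    Internally 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gene_id"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not one_based:
        df = df.assign(start=df["start"] + 1)
    return GeneCoordinates.from_frame(df)


def read_homology(pairs_path, orthogroups_path, node_path=None) -> HomologyTable:
    """Homology TSV (gene, species, dn_ds) + orthogroups TSV
    (gene, orthogroup) + optional node TSV (gene, node[, pseudogene])."""
    pairs = pd.read_csv(pairs_path, sep="\t")
    og = pd.read_csv(orthogroups_path, sep="\t").set_index("gene")["orthogroup"]
    node = pseudo = None
    if node_path is not None:
        nd = pd.read_csv(node_path, sep="\t").set_index("gene")
        node = nd["node"] if "node" in nd.columns else None
        pseudo = nd["pseudogene"] if "pseudogene" in nd.columns else None
    return HomologyTable(pairs=pairs, orthogroup=og, node=node, pseudogene_paralog=pseudo)


def read_paralog_pairs(path) -> ParalogTable:
    """Paralog pairs TSV: gene_a, gene_b[, syntenic, dispersed, dn_ds, pseudogene]."""
    return ParalogTable(table=pd.read_csv(path, sep="\t"))


def read_domain_matrix(path) -> FeatureTable:
    """Binary gene x protein-domain matrix TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    bad = ~values.isin([0.0, 1.0]) & values.notna()
    if bad.to_numpy().any():
        raise ValueError(f"{path}: domain matrix must be binary (0/1)")
    meta = pd.DataFrame(
        {"category": "domain", "kind": "binary", "shared": False},
        index=pd.Index(values.columns, name="feature"),
    )
    return FeatureTable(values=values, meta=meta)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", float_format="%.6f")


def write_model(model, outdir) -> None:
    """Serialize a fitted model to a versioned directory.

    Hyperparameters, seeds, threshold and importances are plain TSV/text;
    the fitted base learners are stored in the host pickle format (noted as
    non-portable across library versions).
    """
    import json
    import pickle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "algorithm": model.algorithm,
        "hyperparameters": model.hyperparameters,
        "threshold": model.threshold,
        "threshold_f": model.threshold_f,
        "seed": model.seed,
        "n_draws": len(model.draws),
        "n_folds": model.n_folds,
        "trained_on_harmonized": model.trained_on_harmonized,
        "feature_names": model.feature_names,
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2) + "\n")
    if model.importances is not None:
        model.importances.rename_axis("feature").to_csv(outdir / "importances.tsv", sep="\t")
    with open(outdir / "learners.pkl", "wb") as fh:
        pickle.dump({"learners": model.learners, "draws": model.draws,
                     "sm_index": model.sm_index}, fh)


def read_model(outdir):
    import json
    import pickle

    from smtransfer.ensemble import EnsembleModel

    outdir = Path(outdir)
    meta = json.loads((outdir / "model.json").read_text())
    with open(outdir / "learners.pkl", "rb") as fh:
        blobs = pickle.load(fh)
    importances = None
    imp_path = outdir / "importances.tsv"
    if imp_path.exists():
        importances = pd.read_csv(imp_path, sep="\t", index_col=0)["importance"]
    return EnsembleModel(
        algorithm=meta["algorithm"],
        hyperparameters=meta["hyperparameters"],
        learners=blobs["learners"],
        draws=blobs["draws"],
        feature_names=meta["feature_names"],
        threshold=meta["threshold"],
        threshold_f=meta["threshold_f"],
        importances=importances,
        seed=meta["seed"],
        n_folds=meta["n_folds"],
        trained_on_harmonized=meta["trained_on_harmonized"],
        sm_index=blobs["sm_index"],
    )
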
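"""Synthetic two-species worlds for exercising the SM/GM classification pipeline.

Real inputs for this problem are curated pathway databases (gene -> SM/GM/DF
annotation) and a large gene x feature matrix assembled from transcriptome,
homology and gene-duplication analyses.  This module generates a statistical
stand-in: two species that share a subset of identically-named features, with
class-dependent feature distributions, observed labels corrupted at
configurable asymmetric rates in the less-well-annotated (target) species, and
a small benchmark subset whose true labels are revealed — emulating a
manually curated gold-standard gene set.

The generator targets the statistical structure the classifier consumes
(shared vs private features, effect sizes, label noise), not transcriptome
realism.

Labels
------
``SM``  specialized metabolism (positive class)
``GM``  general metabolism (negative class)
``DF``  dual function — excluded from training
``UNANNOTATED``  no observed label; the genome-wide application target

Seeding: a single experiment-level seed fans out to per-operation seeds via
``numpy.random.SeedSequence(seed).spawn``; child *i* of the sequence is
consumed by operation *i* in the documented order (source features, target
features, target label corruption, benchmark subset).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from smtransfer.features import FeatureTable

SM = "SM"
GM = "GM"
DF = "DF"
UNANNOTATED = "UNANNOTATED"

LABELS = (SM, GM, DF, UNANNOTATED)


class ConfigurationError(ValueError):
    """Raised when a SynthConfig field violates its invariant."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a two-species synthetic world.

    Defaults mirror the study conditions of the real system this emulates:
    ~2000 annotated enzyme genes per species at SM prevalence 0.19
    (537 SM / 2321 GM in the original annotation), a shared feature set that
    is a subset of each species' full feature set, standardized effect size
    1.0 for informative features, 90% of informative class effects preserved
    across species, and asymmetric target-species mis-annotation rates
    (GM observed as SM at 0.15, SM observed as GM at 0.25), with an
    88-gene benchmark subset.
    """

    n_genes_source: int = 2000
    n_genes_target: int = 2000
    sm_prevalence: float = 0.19
    n_shared_continuous: int = 30
    n_shared_binary: int = 20
    n_private_per_species: int = 10
    n_informative_shared: int = 40
    effect_size: float = 1.0
    cross_species_fidelity: float = 0.9
    eps_gm_to_sm: float = 0.15
    eps_sm_to_gm: float = 0.25
    df_fraction: float = 0.05
    unannotated_fraction: float = 0.10
    benchmark_n: int = 88
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes_source": self.n_genes_source,
            "n_genes_target": self.n_genes_target,
            "n_shared_continuous": self.n_shared_continuous,
            "n_shared_binary": self.n_shared_binary,
            "benchmark_n": self.benchmark_n,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        for name in ("n_private_per_species", "n_informative_shared"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {value!r}")
        fractions = {
            "sm_prevalence": self.sm_prevalence,
            "cross_species_fidelity": self.cross_species_fidelity,
            "eps_gm_to_sm": self.eps_gm_to_sm,
            "eps_sm_to_gm": self.eps_sm_to_gm,
            "df_fraction": self.df_fraction,
            "unannotated_fraction": self.unannotated_fraction,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if not (0.0 < self.sm_prevalence < 1.0):
            raise ConfigurationError(
                f"sm_prevalence must lie strictly inside (0, 1), got {self.sm_prevalence!r}"
            )
        if self.df_fraction + self.unannotated_fraction >= 1.0:
            raise ConfigurationError("df_fraction + unannotated_fraction must be < 1")
        if self.n_informative_shared > self.n_shared_continuous + self.n_shared_binary:
            raise ConfigurationError(
                "n_informative_shared exceeds the number of shared features "
                f"({self.n_informative_shared} > "
                f"{self.n_shared_continuous + self.n_shared_binary})"
            )


@dataclass
class SpeciesData:
    """One species' slice of a synthetic world."""

    name: str
    genes: pd.Index
    true_labels: pd.Series
    observed_labels: pd.Series
    features: FeatureTable
    benchmark: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def annotated(self) -> pd.Index:
        """Genes whose observed label is SM or GM (the trainable set)."""
        mask = self.observed_labels.isin([SM, GM])
        return self.observed_labels.index[mask]


@dataclass
class SyntheticWorld:
    source: SpeciesData
    target: SpeciesData
    shared_features: list[str]
    config: SynthConfig

    @property
    def species(self) -> dict[str, SpeciesData]:
        return {self.source.name: self.source, self.target.name: self.target}


def _feature_layout(config: SynthConfig) -> pd.DataFrame:
    """Feature metadata shared by both species: name, kind, shared flag.

    Shared feature names are identical across species; private features
    exist in each species' table but are absent from the shared list.
    """
    rows = []
    for i in range(config.n_shared_continuous):
        rows.append((f"shared_c{i:03d}", "continuous", True))
    for i in range(config.n_shared_binary):
        rows.append((f"shared_b{i:03d}", "binary", True))
    for i in range(config.n_private_per_species):
        rows.append((f"private_c{i:03d}", "continuous", False))
    meta = pd.DataFrame(rows, columns=["feature", "kind", "shared"]).set_index("feature")
    meta["category"] = "synthetic"
    return meta


def _informative_effects(config: SynthConfig, rng: np.random.Generator) -> pd.Series:
    """Pick which shared features carry a class effect, with a random sign.

    Continuous effects are standardized mean shifts (SM minus GM); binary
    effects are log-odds shifts.  Signs are mixed so that roughly half the
    informative features lean SM and half lean GM, as in real data.
    """
    meta = _feature_layout(config)
    shared = meta.index[meta["shared"]]
    chosen = rng.choice(shared.to_numpy(), size=config.n_informative_shared, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_informative_shared)
    effects = pd.Series(0.0, index=meta.index)
    effects.loc[chosen] = signs * config.effect_size
    return effects


def _draw_true_labels(
    n: int, config: SynthConfig, rng: np.random.Generator
) -> tuple[pd.Series, pd.Series]:
    """Assign true labels: DF and unannotated by fixed fractions, the rest
    SM with probability sm_prevalence.

    Unannotated genes still carry a latent SM/GM component (they are drawn
    from the same generative mixture); their *true* label records that
    component so that genome-wide application can be evaluated.  DF genes are
    a 50/50 mixture and keep the DF true label.
    """
    n_df = int(round(config.df_fraction * n))
    n_un = int(round(config.unannotated_fraction * n))
    idx = rng.permutation(n)
    roles = np.full(n, "annotated", dtype=object)
    roles[idx[:n_df]] = DF
    roles[idx[n_df : n_df + n_un]] = UNANNOTATED
    is_sm = rng.random(n) < config.sm_prevalence
    true = np.where(is_sm, SM, GM).astype(object)
    true[roles == DF] = DF
    return pd.Series(true, dtype=object), pd.Series(roles, dtype=object)


def _draw_features(
    labels: pd.Series,
    effects: pd.Series,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw gene x feature values given per-feature class effects.

    Continuous features: unit-variance Gaussians with mean +effect/2 for SM
    and -effect/2 for GM.  Binary features: Bernoulli with logit(base rate)
    shifted by +effect/2 / -effect/2.  DF genes take each feature's SM or GM
    component with probability 1/2 (independently per gene).
    """
    n = len(labels)
    base_logit = np.log(0.3 / 0.7)  # base binary feature rate 0.3
    component = np.where(labels.to_numpy() == SM, 1.0, -1.0)
    df_mask = labels.to_numpy() == DF
    if df_mask.any():
        component[df_mask] = rng.choice([-1.0, 1.0], size=int(df_mask.sum()))
    values = np.empty((n, len(meta)))
    for j, name in enumerate(meta.index):
        eff = effects.get(name, 0.0)
        shift = component * eff / 2.0
        if meta.loc[name, "kind"] == "continuous":
            values[:, j] = rng.normal(loc=shift, scale=1.0)
        else:
            p = 1.0 / (1.0 + np.exp(-(base_logit + shift)))
            values[:, j] = (rng.random(n) < p).astype(float)
    return pd.DataFrame(values, columns=meta.index)


def corrupt_labels(
    true_labels: pd.Series,
    eps_gm_to_sm: float,
    eps_sm_to_gm: float,
    seed: int | np.random.Generator,
) -> pd.Series:
    """Flip SM<->GM labels independently at the given per-class rates.

    Each true-GM gene is observed as SM with probability ``eps_gm_to_sm``;
    each true-SM gene as GM with probability ``eps_sm_to_gm``.  DF and
    unannotated genes are untouched.  The result has the same index and
    length as the input (corruption is measure-preserving on gene count).
    """
    for name, rate in (("eps_gm_to_sm", eps_gm_to_sm), ("eps_sm_to_gm", eps_sm_to_gm)):
        if not (0.0 <= rate <= 1.0):
            raise ConfigurationError(f"{name} must lie in [0, 1], got {rate!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = true_labels.copy()
    u = rng.random(len(true_labels))
    arr = true_labels.to_numpy()
    flip_gm = (arr == GM) & (u < eps_gm_to_sm)
    flip_sm = (arr == SM) & (u < eps_sm_to_gm)
    observed[flip_gm] = SM
    observed[flip_sm] = GM
    return observed


def make_benchmark_subset(
    labels: pd.Series, true_labels: pd.Series, n: int, seed: int | np.random.Generator
) -> pd.Series:
    """Sample ``n`` annotated genes without replacement, stratified over true
    classes, and return their revealed true labels.

    Emulates a manually curated gold-standard set: the genes chosen are ones
    with an observed SM/GM/DF annotation, but the labels returned are the
    true ones.  Stratification allocates by the true-class proportions among
    annotated genes (largest-remainder rounding), so every class with at
    least one member is represented whenever n allows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    annotated = labels.index[labels.isin([SM, GM, DF])]
    if n > len(annotated):
        raise ValueError(f"benchmark size {n} exceeds annotated gene count {len(annotated)}")
    truth = true_labels.loc[annotated]
    classes = sorted(truth.unique())
    exact = {c: n * (truth == c).sum() / len(annotated) for c in classes}
    alloc = {c: int(np.floor(v)) for c, v in exact.items()}
    remainder = n - sum(alloc.values())
    for c in sorted(classes, key=lambda c: exact[c] - alloc[c], reverse=True)[:remainder]:
        alloc[c] += 1
    chosen: list = []
    for c in classes:
        members = truth.index[truth == c].to_numpy()
        k = min(alloc[c], len(members))
        chosen.extend(rng.choice(members, size=k, replace=False))
    # top up from unchosen annotated genes if a class was exhausted
    if len(chosen) < n:
        pool = np.setdiff1d(annotated.to_numpy(), np.asarray(chosen))
        chosen.extend(rng.choice(pool, size=n - len(chosen), replace=False))
    chosen = pd.Index(chosen)
    return true_labels.loc[chosen].copy()


def generate_world(config: SynthConfig) -> SyntheticWorld:
    """Generate a reproducible two-species synthetic world.

    The source species ("spA") plays the role of the well-annotated model
    organism: its observed labels equal its true labels.  The target species
    ("spB") is the information-poor species: its SM/GM labels are corrupted
    at the configured asymmetric rates, and it carries the benchmark subset.
    In the target, a ``cross_species_fidelity`` fraction of the informative
    shared features keep their class effect; the remainder lose it (their
    effect is zeroed), emulating lineage-specific biology.  Private features
    are always uninformative between species (each species' private columns
    are drawn with the same within-species effects but never enter the
    shared list).
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(6)
    rng_layout = np.random.default_rng(children[0])
    rng_src = np.random.default_rng(children[1])
    rng_tgt = np.random.default_rng(children[2])
    rng_corrupt = np.random.default_rng(children[3])
    rng_bench = np.random.default_rng(children[4])

    meta = _feature_layout(config)
    effects = _informative_effects(config, rng_layout)

    # target-species effects: keep a fidelity fraction of informative features
    informative = effects.index[effects != 0.0].to_numpy()
    n_keep = int(round(config.cross_species_fidelity * len(informative)))
    kept = rng_layout.choice(informative, size=n_keep, replace=False) if len(informative) else []
    effects_target = pd.Series(0.0, index=effects.index)
    effects_target.loc[list(kept)] = effects.loc[list(kept)]

    species = {}
    for name, n, eff, rng in (
        ("spA", config.n_genes_source, effects, rng_src),
        ("spB", config.n_genes_target, effects_target, rng_tgt),
    ):
        true, roles = _draw_true_labels(n, config, rng)
        genes = pd.Index([f"{name}_g{i:05d}" for i in range(n)], name="gene_id")
        true.index = genes
        roles.index = genes
        values = _draw_features(true, eff, meta, rng)
        values.index = genes
        observed = true.copy()
        observed[roles == UNANNOTATED] = UNANNOTATED
        species[name] = SpeciesData(
            name=name,
            genes=genes,
            true_labels=true,
            observed_labels=observed,
            features=FeatureTable(values=values, meta=meta.copy()),
        )

    target = species["spB"]
    unann_mask = target.observed_labels == UNANNOTATED
    target.observed_labels = corrupt_labels(
        target.true_labels, config.eps_gm_to_sm, config.eps_sm_to_gm, rng_corrupt
    )
    # corruption applies to annotated SM/GM labels only; restore the unannotated mask
    target.observed_labels[unann_mask] = UNANNOTATED
    target.benchmark = make_benchmark_subset(
        target.observed_labels, target.true_labels, config.benchmark_n, rng_bench
    )
    source = species["spA"]
    source.benchmark = make_benchmark_subset(
        source.observed_labels, source.true_labels, config.benchmark_n, rng_bench
    )

    shared = meta.index[meta["shared"]].tolist()
    return SyntheticWorld(source=source, target=target, shared_features=shared, config=config)


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write a world to a directory of tab-delimited UTF-8 files.

    Layout: ``features_<species>.tsv`` (genes x features, gene id first
    column), ``labels_<species>.tsv`` (gene_id, observed_label, true_label),
    ``shared_features.txt`` (one name per line), ``benchmark.tsv``
    (species, gene_id, true_label).  Missing values are empty strings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in (world.source, world.target):
        sp.features.values.to_csv(outdir / f"features_{sp.name}.tsv", sep="\t", na_rep="")
        labels = pd.DataFrame(
            {"observed_label": sp.observed_labels, "true_label": sp.true_labels}
        )
        labels.index.name = "gene_id"
        labels.to_csv(outdir / f"labels_{sp.name}.tsv", sep="\t")
    (outdir / "shared_features.txt").write_text("\n".join(world.shared_features) + "\n")
    bench = pd.concat(
        [
            pd.DataFrame(
                {"species": sp.name, "gene_id": sp.benchmark.index, "true_label": sp.benchmark.values}
            )
            for sp in (world.source, world.target)
        ],
        ignore_index=True,
    )
    bench.to_csv(outdir / "benchmark.tsv", sep="\t", index=False)


def config_to_dict(config: SynthConfig) -> dict:
    return dataclasses.asdict(config)
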
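"""End-to-end wiring: layers -> fusion -> solver -> evaluation.

This module owns the workflow the command-line interface exposes. The
label-independent stages (base and gene layers) are computed once; the
label-dependent stages (treatment layer, prior, solver) are recomputed for
every training label matrix so cross-validation never leaks held-out
positives into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation, layer_similarity as ls, ssgc_core as core
from .network_data import AssociationMatrix, PairField, SimilarityMatrix
from .synthetic_data import SyntheticDataset, hold_out

__all__ = [
    "LayerParams",
    "PipelineConfig",
    "LayerBundle",
    "compute_label_free_layers",
    "compute_treatment_layers",
    "fuse_subset",
    "build_similarities",
    "predict",
    "evaluate_holdout",
    "cross_validate_pipeline",
    "LAYER_CHOICES",
]

LAYER_CHOICES = ("base", "base+gene", "base+gene+treatment", "all")


@dataclass(frozen=True)
class LayerParams:
    """Kernel, threshold and projection settings with the method defaults.

    Thresholds cut off small similarity scores, which are mostly noise: 0.1
    for the structural (Tanimoto) drug similarity, 0.14 for the phenotype
    disease similarity, 0.01 for both gene-profile similarities, and 0 for
    the treatment layer (its scores are already sparse and high-contrast).
    """

    gene_kernel: ls.KernelParams = ls.GENE_KERNEL
    treatment_kernel: ls.KernelParams = ls.TREATMENT_KERNEL
    tau_bc: float = 0.1
    tau_gc: float = 0.01
    tau_bd: float = 0.14
    tau_gd: float = 0.01
    tau_tc: float = 0.0
    tau_td: float = 0.0
    k_neighbors: int = 5


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration: which layers, which mode, which scalars."""

    layers: str = "all"  # one of LAYER_CHOICES
    mode: str = "ssgc"  # "ssgc" or "hgbi"
    use_prior: bool = True
    layer_params: LayerParams = field(default_factory=LayerParams)
    solver_params: core.SSGCParams = field(default_factory=core.SSGCParams)

    def __post_init__(self) -> None:
        if self.layers not in LAYER_CHOICES:
            raise ValueError(f"layers must be one of {LAYER_CHOICES}")
        if self.mode not in ("ssgc", "hgbi"):
            raise ValueError("mode must be 'ssgc' or 'hgbi'")
        if self.layers != "all" and self.use_prior:
            object.__setattr__(self, "use_prior", False)


@dataclass
class LayerBundle:
    """Label-independent similarity layers plus the raw gene kernel."""

    S_bc: SimilarityMatrix
    S_bd: SimilarityMatrix
    Sg: SimilarityMatrix
    S_gc: SimilarityMatrix
    S_gd: SimilarityMatrix
    prior_raw: np.ndarray  # kernel-cosine before masking known positives


def compute_label_free_layers(
    dataset: SyntheticDataset, lp: LayerParams | None = None
) -> LayerBundle:
    """Base and gene layers plus the unmasked prior; none depend on Y."""
    lp = lp or LayerParams()
    S_bc = ls.apply_threshold(ls.tanimoto_similarity(dataset.fingerprints), lp.tau_bc)
    S_bd = ls.apply_threshold(dataset.phenotype, lp.tau_bd)
    Dg = ls.shortest_path_distances(dataset.gene_graph, mode="unipartite")
    Sg = ls.perlman_kernel(Dg, lp.gene_kernel)
    S_gc = ls.apply_threshold(
        ls.profile_kernel_similarity(dataset.drug_gene, Sg), lp.tau_gc
    )
    S_gd = ls.apply_threshold(
        ls.profile_kernel_similarity(dataset.disease_gene, Sg), lp.tau_gd
    )
    prior_raw = ls.kernel_cosine(
        dataset.drug_gene.values, Sg.values, dataset.disease_gene.values
    )
    return LayerBundle(S_bc, S_bd, Sg, S_gc, S_gd, prior_raw)


def compute_treatment_layers(
    Y_train: PairField,
    ref_drug: SimilarityMatrix,
    ref_disease: SimilarityMatrix,
    lp: LayerParams | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Treatment-layer similarities over the full registries.

    Computed on the entities with >= 1 training positive and projected onto
    the rest using the base-layer similarities as the reference space.
    """
    lp = lp or LayerParams()
    Y_assoc = AssociationMatrix(Y_train.drugs, Y_train.diseases, Y_train.values)
    S_tc_part, S_td_part = ls.treatment_similarity(Y_assoc, lp.treatment_kernel)
    S_tc = ls.project_to_full(S_tc_part, ref_drug, lp.k_neighbors)
    S_td = ls.project_to_full(S_td_part, ref_disease, lp.k_neighbors)
    return (
        ls.apply_threshold(S_tc, lp.tau_tc),
        ls.apply_threshold(S_td, lp.tau_td),
    )


def fuse_subset(
    layers: dict[str, SimilarityMatrix], include: tuple[str, ...]
) -> tuple[SimilarityMatrix, dict[str, float]]:
    """Convex combination of a subset of layers with inverse-mean weights.

    With a single layer this is the identity; with all three it reduces to
    the standard equal-contribution fusion.
    """
    mats = [layers[k] for k in include]
    if len(mats) == 1:
        return mats[0], {include[0]: 1.0}
    means = [ls.off_diagonal_mean(S) for S in mats]
    if any(x <= 0 for x in means):
        raise ValueError("a layer with zero off-diagonal mean cannot be weighted")
    inv = np.array([1.0 / x for x in means])
    w = inv / inv.sum()
    fused = sum(wk * S.values for wk, S in zip(w, mats))
    out = SimilarityMatrix.from_raw(mats[0].registry, fused, layer_tag="fused")
    return out, dict(zip(include, (float(x) for x in w)))


_LAYER_SETS = {
    "base": ("base",),
    "base+gene": ("base", "gene"),
    "base+gene+treatment": ("base", "gene", "treatment"),
    "all": ("base", "gene", "treatment"),
}


def build_similarities(
    bundle: LayerBundle,
    Y_train: PairField,
    config: PipelineConfig,
) -> tuple[SimilarityMatrix, SimilarityMatrix, dict[str, dict[str, float]]]:
    """Fused comprehensive Sc and Sd for the configured layer subset."""
    include = _LAYER_SETS[config.layers]
    drug_layers = {"base": bundle.S_bc, "gene": bundle.S_gc}
    disease_layers = {"base": bundle.S_bd, "gene": bundle.S_gd}
    if "treatment" in include:
        S_tc, S_td = compute_treatment_layers(
            Y_train, bundle.S_bc, bundle.S_bd, config.layer_params
        )
        drug_layers["treatment"] = S_tc
        disease_layers["treatment"] = S_td
    Sc, w_c = fuse_subset(drug_layers, include)
    Sd, w_d = fuse_subset(disease_layers, include)
    return Sc, Sd, {"drug": w_c, "disease": w_d}


def predict(
    bundle: LayerBundle,
    Y_train: PairField,
    config: PipelineConfig,
) -> tuple[core.PredictionResult, dict[str, dict[str, float]]]:
    """Fuse the configured layers and run the configured solver."""
    Sc, Sd, weights = build_similarities(bundle, Y_train, config)
    if config.mode == "hgbi":
        result = core.hgbi_mode_solve(Sc, Sd, Y_train, config.solver_params)
        return result, weights
    if config.use_prior:
        P_vals = np.where(Y_train.values > 0, 0.0, bundle.prior_raw)
        P = PairField(Y_train.drugs, Y_train.diseases, P_vals)
    else:
        P = PairField.zeros(Y_train.drugs, Y_train.diseases)
    result = core.ssgc_solve(Sc, Sd, Y_train, P, config.solver_params)
    return result, weights


def evaluate_holdout(
    dataset: SyntheticDataset,
    config: PipelineConfig,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    bundle: LayerBundle | None = None,
) -> tuple[evaluation.RocCurve, int, core.PredictionResult]:
    """Hold out a fraction of positives, retrain, and evaluate the ranking.

    Returns the PU ROC over the non-training pairs, the number of held-out
    positives retrieved in the top 1% of the ranking, and the solver result.
    """
    bundle = bundle or compute_label_free_layers(dataset, config.layer_params)
    Y_train, held = hold_out(dataset.Y, holdout_fraction, seed)
    result, _ = predict(bundle, Y_train, config)
    eval_mask = Y_train.values == 0
    y_eval = np.zeros_like(dataset.Y.values)
    for i, j in held:
        y_eval[i, j] = 1.0
    curve = evaluation.modified_roc(result.scores.values, y_eval, mask=eval_mask)
    train_pos = list(zip(*np.nonzero(Y_train.values)))
    retrieved = evaluation.top_percent_retrieval(
        result.scores, held, 1.0, exclude=train_pos
    )
    return curve, retrieved, result


def cross_validate_pipeline(
    dataset: SyntheticDataset,
    config: PipelineConfig,
    k: int = 10,
    seed: int = 0,
) -> evaluation.CrossValidationResult:
    """k-fold PU cross-validation of the configured pipeline.

    The base and gene layers are fold-invariant (they do not read Y); the
    treatment layer and the prior are rebuilt per fold from the training
    labels only.
    """
    bundle = compute_label_free_layers(dataset, config.layer_params)
    folds = evaluation.make_folds(dataset.Y, k, seed)

    def train_predict(Y_train: PairField) -> PairField:
        result, _ = predict(bundle, Y_train, config)
        return result.scores

    return evaluation.cross_validate(train_predict, dataset.Y, folds)
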
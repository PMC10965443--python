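"""Planted-truth simulators for every pipeline stage.

The generative model carries the features of droplet scRNA-seq that matter
for network inference: a sparse signed TF -> gene weight matrix drives
per-cell gene rates through latent TF activities; activities co-vary along
a low-dimensional cell-state manifold (as real cells do — this is what
makes nearest-neighbor super-cell pooling recover signal rather than
average it away); counts are gamma-Poisson (negative binomial) at a
realistic library size; and excess zeros are injected by Bernoulli
dropout.  Perturbations (knockout / overexpression) act on the latent TF
activity, never on the priors, mirroring how biological perturbation
experiments are analyzed: the same prior knowledge, different cells.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import sklearn.metrics

from .io import ExpressionMatrix, Network, PriorEdgeList

__all__ = [
    "PlantedGRN",
    "SimulationConfig",
    "generate_truth",
    "plant_master_regulator",
    "simulate_counts",
    "corrupt_prior",
    "prior_edge_list",
    "empty_ppi_prior",
    "evaluate_recovery",
    "write_simulation",
]

MIN_EFFECT = 0.5  # smallest |weight| a planted edge may carry


@dataclass
class PlantedGRN:
    """Ground-truth regulatory structure for a simulation."""

    true_weights: np.ndarray  # TF x gene, signed; zero = no edge
    tf_activity_mean: np.ndarray  # per-TF baseline activity
    density: float
    tf_ids: np.ndarray = None
    gene_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        n_tfs, n_genes = self.true_weights.shape
        if self.tf_ids is None:
            self.tf_ids = np.array([f"TF{i:03d}" for i in range(n_tfs)], dtype=object)
        if self.gene_ids is None:
            self.gene_ids = np.array(
                [f"G{j:04d}" for j in range(n_genes)], dtype=object
            )
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        nz = self.true_weights[self.true_weights != 0]
        if nz.size and np.abs(nz).min() < MIN_EFFECT - 1e-12:
            raise ValueError(f"planted edges must have |weight| >= {MIN_EFFECT}")

    @property
    def support(self) -> np.ndarray:
        return (self.true_weights != 0).astype(int)


@dataclass
class SimulationConfig:
    """Dimensions and noise levels of one simulated dataset.

    Defaults describe a desk-scale droplet experiment: 2,000 cells over
    200 genes driven by 20 TFs, ~10% of TF-gene pairs regulatory, 60%
    dropout, a 5,000-count median library, and negative-binomial counting
    noise.  ``noise_sd`` is the SD of log TF activity across cells (1.2
    corresponds to the ~3-10x activity range typical across cell states);
    a fraction ``state_share`` of that variance is shared along a
    ``latent_dim``-dimensional cell-state manifold, the rest is
    TF-private.
    """

    n_tfs: int = 20
    n_genes: int = 200
    n_cells: int = 2000
    density: float = 0.1
    dropout_rate: float = 0.6
    noise_sd: float = 1.2
    state_share: float = 0.8
    latent_dim: int = 6
    overdispersion: float = 0.15
    library_size_mean: float = 5000.0
    seed: int = 0
    perturbation: tuple | None = None  # ("knockout", tf) | ("overexpress", tf, factor)

    def __post_init__(self) -> None:
        if min(self.n_tfs, self.n_genes, self.n_cells) < 2:
            raise ValueError("all dimensions must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd <= 0 or self.library_size_mean <= 0:
            raise ValueError("noise_sd and library_size_mean must be positive")
        if not 0 <= self.state_share <= 1:
            raise ValueError("state_share must be in [0, 1]")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.perturbation is not None:
            kind = self.perturbation[0]
            if kind not in ("knockout", "overexpress"):
                raise ValueError(f"unknown perturbation {kind!r}")


def generate_truth(config: SimulationConfig) -> PlantedGRN:
    """Draw a sparse signed TF -> gene weight matrix at the requested density."""
    if config.density * config.n_tfs * config.n_genes < 1:
        raise ValueError("density too low: expected edge count below 1")
    rng = np.random.default_rng([config.seed, 0])
    mask = rng.random((config.n_tfs, config.n_genes)) < config.density
    if not mask.any():
        mask[0, 0] = True
    signs = rng.choice([-1.0, 1.0], size=mask.shape, p=[0.3, 0.7])
    magnitude = rng.uniform(MIN_EFFECT, 4 * MIN_EFFECT, size=mask.shape)
    weights = np.where(mask, signs * magnitude, 0.0)
    activity = rng.uniform(0.5, 1.5, size=config.n_tfs)
    return PlantedGRN(weights, activity, config.density)


def plant_master_regulator(
    truth: PlantedGRN,
    config: SimulationConfig,
    tf: int = 0,
    coverage: float = 0.25,
    exclusivity: float = 0.9,
) -> PlantedGRN:
    """Turn one TF into a master regulator, as in knockout/overexpression
    perturbation studies.

    The chosen TF gets an activating program covering ``coverage`` of the
    gene universe; a fraction ``exclusivity`` of those targets lose their
    other regulators, so the program genuinely depends on the TF — the
    regime in which perturbing it produces the cell-state collapse such
    experiments are designed around.
    """
    rng = np.random.default_rng([config.seed, 3])
    weights = truth.true_weights.copy()
    n_genes = weights.shape[1]
    program = rng.random(n_genes) < coverage
    weights[tf] = np.where(
        program, rng.uniform(2 * MIN_EFFECT, 4 * MIN_EFFECT, n_genes), 0.0
    )
    exclusive = program & (rng.random(n_genes) < exclusivity)
    others = np.arange(weights.shape[0]) != tf
    weights[np.ix_(others, exclusive)] = 0.0
    return PlantedGRN(
        weights, truth.tf_activity_mean, truth.density, truth.tf_ids, truth.gene_ids
    )


def _softplus(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(x)); keeps rates finite at desk scale
    return np.logaddexp(0.0, x)


def _resolve_tf(truth: PlantedGRN, tf) -> int:
    if isinstance(tf, (int, np.integer)):
        return int(tf)
    hits = np.flatnonzero(truth.tf_ids == tf)
    if len(hits) != 1:
        raise ValueError(f"unknown TF {tf!r}")
    return int(hits[0])


def simulate_counts(
    truth: PlantedGRN, config: SimulationConfig, seed: int | None = None
) -> ExpressionMatrix:
    """Simulate a genes x cells sparse count matrix from the planted truth.

    Per cell: log TF activities are Gaussian around log of the per-TF
    baseline, with a ``state_share`` fraction of their variance shared
    along a low-dimensional latent cell-state manifold (TF loadings drawn
    once per truth, so replicates share the same biology); perturbations
    zero or scale the targeted TF's activity.  Gene rates are
    ``softplus(activity @ W)``, modulated by gamma overdispersion and
    rescaled to a lognormal library size; counts are Poisson and observed
    zeros are inflated by Bernoulli dropout.

    ``seed`` defaults to ``config.seed``; pass a different one to draw an
    independent replicate from the same truth.
    """
    if seed is None:
        seed = config.seed
    n_cells, n_tfs = config.n_cells, truth.true_weights.shape[0]
    k = config.latent_dim

    # manifold loadings belong to the truth, not the replicate
    load_rng = np.random.default_rng([config.seed, 4])
    loadings = load_rng.standard_normal((n_tfs, k)) / np.sqrt(k)

    rng = np.random.default_rng([seed, 1])
    state = rng.standard_normal((n_cells, k))
    private = rng.standard_normal((n_cells, n_tfs))
    log_noise = config.noise_sd * (
        np.sqrt(config.state_share) * state @ loadings.T
        + np.sqrt(1.0 - config.state_share) * private
    )
    activity = truth.tf_activity_mean[None, :] * np.exp(log_noise)
    if config.perturbation is not None:
        kind = config.perturbation[0]
        idx = _resolve_tf(truth, config.perturbation[1])
        if kind == "knockout":
            activity[:, idx] = 0.0
        else:
            factor = config.perturbation[2] if len(config.perturbation) > 2 else 2.0
            activity[:, idx] *= factor

    rates = _softplus(activity @ truth.true_weights)  # cells x genes
    if config.overdispersion > 0:
        phi = config.overdispersion
        rates = rates * rng.gamma(1.0 / phi, phi, size=rates.shape)
    lib = rng.lognormal(mean=np.log(config.library_size_mean), sigma=0.3, size=n_cells)
    row_sums = rates.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    rates = rates / row_sums[:, None] * lib[:, None]

    counts = rng.poisson(rates).astype(float)
    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts *= keep
    cells = np.array([f"C{i:05d}" for i in range(n_cells)], dtype=object)
    return ExpressionMatrix(sp.csr_matrix(counts.T), truth.gene_ids, cells)


def prior_edge_list(
    support: np.ndarray, truth: PlantedGRN, score: float = 1.0
) -> PriorEdgeList:
    """Wrap a binary TF x gene support matrix as a regulatory edge list."""
    tf_idx, gene_idx = np.nonzero(support)
    frame = pd.DataFrame(
        {
            "source": truth.tf_ids[tf_idx],
            "target": truth.gene_ids[gene_idx],
            "score": score,
        }
    )
    return PriorEdgeList(frame, "regulatory")


def empty_ppi_prior() -> PriorEdgeList:
    """A cooperativity prior with no off-diagonal evidence.

    The generative model plants no TF-TF cooperation, so the honest
    cooperativity prior is self-cooperation only (the aligned dense prior
    becomes the identity-scaled diagonal).
    """
    return PriorEdgeList(
        pd.DataFrame(columns=["source", "target", "score"]), "cooperativity"
    )


def corrupt_prior(
    truth: PlantedGRN,
    mode: str = "exact",
    seed: int = 0,
    fpr: float = 0.0,
    fnr: float = 0.0,
    n_swap_rounds: int = 10,
) -> PriorEdgeList:
    """Derive a motif prior from the planted truth, optionally degraded.

    ``exact``: the binarized truth support.  ``noisy``: each absent pair
    turns on with probability ``fpr`` and each true edge drops with
    probability ``fnr``.  ``randomized``: a degree-preserving shuffle of
    the binary support (checkerboard swaps keep every row and column sum),
    the standard negative control for prior informativeness.
    """
    support = truth.support.copy()
    rng = np.random.default_rng([seed, 2])
    if mode == "exact":
        pass
    elif mode == "noisy":
        if not (0 <= fpr < 1 and 0 <= fnr < 1):
            raise ValueError("fpr and fnr must be in [0, 1)")
        flips_on = (support == 0) & (rng.random(support.shape) < fpr)
        flips_off = (support == 1) & (rng.random(support.shape) < fnr)
        support[flips_on] = 1
        support[flips_off] = 0
    elif mode == "randomized":
        edges = np.argwhere(support == 1)
        n_edges = len(edges)
        if n_edges >= 2:
            for _ in range(n_swap_rounds * n_edges):
                k1, k2 = rng.integers(0, n_edges, size=2)
                (r1, c1), (r2, c2) = edges[k1], edges[k2]
                if r1 == r2 or c1 == c2:
                    continue
                if support[r1, c2] or support[r2, c1]:
                    continue
                support[r1, c1] = support[r2, c2] = 0
                support[r1, c2] = support[r2, c1] = 1
                edges[k1] = (r1, c2)
                edges[k2] = (r2, c1)
    else:
        raise ValueError(f"unknown prior mode {mode!r}")
    return prior_edge_list(support, truth)


def evaluate_recovery(
    net: Network | pd.DataFrame, truth: PlantedGRN
) -> tuple[float, float]:
    """AUROC and AUPRC of |refined weight| against the planted edge support.

    Scores are absolute values because refined weights are signed z-units
    while the truth support is binary presence.
    """
    frame = net.to_frame() if isinstance(net, Network) else net
    truth_frame = pd.DataFrame(
        truth.support, index=truth.tf_ids, columns=truth.gene_ids
    )
    tfs = frame.index.intersection(truth_frame.index)
    genes = frame.columns.intersection(truth_frame.columns)
    if len(tfs) == 0 or len(genes) == 0:
        raise ValueError("network and truth share no labels")
    scores = np.abs(frame.loc[tfs, genes].to_numpy(dtype=float)).ravel()
    labels = truth_frame.loc[tfs, genes].to_numpy().ravel()
    if labels.min() == labels.max():
        raise ValueError("truth support is single-class on the shared universe")
    auroc = sklearn.metrics.roc_auc_score(labels, scores)
    precision, recall, _ = sklearn.metrics.precision_recall_curve(labels, scores)
    auprc = sklearn.metrics.auc(recall, precision)
    return float(auroc), float(auprc)


def write_simulation(
    directory: str | Path, config: SimulationConfig, prior_mode: str = "exact"
) -> None:
    """Write a complete simulated dataset to ``directory``.

    Produces the 10x-style counts triplet, the motif and PPI prior TSVs,
    the planted truth as TSV, and the config as JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    expr = simulate_counts(truth, config)
    import scipy.io

    scipy.io.mmwrite(directory / "matrix.mtx", expr.values)
    with open(directory / "features.tsv", "w") as handle:
        handle.write("\n".join(str(g) for g in expr.gene_ids) + "\n")
    with open(directory / "barcodes.tsv", "w") as handle:
        handle.write("\n".join(str(c) for c in expr.cell_ids) + "\n")
    motif = corrupt_prior(truth, prior_mode, seed=config.seed)
    motif.edges.to_csv(directory / "motif_prior.tsv", sep="\t", index=False)
    empty_ppi_prior().edges.to_csv(directory / "ppi_prior.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.true_weights, index=truth.tf_ids, columns=truth.gene_ids
    ).to_csv(directory / "truth.tsv", sep="\t")
    cfg = asdict(config)
    cfg["perturbation"] = list(config.perturbation) if config.perturbation else None
    with open(directory / "config.json", "w") as handle:
        json.dump(cfg, handle, indent=2, sort_keys=True)
        handle.write("\n")
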
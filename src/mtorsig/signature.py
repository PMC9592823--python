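"""In vitro everolimus-response signature: correlation-selected genes,
SVD metagenes, and Bayesian probit regression fitted by Gibbs sampling.

The model follows the Bayesian binary-regression ("binreg") framework of
West-style expression signatures: genes most correlated with the binary
treatment status form the signature, the first k principal components
(metagenes) of the quantile-normalized signature submatrix summarize each
sample, and a probit regression of treatment status on the metagene scores
is fitted with the Albert–Chib latent-variable Gibbs sampler

    z_i | beta ~ Normal(x_i' beta, 1), truncated positive for treated
                 samples and negative for controls,
    beta | z   ~ Normal(A^{-1} X'z, A^{-1}),  A = X'X + I / tau^2,

under a diffuse prior beta ~ Normal(0, tau^2 I). Predictions average
Phi(x' beta) over post-burn-in draws, with 95% intervals from the draw-level
probability percentiles.

`SignatureModel` is the user-facing model object (fit() -> SignatureResults);
the module-level functions are the individual pipeline steps it composes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .expression import (ExpressionMatrix, QuantileReference, quantile_normalize)

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "SignatureGeneSet",
    "MetageneBasis",
    "MetageneScores",
    "BinregPosterior",
    "PosteriorPrediction",
    "LOOCVReport",
    "SignatureModel",
    "SignatureResults",
    "select_signature_genes",
    "compute_metagenes",
    "project_new_samples",
    "fit_binreg",
    "predict_binreg",
    "loocv_cell_lines",
]

CONDITION_CODES = {"control": 0, "treated": 1}


@dataclass
class MCMCConfig:
    """Gibbs-sampler settings: iterations, burn-in, prior variance tau^2, seed."""

    n_iter: int = 5000
    n_burn: int = 1000
    prior_variance: float = 100.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be positive")


@dataclass
class SignatureGeneSet:
    """Signature genes with direction and Pearson r against treatment."""

    genes: list[str]
    direction: dict[str, str]  # gene -> up_in_treated / down_in_treated
    correlation: dict[str, float]

    def __post_init__(self) -> None:
        for g in self.genes:
            r, d = self.correlation[g], self.direction[g]
            if (r > 0) != (d == "up_in_treated") and r != 0:
                raise ValueError(f"direction of {g} disagrees with correlation sign")

    @property
    def up_genes(self) -> list[str]:
        return [g for g in self.genes if self.direction[g] == "up_in_treated"]

    @property
    def down_genes(self) -> list[str]:
        return [g for g in self.genes if self.direction[g] == "down_in_treated"]


@dataclass
class MetageneBasis:
    """Left singular vectors (unit-norm loadings) of the centered signature
    submatrix, plus the gene means used for centering."""

    gene_ids: list[str]
    loadings: np.ndarray  # genes x k
    singular_values: np.ndarray
    training_gene_means: np.ndarray

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass
class MetageneScores:
    """Per-sample metagene scores (the probit regression design)."""

    sample_ids: list[str]
    scores: np.ndarray  # samples x k


@dataclass
class BinregPosterior:
    """Post-burn-in coefficient draws (intercept first)."""

    beta_draws: np.ndarray  # draws x (k+1)
    mcmc_config: MCMCConfig

    @property
    def mean(self) -> np.ndarray:
        return self.beta_draws.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.beta_draws.std(axis=0, ddof=1)


@dataclass
class PosteriorPrediction:
    """Posterior predictive response probability with a 95% interval."""

    probability: float
    ci_low: float
    ci_high: float


@dataclass
class LOOCVReport:
    """Out-of-fold predictions, one row per held-out sample."""

    table: pd.DataFrame  # sample_id, probability, ci_low, ci_high, predicted, truth
    fold_features: dict[str, list[str]]

    @property
    def accuracy(self) -> float:
        return float((self.table["predicted"] == self.table["truth"]).mean())

    @property
    def n_folds(self) -> int:
        return len(self.table)


def _condition_vector(labels, sample_ids: Sequence[str]) -> np.ndarray:
    """Coerce condition labels (sequence or mapping) into a 0/1 vector."""
    if isinstance(labels, dict):
        labels = [labels[s] for s in sample_ids]
    elif isinstance(labels, pd.Series):
        labels = labels.reindex(list(sample_ids)).tolist()
    y = np.array([CONDITION_CODES.get(str(v), v) for v in labels])
    y = y.astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be control/treated or 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) != len(sample_ids):
        raise ValueError("label length does not match samples")
    return y


def select_signature_genes(matrix: ExpressionMatrix, labels,
                           n_genes: int = 100) -> SignatureGeneSet:
    """Select the signature genes most correlated with treatment status.

    Genes are ranked by Pearson correlation with the 0/1 treatment label;
    the n_genes/2 most positively and n_genes/2 most negatively correlated
    genes are kept (balanced split), ties broken lexicographically by id.
    """
    if n_genes % 2:
        raise ValueError("n_genes must be even for the balanced up/down split")
    if n_genes > matrix.n_genes:
        raise ValueError(f"n_genes={n_genes} exceeds gene count {matrix.n_genes}")
    y = _condition_vector(labels, matrix.sample_ids)
    yc = y - y.mean()
    xc = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ yc) / denom, 0.0)

    order = sorted(range(matrix.n_genes), key=lambda i: (-r[i], matrix.gene_ids[i]))
    half = n_genes // 2
    up = order[:half]
    down = sorted(range(matrix.n_genes), key=lambda i: (r[i], matrix.gene_ids[i]))[:half]
    if set(up) & set(down):
        raise ValueError("up/down selections overlap; too few distinct genes")
    chosen = up + down
    up_set = set(up)
    genes = [matrix.gene_ids[i] for i in chosen]
    direction = {matrix.gene_ids[i]: ("up_in_treated" if i in up_set else "down_in_treated")
                 for i in chosen}
    correlation = {matrix.gene_ids[i]: float(r[i]) for i in chosen}
    return SignatureGeneSet(genes, direction, correlation)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic SVD sign convention: the largest-|value| entry of each
    loading column is made positive (in place)."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def compute_metagenes(matrix: ExpressionMatrix, k: int = 2,
                      ) -> tuple[MetageneBasis, MetageneScores]:
    """Metagenes of the signature submatrix via SVD.

    Genes are centered by their training means; the first k left singular
    vectors are the loadings and the per-sample scores are the projections
    (right singular vectors scaled by singular values). A numerically
    rank-deficient matrix yields zero trailing columns.
    """
    if k < 1 or k > min(matrix.n_genes, matrix.n_samples):
        raise ValueError(f"k={k} must lie in [1, min(genes, samples)]")
    means = matrix.values.mean(axis=1)
    centered = matrix.values - means[:, None]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = u[:, :k].copy()
    scores = (vt[:k].T * s[:k]).copy()
    _fix_signs(loadings, scores)
    basis = MetageneBasis(list(matrix.gene_ids), loadings, s[:k].copy(), means)
    return basis, MetageneScores(list(matrix.sample_ids), scores)


def project_new_samples(basis: MetageneBasis, reference: QuantileReference,
                        new_matrix: ExpressionMatrix,
                        reference_genes: Optional[Sequence[str]] = None,
                        ) -> MetageneScores:
    """Score new samples against a fitted basis without refitting.

    Each new column is quantile-mapped onto the frozen training reference
    (over ``reference_genes``, the gene universe the normalization was
    trained on; defaults to the basis genes), then restricted to the basis
    genes, centered by the training gene means and projected onto the
    loadings.
    """
    genes = list(reference_genes) if reference_genes is not None else list(basis.gene_ids)
    missing = sorted(set(genes) - set(new_matrix.gene_ids))
    if missing:
        raise KeyError(f"new matrix lacks basis genes: {missing[:10]}")
    sub = new_matrix.select_genes(genes)
    normalized, _ = quantile_normalize(sub, reference)
    sig = normalized.select_genes(list(basis.gene_ids))
    centered = sig.values - basis.training_gene_means[:, None]
    return MetageneScores(list(new_matrix.sample_ids), centered.T @ basis.loadings)


def _sample_truncnorm(rng: np.random.Generator, mean: np.ndarray,
                      positive: np.ndarray) -> np.ndarray:
    """Unit-variance normals truncated to (0, inf) or (-inf, 0] by inverse CDF."""
    p_neg = np.clip(ndtr(-mean), 1e-12, 1 - 1e-12)
    u = rng.random(mean.size)
    p = np.where(positive, p_neg + u * (1 - p_neg), u * p_neg)
    return mean + ndtri(np.clip(p, 1e-12, 1 - 1e-12))


def fit_binreg(scores: MetageneScores, labels,
               config: Optional[MCMCConfig] = None) -> BinregPosterior:
    """Bayesian probit regression on metagene scores via Albert–Chib Gibbs.

    Identical seeds give bitwise-identical draws. Degenerate designs whose
    score columns are constant across samples are rejected.
    """
    config = config or MCMCConfig()
    y = _condition_vector(labels, scores.sample_ids)
    X = np.column_stack([np.ones(len(y)), scores.scores])
    if np.any(X[:, 1:].std(axis=0) == 0):
        raise ValueError("metagene scores are constant; probit fit is degenerate")

    rng = np.random.default_rng(config.seed)
    p = X.shape[1]
    A = X.T @ X + np.eye(p) / config.prior_variance
    L = np.linalg.cholesky(np.linalg.inv(A))
    AinvXt = np.linalg.solve(A, X.T)
    positive = y == 1

    beta = np.zeros(p)
    draws = np.empty((config.n_iter - config.n_burn, p))
    for it in range(config.n_iter):
        z = _sample_truncnorm(rng, X @ beta, positive)
        beta = AinvXt @ z + L @ rng.standard_normal(p)
        if it >= config.n_burn:
            draws[it - config.n_burn] = beta
    return BinregPosterior(draws, config)


def predict_binreg(posterior: BinregPosterior, new_scores: MetageneScores,
                   ) -> list[PosteriorPrediction]:
    """Posterior predictive probability Phi(x'beta) averaged over draws,
    with 2.5/97.5 percentile interval of the draw-level probabilities."""
    X = np.column_stack([np.ones(len(new_scores.sample_ids)), new_scores.scores])
    if X.shape[1] != posterior.beta_draws.shape[1]:
        raise ValueError(
            f"score dimension {X.shape[1] - 1} does not match posterior "
            f"{posterior.beta_draws.shape[1] - 1}"
        )
    probs = ndtr(X @ posterior.beta_draws.T)  # samples x draws
    lo, hi = np.percentile(probs, [2.5, 97.5], axis=1)
    return [PosteriorPrediction(float(p), float(l), float(h))
            for p, l, h in zip(probs.mean(axis=1), lo, hi)]


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class SignatureModel:
    """Everolimus-response signature model for treated-vs-control cell lines.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Filtered log-expression (genes x samples); quantile normalization is
        applied internally and its reference frozen into the results.
    conditions : sequence, mapping or Series
        Per-sample ``control``/``treated`` labels (or 0/1).
    n_genes : int
        Signature size (balanced: half up-, half down-regulated).
    n_metagenes : int
        Number of SVD metagenes used as probit predictors.
    mcmc : MCMCConfig, optional
        Gibbs-sampler settings.
    """

    def __init__(self, matrix: ExpressionMatrix, conditions, n_genes: int = 100,
                 n_metagenes: int = 2, mcmc: Optional[MCMCConfig] = None):
        self.matrix = matrix
        self.conditions = _condition_vector(conditions, matrix.sample_ids)
        self.n_genes = n_genes
        self.n_metagenes = n_metagenes
        self.mcmc = mcmc or MCMCConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conditions, **kwargs) -> "SignatureModel":
        return cls(ExpressionMatrix.from_dataframe(df), conditions, **kwargs)

    def fit(self, seed: Optional[int] = None) -> "SignatureResults":
        mcmc = self.mcmc if seed is None else MCMCConfig(
            self.mcmc.n_iter, self.mcmc.n_burn, self.mcmc.prior_variance, seed)
        normalized, reference = quantile_normalize(self.matrix)
        gene_set = select_signature_genes(normalized, self.conditions, self.n_genes)
        basis, scores = compute_metagenes(normalized.select_genes(gene_set.genes),
                                          self.n_metagenes)
        posterior = fit_binreg(scores, self.conditions, mcmc)
        return SignatureResults(self, gene_set, basis, scores, posterior,
                                reference, list(self.matrix.gene_ids))

    def loocv(self, seed: Optional[int] = None) -> LOOCVReport:
        """Leave-one-cell-line-sample-out CV with per-fold reselection.

        Each fold re-runs quantile normalization, gene selection, metagene
        computation and the probit fit on the training samples only; the
        held-out sample is projected onto the frozen fold normalization.
        """
        if self.matrix.n_samples < 4:
            raise ValueError("LOOCV needs at least 4 samples")
        rows = []
        fold_features: dict[str, list[str]] = {}
        for j, sid in enumerate(self.matrix.sample_ids):
            train_mask = np.ones(self.matrix.n_samples, dtype=bool)
            train_mask[j] = False
            y_train = self.conditions[train_mask]
            if len(np.unique(y_train)) < 2:
                raise ValueError(f"fold holding out {sid} loses a class")
            train = self.matrix.drop_samples([sid])
            submodel = SignatureModel(train, y_train, self.n_genes,
                                      self.n_metagenes, self.mcmc)
            res = submodel.fit(seed)
            pred = res.predict(self.matrix.select_samples([sid]))[0]
            fold_features[sid] = list(res.gene_set.genes)
            rows.append({
                "sample_id": sid,
                "probability": pred.probability,
                "ci_low": pred.ci_low,
                "ci_high": pred.ci_high,
                "predicted": "treated" if pred.probability > 0.5 else "control",
                "truth": "treated" if self.conditions[j] == 1 else "control",
            })
        return LOOCVReport(pd.DataFrame(rows), fold_features)


class SignatureResults:
    """Fitted in vitro signature: gene set, metagene basis, probit posterior
    and the frozen quantile reference needed to score new samples."""

    def __init__(self, model: SignatureModel, gene_set: SignatureGeneSet,
                 basis: MetageneBasis, scores: MetageneScores,
                 posterior: BinregPosterior, quantile_reference: QuantileReference,
                 training_genes: list[str]):
        self.model = model
        self.gene_set = gene_set
        self.basis = basis
        self.scores = scores
        self.posterior = posterior
        self.quantile_reference = quantile_reference
        self.training_genes = training_genes

    @property
    def fittedvalues(self) -> list[PosteriorPrediction]:
        return predict_binreg(self.posterior, self.scores)

    def predict(self, new_matrix: ExpressionMatrix) -> list[PosteriorPrediction]:
        new_scores = project_new_samples(self.basis, self.quantile_reference,
                                         new_matrix, self.training_genes)
        return predict_binreg(self.posterior, new_scores)

    def summary(self) -> str:
        mean, sd = self.posterior.mean, self.posterior.sd
        lines = [
            "In vitro everolimus-response signature (Bayesian probit on metagenes)",
            f"  samples: {len(self.scores.sample_ids)}   signature genes: "
            f"{len(self.gene_set.genes)} ({len(self.gene_set.up_genes)} up / "
            f"{len(self.gene_set.down_genes)} down)",
            f"  metagenes: {self.basis.k}   MCMC draws: {self.posterior.beta_draws.shape[0]}"
            f" (seed {self.posterior.mcmc_config.seed})",
            "  coefficient   post.mean   post.sd",
        ]
        names = ["intercept"] + [f"metagene_{i + 1}" for i in range(self.basis.k)]
        for nm, m, s in zip(names, mean, sd):
            lines.append(f"  {nm:<12} {m:>10.4f} {s:>9.4f}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------
    def to_dict(self, include_draws: bool = True) -> dict:
        d = {
            "genes": self.gene_set.genes,
            "direction": self.gene_set.direction,
            "correlation": self.gene_set.correlation,
            "loadings": self.basis.loadings.tolist(),
            "singular_values": self.basis.singular_values.tolist(),
            "training_gene_means": self.basis.training_gene_means.tolist(),
            "training_genes": self.training_genes,
            "quantile_reference": self.quantile_reference.sorted_reference.tolist(),
            "mcmc_config": asdict(self.posterior.mcmc_config),
            "posterior_mean": self.posterior.mean.tolist(),
            "posterior_sd": self.posterior.sd.tolist(),
        }
        if include_draws:
            d["beta_draws"] = self.posterior.beta_draws.tolist()
        return d

    def save(self, path, include_draws: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_draws), fh)

    @classmethod
    def load(cls, path) -> "SignatureResults":
        with open(path) as fh:
            d = json.load(fh)
        gene_set = SignatureGeneSet(d["genes"], d["direction"],
                                    {k: float(v) for k, v in d["correlation"].items()})
        basis = MetageneBasis(d["genes"], np.array(d["loadings"]),
                              np.array(d["singular_values"]),
                              np.array(d["training_gene_means"]))
        cfg = MCMCConfig(**d["mcmc_config"])
        if "beta_draws" in d:
            posterior = BinregPosterior(np.array(d["beta_draws"]), cfg)
        else:
            # posterior summarized only; reconstruct a normal approximation
            rng = np.random.default_rng(cfg.seed)
            mean = np.array(d["posterior_mean"])
            sd = np.array(d["posterior_sd"])
            posterior = BinregPosterior(
                mean + sd * rng.standard_normal((cfg.n_iter - cfg.n_burn, mean.size)), cfg)
        ref = QuantileReference(np.array(d["quantile_reference"]))
        return cls(None, gene_set, basis,
                   MetageneScores([], np.empty((0, basis.k))), posterior, ref,
                   d["training_genes"])


def loocv_cell_lines(matrix: ExpressionMatrix, labels,
                     config: Optional[MCMCConfig] = None, n_genes: int = 100,
                     n_metagenes: int = 2) -> LOOCVReport:
    """Functional wrapper around :meth:`SignatureModel.loocv`."""
    return SignatureModel(matrix, labels, n_genes, n_metagenes, config).loocv()
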
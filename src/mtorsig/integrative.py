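"""Integrative random-forest classifier of clinical everolimus response.

The clinical model fuses two feature sources inside a leakage-free
leave-one-out cross-validation: (1) the in vitro signature genes carried
over from the cell-line stage, and (2) genes selected per training fold by
FCBF against the binary Ki67-derived response label. The union is fed as
raw standardized expression into a random forest whose ``mtry``
(``max_features``) hyperparameter is tuned by repeated stratified k-fold CV
inside each training fold. The fold's held-out patient is never visible to
discretization thresholds, FCBF, tuning or training.

`IntegrativeModel.fit()` returns `IntegrativeResults` (final forest on all
patients) and `IntegrativeModel.loocv()` the out-of-fold report; external
cohorts are scored with `IntegrativeResults.predict` and compared across
groups (one-way ANOVA + Tukey HSD) with `compare_groups`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .expression import ExpressionMatrix, PhenotypeTable, standardize_genes
from .fcbf import FCBFResult, discretize, fcbf_select
from .signature import SignatureGeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ForestConfig",
    "ResponseLabel",
    "IntegratedFeatureSet",
    "TunedForest",
    "PatientLOOCVReport",
    "CohortPrediction",
    "GroupComparison",
    "IntegrativeModel",
    "IntegrativeResults",
    "label_response",
    "build_integrated_features",
    "tune_and_train_rf",
    "compare_groups",
]

RESPONDER, NON_RESPONDER = "responder", "non_responder"


@dataclass
class ForestConfig:
    """Random-forest and selection settings for the integrative model.

    ``mtry_grid`` defaults to all integers 2..min(15, n_features);
    ``inner_folds`` x ``inner_repeats`` define the repeated stratified CV
    used to tune mtry inside each training fold. ``fcbf_delta`` is the FCBF
    relevance threshold on symmetrical uncertainty with the class.
    """

    n_trees: int = 500
    tune_n_trees: Optional[int] = None  # forest size during mtry tuning only
    mtry_grid: Optional[Sequence[int]] = None
    inner_folds: int = 5
    inner_repeats: int = 5
    fcbf_delta: float = 0.25
    seed: int = 17

    def grid_for(self, n_features: int) -> list[int]:
        if self.mtry_grid is not None:
            grid = [m for m in self.mtry_grid if m <= n_features]
            skipped = [m for m in self.mtry_grid if m > n_features]
        else:
            grid = list(range(2, min(15, n_features) + 1)) or [1]
            skipped = []
        if skipped:
            logger.warning("mtry values %s exceed feature count %d; skipped",
                           skipped, n_features)
        if not grid:
            raise ValueError("no usable mtry value for the feature count")
        return grid


@dataclass
class ResponseLabel:
    """Clinical response from on-treatment Ki67 change."""

    sample_id: str
    label: str
    ki67_change: float  # percent decrease (relative or absolute points)


@dataclass
class IntegratedFeatureSet:
    """Union of in vitro signature genes and FCBF-selected genes."""

    genes: list[str]
    provenance: dict[str, str]  # gene -> invitro / fcbf / both

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in integrated feature set")


@dataclass
class TunedForest:
    """A random forest with its tuned mtry and the tuning curve."""

    forest: RandomForestClassifier
    n_trees: int
    mtry_grid: list[int]
    chosen_mtry: int
    internal_cv_accuracy: dict[int, float]
    seed: int

    @property
    def peak_accuracy(self) -> float:
        return self.internal_cv_accuracy[self.chosen_mtry]


@dataclass
class PatientLOOCVReport:
    """Out-of-fold response probabilities, one row per held-out patient."""

    table: pd.DataFrame  # sample_id, prob_response, predicted, truth
    fold_features: dict[str, list[str]]
    fold_mtry: dict[str, int]

    @property
    def accuracy(self) -> float:
        return float((self.table["predicted"] == self.table["truth"]).mean())

    @property
    def n_folds(self) -> int:
        return len(self.table)


@dataclass
class CohortPrediction:
    """Per-sample response probabilities for a scored cohort."""

    probabilities: pd.Series
    high_response_cutoff: float = 0.75
    groups: Optional[pd.Series] = None
    comparison: Optional["GroupComparison"] = None

    @property
    def high_response_flags(self) -> pd.Series:
        return self.probabilities > self.high_response_cutoff


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey-HSD pairwise comparisons across groups."""

    anova_f: float
    anova_p: float
    group_means: dict[str, float]
    pairwise: pd.DataFrame  # group1, group2, mean_diff, p_adj
    high_response_fraction: dict[str, float]
    cutoff: float


# ---------------------------------------------------------------------------
# Response labeling
# ---------------------------------------------------------------------------

def label_response(pheno: PhenotypeTable, threshold_pct: float = 10.0,
                   relative: bool = True) -> list[ResponseLabel]:
    """Label responders from Ki67 change.

    A patient is a responder when the on-treatment Ki67 decrease exceeds
    ``threshold_pct`` — as a fraction of the baseline when ``relative``
    (the default), otherwise in absolute percentage points. Provided
    ``response`` labels are passed through unchanged.
    """
    df = pheno.table
    out: list[ResponseLabel] = []
    has_response = "response" in df.columns
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if has_response and isinstance(row.get("response"), str):
            pre, post = row.get("ki67_pre"), row.get("ki67_post")
            change = float("nan")
            if pd.notna(pre) and pd.notna(post) and pre > 0:
                change = 100.0 * (pre - post) / pre if relative else pre - post
            out.append(ResponseLabel(sid, row["response"], change))
            continue
        pre, post = row.get("ki67_pre"), row.get("ki67_post")
        if pd.isna(pre) or pd.isna(post):
            raise ValueError(f"{sid}: no response label and incomplete Ki67 data")
        if pre <= 0:
            raise ValueError(f"{sid}: ki67_pre must be positive to derive response")
        change = 100.0 * (pre - post) / pre if relative else pre - post
        label = RESPONDER if change > threshold_pct else NON_RESPONDER
        out.append(ResponseLabel(sid, label, float(change)))
    return out


def _response_vector(labels, sample_ids: Sequence[str]) -> np.ndarray:
    """Coerce responder labels into 0/1 (1 = responder) aligned to samples."""
    if isinstance(labels, PhenotypeTable):
        labels = {r.sample_id: r.label for r in label_response(labels)}
    if isinstance(labels, Mapping):
        labels = [labels[s] for s in sample_ids]
    elif isinstance(labels, pd.Series):
        labels = labels.reindex(list(sample_ids)).tolist()
    elif isinstance(labels, list) and labels and isinstance(labels[0], ResponseLabel):
        by_id = {r.sample_id: r.label for r in labels}
        labels = [by_id[s] for s in sample_ids]
    codes = {RESPONDER: 1, NON_RESPONDER: 0, 1: 1, 0: 0, "1": 1, "0": 0}
    try:
        y = np.array([codes[v] for v in labels], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown response label {e}") from None
    if len(y) != len(sample_ids):
        raise ValueError("label length does not match samples")
    return y


# ---------------------------------------------------------------------------
# Feature fusion and forest tuning
# ---------------------------------------------------------------------------

def build_integrated_features(signature: Union[SignatureGeneSet, Sequence[str]],
                              fcbf_genes: Sequence[str],
                              platform_genes: Sequence[str]) -> IntegratedFeatureSet:
    """Union of in vitro signature genes (restricted to the platform) and
    FCBF-selected genes, deduplicated, in vitro genes first."""
    sig_genes = signature.genes if isinstance(signature, SignatureGeneSet) else list(signature)
    platform = set(platform_genes)
    invitro = [g for g in sig_genes if g in platform]
    dropped = len(sig_genes) - len(invitro)
    if dropped:
        logger.info("build_integrated_features: %d signature genes absent "
                    "from the platform", dropped)
    fcbf_set = set(fcbf_genes)
    genes = invitro + [g for g in fcbf_genes if g not in set(invitro)]
    if not genes:
        raise ValueError("integrated feature set is empty")
    provenance = {}
    for g in genes:
        in_sig = g in set(invitro)
        in_fcbf = g in fcbf_set
        provenance[g] = "both" if (in_sig and in_fcbf) else ("invitro" if in_sig else "fcbf")
    return IntegratedFeatureSet(genes, provenance)


def _derive_seed(seed: int, token: str) -> int:
    digest = hashlib.sha256(f"{seed}:{token}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def tune_and_train_rf(X: np.ndarray, y: np.ndarray,
                      config: ForestConfig) -> TunedForest:
    """Tune mtry by repeated stratified k-fold CV, then refit on all data.

    Accuracy per grid value is the mean over inner_folds x inner_repeats
    stratified folds of the provided (training) data only; ties go to the
    smaller mtry. The class probability of the refit forest is the usual
    tree-vote fraction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    n, p = X.shape
    grid = config.grid_for(p)
    n_splits = min(config.inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few samples per class for internal CV")

    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=config.inner_repeats,
                                 random_state=_derive_seed(config.seed, "inner-cv"))
    splits = list(cv.split(X, y))
    tune_trees = config.tune_n_trees or config.n_trees
    accuracy: dict[int, float] = {}
    for mtry in grid:
        correct = total = 0
        for f, (tr, te) in enumerate(splits):
            rf = RandomForestClassifier(
                n_estimators=tune_trees, max_features=mtry,
                random_state=_derive_seed(config.seed, f"tune-{mtry}-{f}"))
            rf.fit(X[tr], y[tr])
            correct += int((rf.predict(X[te]) == y[te]).sum())
            total += len(te)
        accuracy[mtry] = correct / total
    chosen = min(grid, key=lambda m: (-accuracy[m], m))
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=chosen,
        random_state=_derive_seed(config.seed, "final-fit"))
    forest.fit(X, y)
    return TunedForest(forest, config.n_trees, grid, chosen, accuracy, config.seed)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class IntegrativeModel:
    """Integrative everolimus-response classifier for patient cohorts.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Standardized (per-gene mean 0, sd 1) patient expression.
    response : PhenotypeTable, mapping, Series or list of ResponseLabel
        Binary responder/non_responder labels (or a phenotype table with
        Ki67 columns to derive them from).
    signature : SignatureGeneSet or sequence of gene ids
        The in vitro signature carried into every feature set.
    config : ForestConfig, optional
    """

    def __init__(self, matrix: ExpressionMatrix, response,
                 signature: Union[SignatureGeneSet, Sequence[str]],
                 config: Optional[ForestConfig] = None):
        self.matrix = matrix
        self.y = _response_vector(response, matrix.sample_ids)
        self.signature = signature
        self.config = config or ForestConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response, signature,
                       **kwargs) -> "IntegrativeModel":
        return cls(ExpressionMatrix.from_dataframe(df, "standardized"),
                   response, signature, **kwargs)

    def _select_and_train(self, matrix: ExpressionMatrix, y: np.ndarray,
                          seed: int) -> tuple[IntegratedFeatureSet, FCBFResult, TunedForest]:
        disc = discretize(matrix)
        fcbf = fcbf_select(disc, y, self.config.fcbf_delta)
        features = build_integrated_features(self.signature, fcbf.selected,
                                             matrix.gene_ids)
        sub = matrix.select_genes(features.genes)
        cfg = dataclasses.replace(self.config, seed=seed)
        tuned = tune_and_train_rf(sub.values.T, y, cfg)
        return features, fcbf, tuned

    def fit(self) -> "IntegrativeResults":
        """FCBF on all patients, feature fusion, tuned forest on all patients."""
        features, fcbf, tuned = self._select_and_train(self.matrix, self.y,
                                                       self.config.seed)
        return IntegrativeResults(self, features, fcbf, tuned)

    def loocv(self) -> PatientLOOCVReport:
        """Leave-one-patient-out CV with per-fold selection and tuning.

        Discretization thresholds, FCBF, the integrated feature set, mtry
        tuning and forest training all see only the 22 training patients of
        each fold; per-fold seeds are derived from (seed, held-out id) so
        results do not depend on patient column order.
        """
        if self.matrix.n_samples < 6:
            raise ValueError("patient LOOCV needs at least 6 samples")
        y_of = dict(zip(self.matrix.sample_ids, self.y))
        rows, fold_features, fold_mtry = [], {}, {}
        for j, sid in enumerate(self.matrix.sample_ids):
            # canonical training order keyed by sample id, so out-of-fold
            # results do not depend on the column order of the input matrix
            train_ids = sorted(s for s in self.matrix.sample_ids if s != sid)
            y_train = np.array([y_of[s] for s in train_ids])
            if len(np.unique(y_train)) < 2:
                raise ValueError(f"fold holding out {sid} loses a class")
            train = self.matrix.select_samples(train_ids)
            fold_seed = _derive_seed(self.config.seed, sid)
            features, _, tuned = self._select_and_train(train, y_train, fold_seed)
            x_test = self.matrix.select_genes(features.genes).values[:, j]
            prob = float(tuned.forest.predict_proba(x_test[None, :])[0][
                list(tuned.forest.classes_).index(1)])
            rows.append({
                "sample_id": sid,
                "prob_response": prob,
                "predicted": RESPONDER if prob > 0.5 else NON_RESPONDER,
                "truth": RESPONDER if self.y[j] == 1 else NON_RESPONDER,
            })
            fold_features[sid] = features.genes
            fold_mtry[sid] = tuned.chosen_mtry
        return PatientLOOCVReport(pd.DataFrame(rows), fold_features, fold_mtry)


class IntegrativeResults:
    """Final integrative model: feature set + tuned random forest."""

    def __init__(self, model: IntegrativeModel, features: IntegratedFeatureSet,
                 fcbf: FCBFResult, tuned: TunedForest):
        self.model = model
        self.features = features
        self.fcbf = fcbf
        self.tuned = tuned

    @property
    def fittedvalues(self) -> pd.Series:
        """In-sample responder probabilities of the final forest."""
        sub = self.model.matrix.select_genes(self.features.genes)
        idx = list(self.tuned.forest.classes_).index(1)
        return pd.Series(self.tuned.forest.predict_proba(sub.values.T)[:, idx],
                         index=self.model.matrix.sample_ids)

    def predict(self, cohort: ExpressionMatrix, max_missing: float = 0.20,
                high_response_cutoff: float = 0.75) -> CohortPrediction:
        """Score an external cohort with the final forest.

        The cohort is standardized per gene within the cohort if not
        already; model genes missing from the cohort are imputed as
        standardized 0 when at most ``max_missing`` of the features are
        missing, otherwise scoring fails.
        """
        if cohort.scale_tag != "standardized":
            cohort = standardize_genes(cohort)
        present = [g for g in self.features.genes if g in set(cohort.gene_ids)]
        missing = [g for g in self.features.genes if g not in set(cohort.gene_ids)]
        frac = len(missing) / len(self.features.genes)
        if frac > max_missing:
            raise ValueError(
                f"{len(missing)}/{len(self.features.genes)} model features "
                f"missing from cohort (> {max_missing:.0%})")
        if missing:
            logger.warning("predict: imputing %d missing model genes as 0", len(missing))
        X = np.zeros((cohort.n_samples, len(self.features.genes)))
        sub = cohort.select_genes(present)
        pos = {g: i for i, g in enumerate(self.features.genes)}
        for g, row in zip(present, sub.values):
            X[:, pos[g]] = row
        idx = list(self.tuned.forest.classes_).index(1)
        probs = pd.Series(self.tuned.forest.predict_proba(X)[:, idx],
                          index=cohort.sample_ids)
        return CohortPrediction(probs, high_response_cutoff)

    def summary(self) -> str:
        prov = pd.Series(self.features.provenance)
        counts = prov.value_counts()
        lines = [
            "Integrative everolimus-response model (random forest)",
            f"  patients: {self.model.matrix.n_samples}   features: "
            f"{len(self.features.genes)} "
            f"(invitro {counts.get('invitro', 0)}, fcbf {counts.get('fcbf', 0)}, "
            f"both {counts.get('both', 0)})",
            f"  trees: {self.tuned.n_trees}   chosen mtry: {self.tuned.chosen_mtry}"
            f"   internal CV accuracy at optimum: {self.tuned.peak_accuracy:.3f}",
            "  mtry tuning curve: " + ", ".join(
                f"{m}:{a:.3f}" for m, a in sorted(self.tuned.internal_cv_accuracy.items())),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "features": self.features.genes,
            "provenance": self.features.provenance,
            "fcbf_selected": self.fcbf.selected,
            "fcbf_su_to_class": self.fcbf.su_to_class,
            "fcbf_delta": self.fcbf.delta,
            "n_trees": self.tuned.n_trees,
            "mtry_grid": list(self.tuned.mtry_grid),
            "chosen_mtry": self.tuned.chosen_mtry,
            "internal_cv_accuracy": {str(k): v for k, v
                                     in self.tuned.internal_cv_accuracy.items()},
            "seed": self.tuned.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_groups(pred: Union[CohortPrediction, pd.Series], groups,
                   cutoff: float = 0.75) -> GroupComparison:
    """One-way ANOVA + Tukey HSD of response probabilities across groups.

    Also reports the per-group fraction of samples whose predicted response
    probability exceeds ``cutoff``.
    """
    probs = pred.probabilities if isinstance(pred, CohortPrediction) else pred
    groups = pd.Series(groups, index=probs.index) if not isinstance(groups, pd.Series) \
        else groups.reindex(probs.index)
    names = sorted(groups.dropna().unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [probs[groups == g].to_numpy() for g in names]
    for g, arr in zip(names, samples):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    f_stat, p_val = stats.f_oneway(*samples)
    # rounding can push F to a tiny negative value when group means coincide
    if not np.isfinite(p_val) or f_stat < 0:
        f_stat = max(float(f_stat), 0.0)
        n_total = sum(len(a) for a in samples)
        p_val = stats.f.sf(f_stat, len(samples) - 1, n_total - len(samples))
    tukey = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group1": names[i], "group2": names[j],
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "p_adj": float(tukey.pvalue[i, j]),
            })
    comparison = GroupComparison(
        anova_f=float(f_stat), anova_p=float(p_val),
        group_means={g: float(a.mean()) for g, a in zip(names, samples)},
        pairwise=pd.DataFrame(rows),
        high_response_fraction={g: float((a > cutoff).mean())
                                for g, a in zip(names, samples)},
        cutoff=cutoff,
    )
    if isinstance(pred, CohortPrediction):
        pred.groups = groups
        pred.comparison = comparison
    return comparison
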
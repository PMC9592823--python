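"""Synthetic expression cohorts with known ground truth.

Three generators emulate the study designs the pipeline consumes, so every
stage is testable without downloads:

* ``simulate_cell_lines`` — a paired in vitro design: n_lines ER+ breast
  cancer cell lines, each profiled under control (DMSO) and treated
  (everolimus + exemestane) conditions, with a planted set of
  treatment-responsive genes shifted by ``effect_size`` log2 units (half up,
  half down).
* ``simulate_patient_cohort`` — a small neoadjuvant-trial cohort whose
  binary response is driven by a few informative genes (optionally
  overlapping the in vitro signature), with redundant near-copies of the
  informative genes and nuisance genes; emitted Ki67 pre/post pairs are
  label-consistent by construction.
* ``simulate_external_cohort`` — a larger cohort split into risk groups
  whose informative-gene shifts scale with per-group means, producing
  group-ordered predicted response probabilities under a matched model.

All generators are pure functions of their config (including the seed):
identical inputs give identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, PhenotypeTable
from .signature import SignatureGeneSet

__all__ = [
    "CellLineSimConfig",
    "PatientSimConfig",
    "ExternalCohortSimConfig",
    "SimTruth",
    "simulate_cell_lines",
    "simulate_patient_cohort",
    "simulate_external_cohort",
]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


@dataclass
class CellLineSimConfig:
    """Paired treated/control cell-line design.

    ``effect_size`` is the treatment shift in log2 units applied to the
    planted responsive genes (half up, half down); ``line_sd`` is the
    per-line baseline wobble shared by both conditions of a line and
    ``noise_sd`` the residual measurement noise.
    """

    n_lines: int = 9
    n_genes: int = 5000
    n_true_genes: int = 200
    effect_size: float = 1.5
    line_sd: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_genes > self.n_genes:
            raise ValueError("n_true_genes exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_lines < 2:
            raise ValueError("need at least 2 cell lines")


@dataclass
class PatientSimConfig:
    """Small clinical cohort with planted response structure."""

    n_patients: int = 23
    n_genes: int = 5000
    n_informative: int = 10
    n_redundant_per_informative: int = 1
    effect_size: float = 2.0
    overlap_with_invitro: float = 0.5
    response_rate: float = 0.5
    noise_sd: float = 1.0
    redundant_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        n_extra = self.n_informative * (1 + self.n_redundant_per_informative)
        if n_extra > self.n_genes:
            raise ValueError("informative + redundant genes exceed n_genes")
        if not (0 <= self.response_rate <= 1):
            raise ValueError("response_rate must lie in [0, 1]")
        if not (0 <= self.overlap_with_invitro <= 1):
            raise ValueError("overlap_with_invitro must lie in [0, 1]")


@dataclass
class ExternalCohortSimConfig:
    """External validation cohort with risk-group structure."""

    n_per_group: int = 50
    n_genes: int = 5000
    noise_sd: float = 1.0
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    true_gene_ids: list[str] = field(default_factory=list)
    directions: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    informative_ids: list[str] = field(default_factory=list)
    redundant_map: dict[str, str] = field(default_factory=dict)
    response: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    single_class: bool = False


def simulate_cell_lines(config: CellLineSimConfig,
                        ) -> tuple[ExpressionMatrix, pd.Series, SimTruth]:
    """Simulate the paired control/treated cell-line experiment.

    Per gene g: baseline b_g ~ Normal(6, 2). Per line l: a shared line
    effect u_gl ~ Normal(0, line_sd). Control value = b_g + u_gl + eps;
    treated value adds effect_size * s_g for the planted responsive genes
    (s_g = +1 for the first half, -1 for the second), eps ~ Normal(0,
    noise_sd) independently per measurement.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baseline = rng.normal(6.0, 2.0, size=config.n_genes)

    true_idx = rng.choice(config.n_genes, size=config.n_true_genes, replace=False)
    signs = np.zeros(config.n_genes)
    half = config.n_true_genes // 2
    signs[true_idx[:half]] = 1.0
    signs[true_idx[half:]] = -1.0

    cols, ids, labels = [], [], []
    for line in range(1, config.n_lines + 1):
        u = rng.normal(0.0, config.line_sd, size=config.n_genes)
        control = baseline + u + rng.normal(0, config.noise_sd, config.n_genes)
        treated = (baseline + u + config.effect_size * signs
                   + rng.normal(0, config.noise_sd, config.n_genes))
        cols += [control, treated]
        ids += [f"line{line}_control", f"line{line}_treated"]
        labels += ["control", "treated"]

    matrix = ExpressionMatrix(genes, ids, np.column_stack(cols))
    truth = SimTruth(
        true_gene_ids=[genes[i] for i in true_idx],
        directions={genes[i]: int(signs[i]) for i in true_idx},
    )
    return matrix, pd.Series(labels, index=ids), truth


def _pick_informative(rng: np.random.Generator, genes: list[str],
                      config: PatientSimConfig,
                      signature: Optional[SignatureGeneSet]) -> list[str]:
    gene_set = set(genes)
    informative: list[str] = []
    if signature is not None and config.overlap_with_invitro > 0:
        candidates = [g for g in signature.genes if g in gene_set]
        n_from_sig = min(int(round(config.overlap_with_invitro * config.n_informative)),
                         len(candidates))
        if n_from_sig:
            informative += list(rng.choice(candidates, size=n_from_sig, replace=False))
    pool = [g for g in genes if g not in set(informative)
            and (signature is None or g not in set(signature.genes))]
    n_rest = config.n_informative - len(informative)
    informative += list(rng.choice(pool, size=n_rest, replace=False))
    return informative


def simulate_patient_cohort(config: PatientSimConfig,
                            signature: Optional[SignatureGeneSet] = None,
                            ) -> tuple[ExpressionMatrix, PhenotypeTable, SimTruth]:
    """Simulate a pre-treatment patient cohort with planted response.

    Responders (Bernoulli ``response_rate``) receive an ``effect_size``
    shift on the informative genes (sign alternating; for genes drawn from
    the in vitro signature the planted sign matches the signature's
    direction so the integration step sees a consistent signal). Each
    informative gene gets ``n_redundant_per_informative`` redundant
    near-copies (parent + Normal(0, redundant_noise_sd)). Ki67 pre/post
    pairs are generated so the default >10%-relative-decrease labeling
    rule reproduces the planted response exactly (responders: planted
    decrease 20-80%; non-responders: -10% to +10%).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    patients = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]

    responder = rng.random(config.n_patients) < config.response_rate
    informative = _pick_informative(rng, genes, config, signature)
    directions = {}
    for i, g in enumerate(informative):
        if signature is not None and g in signature.direction:
            directions[g] = 1 if signature.direction[g] == "up_in_treated" else -1
        else:
            directions[g] = 1 if i % 2 == 0 else -1

    baseline = rng.normal(6.0, 2.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(0, config.noise_sd,
                                            (config.n_genes, config.n_patients))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in informative:
        values[gene_pos[g], responder] += config.effect_size * directions[g]

    # redundant near-copies of informative genes, overwriting nuisance rows
    used = set(informative)
    pool = [g for g in genes if g not in used]
    redundant_map: dict[str, str] = {}
    n_red = config.n_redundant_per_informative
    if n_red:
        targets = rng.choice(pool, size=len(informative) * n_red, replace=False)
        for i, parent in enumerate(informative):
            for j in range(n_red):
                child = str(targets[i * n_red + j])
                values[gene_pos[child]] = (values[gene_pos[parent]]
                                           + rng.normal(0, config.redundant_noise_sd,
                                                        config.n_patients))
                redundant_map[child] = parent

    ki67_pre = rng.uniform(10, 60, size=config.n_patients)
    decrease = np.where(responder, rng.uniform(20, 80, config.n_patients),
                        rng.uniform(-10, 10, config.n_patients))
    ki67_post = np.clip(ki67_pre * (1 - decrease / 100.0), 0, 100)

    response = np.where(responder, "responder", "non_responder")
    pheno = PhenotypeTable(pd.DataFrame({
        "sample_id": patients,
        "ki67_pre": np.round(ki67_pre, 3),
        "ki67_post": np.round(ki67_post, 3),
        "response": response,
    }))
    matrix = ExpressionMatrix(genes, patients, values, "log2_intensity")
    truth = SimTruth(
        informative_ids=informative,
        directions=directions,
        redundant_map=redundant_map,
        response=dict(zip(patients, response)),
        single_class=len(set(response)) < 2,
    )
    return matrix, pheno, truth


def simulate_external_cohort(config: ExternalCohortSimConfig,
                             truth: SimTruth,
                             group_means: Mapping[str, float],
                             ) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate an external cohort with group-scaled response signal.

    Reuses the informative genes and directions of a patient-cohort
    ``truth`` (so a model trained on the matched simulation transfers);
    samples in group G receive ``group_means[G]`` times the unit responder
    shift on each informative gene. Redundant genes are copied from their
    parents as in the patient generator.
    """
    if len(group_means) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in list(truth.informative_ids) + list(truth.redundant_map):
        if g not in gene_pos:
            raise ValueError(f"truth gene {g} outside the simulated universe")

    groups = list(group_means)
    n_total = config.n_per_group * len(groups)
    sample_ids = [f"E{i:04d}" for i in range(1, n_total + 1)]
    group_of = [groups[i // config.n_per_group] for i in range(n_total)]

    baseline = rng.normal(6.0, 2.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(0, config.noise_sd,
                                            (config.n_genes, n_total))
    shift = np.array([group_means[g] for g in group_of])
    for g in truth.informative_ids:
        values[gene_pos[g]] += shift * truth.directions.get(g, 1)
    for child, parent in truth.redundant_map.items():
        values[gene_pos[child]] = (values[gene_pos[parent]]
                                   + rng.normal(0, 0.1, n_total))

    matrix = ExpressionMatrix(genes, sample_ids, values, "log2_intensity")
    return matrix, pd.Series(group_of, index=sample_ids)
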
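"""Synthetic perinatal cohorts with known trajectory and network structure.

The generator emulates a longitudinal sleep-quality study: each subject
belongs to one of a small number of latent trajectory groups; her sleep
score at each assessment wave is a group-specific polynomial in time
plus normal noise, censored to the instrument's 0-21 range; post-
baseline waves may be missing completely at random.  Depressive-symptom
items (ten items scored 0-3) are generated per group from an Ising
distribution over presence/absence, with present symptoms assigned an
ordinal severity.  Demographic covariates default to the marginal rates
typical of a middle-class urban Chinese perinatal cohort.

True group labels are retained so that downstream estimators can be
validated against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ising import IsingNetwork
from .nira import GibbsConfig, gibbs_sample

__all__ = [
    "TrajectoryGroupSpec",
    "IsingParameterSpec",
    "CovariateSpec",
    "SyntheticCohortConfig",
    "CohortDataset",
    "ConfigurationError",
    "ParseError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_two_group_config",
]

N_ITEMS = 10
ITEM_COLUMNS = [f"item{i}" for i in range(1, N_ITEMS + 1)]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


class ParseError(ValueError):
    """Malformed cohort file."""


@dataclass
class TrajectoryGroupSpec:
    """One latent group: mixing proportion, polynomial mean, residual SD."""

    label: str
    proportion: float
    poly_coeffs: tuple[float, ...]
    residual_sd: float

    def __post_init__(self) -> None:
        self.poly_coeffs = tuple(float(c) for c in self.poly_coeffs)
        if not 0 < self.proportion <= 1:
            raise ConfigurationError(
                f"group {self.label}: proportion must be in (0, 1]")
        if len(self.poly_coeffs) == 0 or len(self.poly_coeffs) > 4:
            raise ConfigurationError(
                f"group {self.label}: polynomial degree must be 0..3")
        if self.residual_sd <= 0:
            raise ConfigurationError(
                f"group {self.label}: residual_sd must be > 0")

    def mean_at(self, t: np.ndarray) -> np.ndarray:
        return np.polyval(self.poly_coeffs[::-1], t)


@dataclass
class IsingParameterSpec:
    """Thresholds and couplings generating one group's symptom vectors."""

    thresholds: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        p = self.thresholds.shape[0]
        if self.weights.shape != (p, p):
            raise ConfigurationError("weights must be p x p")
        if not np.array_equal(self.weights, self.weights.T):
            raise ConfigurationError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ConfigurationError("weights must have zero diagonal")

    @property
    def p(self) -> int:
        return self.thresholds.shape[0]

    def as_network(self, labels: Sequence[str] | None = None) -> IsingNetwork:
        labels = list(labels) if labels is not None else \
            [f"item{i}" for i in range(1, self.p + 1)]
        return IsingNetwork(thresholds=self.thresholds.copy(),
                            weights=self.weights.copy(), labels=labels)


@dataclass
class CovariateSpec:
    """Either a Bernoulli/categorical column or a normal column."""

    name: str
    kind: str                     # "categorical" | "normal"
    levels: tuple = ()
    probs: tuple = ()
    mean: float = 0.0
    sd: float = 1.0


def _default_covariates() -> list[CovariateSpec]:
    # marginal rates of the usual demographic adjustment set
    return [
        CovariateSpec("age", "normal", mean=29.7, sd=4.1),
        CovariateSpec("education", "categorical",
                      levels=("secondary", "associate", "bachelor"),
                      probs=(0.301, 0.374, 0.325)),
        CovariateSpec("employed", "categorical", levels=(0, 1),
                      probs=(0.271, 0.729)),
        CovariateSpec("urban_birthplace", "categorical", levels=(0, 1),
                      probs=(0.597, 0.403)),
        CovariateSpec("married", "categorical", levels=(0, 1),
                      probs=(0.056, 0.944)),
        CovariateSpec("income_high", "categorical", levels=(0, 1),
                      probs=(0.247, 0.753)),
        CovariateSpec("nulliparous", "categorical", levels=(0, 1),
                      probs=(0.5, 0.5)),
        CovariateSpec("planned_pregnancy", "categorical", levels=(0, 1),
                      probs=(0.107, 0.893)),
        CovariateSpec("vaginal_delivery", "categorical", levels=(0, 1),
                      probs=(0.388, 0.612)),
    ]


@dataclass
class SyntheticCohortConfig:
    n_subjects: int = 372
    waves: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    groups: list[TrajectoryGroupSpec] = field(default_factory=list)
    score_bounds: tuple[float, float] = (0.0, 21.0)
    symptom_specs: list[IsingParameterSpec] = field(default_factory=list)
    severity_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    missing_rate: float = 0.0
    covariate_specs: list[CovariateSpec] = field(
        default_factory=_default_covariates)
    round_scores: bool = False
    standard_design: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigurationError("at least one trajectory group required")
        total = sum(g.proportion for g in self.groups)
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(
                f"group proportions sum to {total!r}, not 1")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if len(self.symptom_specs) != len(self.groups):
            raise ConfigurationError(
                "one Ising parameter spec required per group")
        if self.standard_design:
            if not 2 <= len(self.groups) <= 4:
                raise ConfigurationError(
                    "standard-design cohorts use 2-4 trajectory groups")
            for s in self.symptom_specs:
                if s.p != N_ITEMS:
                    raise ConfigurationError(
                        f"standard-design cohorts use {N_ITEMS} items")
        if self.score_bounds[0] >= self.score_bounds[1]:
            raise ConfigurationError("score_bounds must be increasing")
        if abs(sum(self.severity_probs) - 1.0) > 1e-8:
            raise ConfigurationError("severity_probs must sum to 1")


@dataclass
class CohortDataset:
    """Long trajectory records, wide item table, covariates, true labels."""

    trajectory_table: pd.DataFrame   # subject_id, wave, score
    item_table: pd.DataFrame         # subject_id, item1..item10
    covariate_table: pd.DataFrame    # subject_id, ...
    true_labels: pd.Series | None = None

    @property
    def n_subjects(self) -> int:
        return self.item_table.shape[0]

    def subjects(self) -> np.ndarray:
        return self.item_table["subject_id"].to_numpy()


def default_two_group_config(n_subjects: int = 372, missing_rate: float = 0.0,
                             seed: int = 0) -> SyntheticCohortConfig:
    """Cohort matched to the study conditions: two linear trajectories.

    The majority "stably good" group drifts slowly upward from a PSQI
    of 3.5; the "increasingly poor" group starts at a moderate 6.5 and
    worsens by one point per wave, ending three residual SDs above the
    good group.  Symptom networks are chain graphs with moderate
    positive couplings; the poor-sleep group has uniformly higher
    thresholds, so it expresses more depressive symptoms.
    """
    groups = [
        TrajectoryGroupSpec("increasingly_poor", 0.414, (6.5, 1.0), 1.5),
        TrajectoryGroupSpec("stably_good", 0.586, (3.5, 0.5), 1.5),
    ]

    def chain(tau0: float) -> IsingParameterSpec:
        w = np.zeros((N_ITEMS, N_ITEMS))
        for i in range(N_ITEMS - 1):
            w[i, i + 1] = w[i + 1, i] = 0.8
        return IsingParameterSpec(np.full(N_ITEMS, tau0), w)

    return SyntheticCohortConfig(
        n_subjects=n_subjects,
        groups=groups,
        symptom_specs=[chain(-0.2), chain(-1.2)],
        missing_rate=missing_rate,
        seed=seed,
    )


def generate_cohort(config: SyntheticCohortConfig) -> CohortDataset:
    """Draw a full cohort; bit-reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    waves = np.asarray(config.waves, dtype=float)
    k = len(config.groups)

    proportions = np.array([g.proportion for g in config.groups])
    labels_idx = rng.choice(k, size=n, p=proportions / proportions.sum())
    subject_ids = np.arange(1, n + 1)

    lo, hi = config.score_bounds
    rows = []
    for i, g_idx in enumerate(labels_idx):
        g = config.groups[g_idx]
        mu = g.mean_at(waves)
        score = mu + rng.normal(0.0, g.residual_sd, size=waves.shape[0])
        score = np.clip(score, lo, hi)
        if config.round_scores:
            score = np.clip(np.round(score), lo, hi)
        # baseline (first wave) is always observed
        miss = rng.random(waves.shape[0]) < config.missing_rate
        miss[0] = False
        for t, s, m in zip(waves, score, miss):
            if not m:
                rows.append((subject_ids[i], t, s))
    trajectory_table = pd.DataFrame(
        rows, columns=["subject_id", "wave", "score"])

    # symptom items: one Gibbs run per group, severities for present items
    items = np.zeros((n, N_ITEMS if config.standard_design
                      else config.symptom_specs[0].p), dtype=int)
    severities = np.array([1, 2, 3])
    for g_idx, spec in enumerate(config.symptom_specs):
        members = np.flatnonzero(labels_idx == g_idx)
        if members.size == 0:
            continue
        net = spec.as_network()
        cfg = GibbsConfig(n_samples=members.size, sweeps=100,
                          seed=int(rng.integers(2**31)))
        present = gibbs_sample(net, cfg).values.astype(int)
        sev = rng.choice(severities, size=present.shape,
                         p=np.asarray(config.severity_probs))
        items[members] = present * sev
    item_table = pd.DataFrame(items, columns=ITEM_COLUMNS[:items.shape[1]])
    item_table.insert(0, "subject_id", subject_ids)

    cov = {"subject_id": subject_ids}
    for spec in config.covariate_specs:
        if spec.kind == "normal":
            cov[spec.name] = rng.normal(spec.mean, spec.sd, size=n)
        elif spec.kind == "categorical":
            cov[spec.name] = rng.choice(np.asarray(spec.levels),
                                        size=n, p=np.asarray(spec.probs))
        else:
            raise ConfigurationError(
                f"unknown covariate kind {spec.kind!r}")
    covariate_table = pd.DataFrame(cov)

    true_labels = pd.Series(
        [config.groups[g].label for g in labels_idx],
        index=pd.Index(subject_ids, name="subject_id"), name="group")

    return CohortDataset(trajectory_table=trajectory_table,
                         item_table=item_table,
                         covariate_table=covariate_table,
                         true_labels=true_labels)


def write_cohort(dataset: CohortDataset, directory: str | Path) -> list[Path]:
    """Write the cohort as UTF-8 CSV files; missing scores as empty cells."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in (("trajectories.csv", dataset.trajectory_table),
                        ("items.csv", dataset.item_table),
                        ("covariates.csv", dataset.covariate_table)):
        path = directory / name
        table.to_csv(path, index=False)
        written.append(path)
    if dataset.true_labels is not None:
        path = directory / "labels.csv"
        dataset.true_labels.rename("group").to_csv(path)
        written.append(path)
    return written


def read_cohort(directory: str | Path) -> CohortDataset:
    """Read and validate a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    traj = pd.read_csv(directory / "trajectories.csv")
    if traj.shape[0] == 0:
        raise ParseError("trajectories.csv: no records")
    dup = traj.duplicated(subset=["subject_id", "wave"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ParseError(
            f"trajectories.csv: duplicate subject-wave pair at row {row}")

    items = pd.read_csv(directory / "items.csv")
    vals = items[[c for c in items.columns if c != "subject_id"]].to_numpy()
    bad = ~np.isin(vals, (0, 1, 2, 3))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"items.csv: item score out of range at row {r}: {vals[r, c]!r}")

    cov = pd.read_csv(directory / "covariates.csv")

    traj_ids = set(traj.subject_id)
    item_ids = set(items.subject_id)
    if not traj_ids <= item_ids:
        raise ParseError(
            "trajectories.csv mentions subjects absent from items.csv")

    labels = None
    labels_path = directory / "labels.csv"
    if labels_path.exists():
        lab = pd.read_csv(labels_path)
        labels = pd.Series(lab["group"].to_numpy(),
                           index=pd.Index(lab["subject_id"].to_numpy(),
                                          name="subject_id"), name="group")
    return CohortDataset(trajectory_table=traj, item_table=items,
                         covariate_table=cov, true_labels=labels)
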
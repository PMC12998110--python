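"""Synthetic questionnaire data and exact/Gibbs Ising samplers.

Two generators live here.  ``generate_likert`` draws respondent-by-item
Likert matrices from a finite mixture of latent classes: each class has a
mean profile on the latent (continuous) scale, correlated within-class
Gaussian noise, and responses are discretized to the ordinal scale by fixed
thresholds.  The default configuration emulates a three-class (low /
moderate / high self-efficacy) structure typical of nurse nutrition-care
surveys: class shares ≈ 0.16 / 0.49 / 0.35 and class-conditional item means
around 2.0 / 3.05 / 4.3 on the 5-point scale.

``sample_ising`` draws exact (full 2^P enumeration, P ≤ 15) or Gibbs samples
from an Ising model, used as the ground-truth oracle for the network
estimation and simulated-intervention stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import SENNC_DIMENSIONS, SENNC_ITEMS, ResponseDataset
from .ising import BinaryMatrix, IsingNetwork

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "default_three_class_config",
    "generate_likert",
    "sample_ising",
    "enumerate_ising",
]

# Default three-class conditional mean profiles (27 items, low/moderate/high).
THREE_CLASS_MEANS: dict[str, tuple[float, ...]] = {
    "low": (
        2.303, 2.070, 2.178, 1.984, 1.962, 1.901,
        2.044, 2.123, 2.069, 2.072, 2.194, 2.037, 1.948, 1.988, 2.095,
        1.978, 2.015, 1.908, 2.064, 1.984, 1.884,
        2.094, 2.014, 2.001, 2.138, 2.158, 2.304,
    ),
    "moderate": (
        3.097, 3.073, 3.058, 3.025, 3.059, 3.009,
        3.117, 3.113, 2.993, 3.005, 3.113, 3.033, 2.997, 3.021, 3.050,
        3.019, 3.016, 3.014, 3.087, 3.066, 2.997,
        3.069, 3.067, 3.032, 3.087, 3.104, 3.170,
    ),
    "high": (
        4.303, 4.298, 4.270, 4.309, 4.254, 4.246,
        4.348, 4.403, 4.264, 4.319, 4.359, 4.381, 4.320, 4.313, 4.347,
        4.298, 4.308, 4.337, 4.331, 4.274, 4.264,
        4.365, 4.303, 4.359, 4.337, 4.354, 4.353,
    ),
}

THREE_CLASS_PROPORTIONS = (81 / 510, 251 / 510, 178 / 510)


@dataclass
class ClassSpec:
    """One latent class of the mixture generator."""

    label: str
    proportion: float
    item_means: tuple[float, ...]
    within_class_sd: float = 0.45
    rho_within: float = 0.3  # correlation between items of the same dimension
    rho_between: float = 0.15  # correlation across dimensions

    def __post_init__(self) -> None:
        self.item_means = tuple(float(m) for m in self.item_means)
        if not (0 < self.proportion <= 1):
            raise ValueError("class proportion must be in (0, 1]")
        if self.within_class_sd <= 0:
            raise ValueError("within_class_sd must be positive")


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic Likert survey."""

    n_total: int
    classes: list[ClassSpec]
    likert_levels: int = 5
    cut_points: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5)
    item_labels: tuple[str, ...] = SENNC_ITEMS
    dimensions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: v for k, v in SENNC_DIMENSIONS.items()}
    )
    duration_mean_seconds: float = 420.0
    duration_sd_seconds: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if self.likert_levels < 2:
            raise ValueError("need at least 2 Likert levels")
        total = sum(c.proportion for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        cuts = np.asarray(self.cut_points, dtype=float)
        if len(cuts) != self.likert_levels - 1 or np.any(np.diff(cuts) <= 0):
            raise ValueError("cut points must be strictly increasing, one per boundary")
        P = len(self.item_labels)
        for c in self.classes:
            if len(c.item_means) != P:
                raise ValueError(
                    f"class {c.label!r}: {len(c.item_means)} item means for {P} items"
                )


def config_to_yaml(config: GeneratorConfig, path) -> None:
    """Write a generator configuration as a declarative YAML file."""
    import yaml
    from dataclasses import asdict
    from pathlib import Path

    raw = asdict(config)
    raw["classes"] = [asdict(c) for c in config.classes]
    for c in raw["classes"]:
        c["item_means"] = list(c["item_means"])
    raw["cut_points"] = list(raw["cut_points"])
    raw["item_labels"] = list(raw["item_labels"])
    raw["dimensions"] = {k: list(v) for k, v in raw["dimensions"].items()}
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def config_from_yaml(path) -> GeneratorConfig:
    """Read a generator configuration written by :func:`config_to_yaml`."""
    import yaml
    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text())
    raw["classes"] = [
        ClassSpec(
            label=c["label"],
            proportion=c["proportion"],
            item_means=tuple(c["item_means"]),
            within_class_sd=c.get("within_class_sd", 0.45),
            rho_within=c.get("rho_within", 0.3),
            rho_between=c.get("rho_between", 0.15),
        )
        for c in raw["classes"]
    ]
    raw["cut_points"] = tuple(raw.get("cut_points", (1.5, 2.5, 3.5, 4.5)))
    raw["item_labels"] = tuple(raw.get("item_labels", SENNC_ITEMS))
    if "dimensions" in raw:
        raw["dimensions"] = {k: tuple(v) for k, v in raw["dimensions"].items()}
    return GeneratorConfig(**raw)


def default_three_class_config(n_total: int = 510, seed: int = 0) -> GeneratorConfig:
    """The package's reference study conditions: three classes, n = 510."""
    classes = [
        ClassSpec("low", THREE_CLASS_PROPORTIONS[0], THREE_CLASS_MEANS["low"]),
        ClassSpec("moderate", THREE_CLASS_PROPORTIONS[1], THREE_CLASS_MEANS["moderate"]),
        ClassSpec("high", THREE_CLASS_PROPORTIONS[2], THREE_CLASS_MEANS["high"]),
    ]
    return GeneratorConfig(n_total=n_total, classes=classes, seed=seed)


def _correlation_matrix(config: GeneratorConfig, spec: ClassSpec) -> np.ndarray:
    """Block-exchangeable item correlation: rho_within inside a dimension,
    rho_between across dimensions."""
    labels = list(config.item_labels)
    P = len(labels)
    dim_of = {}
    for dim, items in config.dimensions.items():
        for it in items:
            dim_of[it] = dim
    R = np.full((P, P), spec.rho_between)
    for i in range(P):
        for j in range(P):
            if dim_of.get(labels[i]) == dim_of.get(labels[j]):
                R[i, j] = spec.rho_within
    np.fill_diagonal(R, 1.0)
    return R


def generate_likert(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[ResponseDataset, np.ndarray]:
    """Draw a synthetic survey; returns the dataset and the true class labels.

    Latent responses are multivariate normal per class (mean = class profile,
    sd = within_class_sd, block-exchangeable correlation); discretization cuts
    the latent value at ``cut_points`` and clips to [1, likert_levels], which
    preserves the conditional-mean interpretation of the class profiles.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    P = len(config.item_labels)
    props = np.array([c.proportion for c in config.classes])
    assignments = rng.choice(len(config.classes), size=config.n_total, p=props)

    latent = np.empty((config.n_total, P))
    for k, spec in enumerate(config.classes):
        idx = np.flatnonzero(assignments == k)
        if len(idx) == 0:
            continue
        R = _correlation_matrix(config, spec)
        cov = (spec.within_class_sd**2) * R
        latent[idx] = rng.multivariate_normal(
            np.asarray(spec.item_means), cov, size=len(idx), method="cholesky"
        )

    cuts = np.asarray(config.cut_points)
    responses = np.digitize(latent, cuts) + 1  # 1..likert_levels
    responses = np.clip(responses, 1, config.likert_levels)

    durations = np.maximum(
        rng.normal(config.duration_mean_seconds, config.duration_sd_seconds,
                   size=config.n_total),
        30.0,
    )
    table = pd.DataFrame(responses, columns=list(config.item_labels))
    table.insert(0, "respondent_id", np.arange(config.n_total))
    table["duration_seconds"] = np.round(durations, 1)
    table["true_class"] = [config.classes[k].label for k in assignments]
    data = ResponseDataset(
        table, item_labels=config.item_labels, likert_levels=config.likert_levels
    )
    return data, assignments


# ---------------------------------------------------------------------------
# Ising sampling
# ---------------------------------------------------------------------------

_EXACT_MAX_NODES = 15


def enumerate_ising(network: IsingNetwork) -> tuple[np.ndarray, np.ndarray]:
    """All 2^P states and their exact probabilities (P ≤ 15)."""
    P = network.n_nodes
    if P > _EXACT_MAX_NODES:
        raise ValueError(f"exact enumeration limited to P <= {_EXACT_MAX_NODES}")
    states = ((np.arange(2**P)[:, None] >> np.arange(P)) & 1).astype(float)
    tau = network.thresholds
    W = network.weights
    energy = states @ tau + 0.5 * np.einsum("si,ij,sj->s", states, W, states)
    energy -= energy.max()
    p = np.exp(energy)
    p /= p.sum()
    return states, p


def _gibbs_sweeps(
    states: np.ndarray,
    tau: np.ndarray,
    W: np.ndarray,
    n_sweeps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequential-scan Gibbs updates, vectorized over independent chains."""
    from scipy.special import expit

    P = states.shape[1]
    for _ in range(n_sweeps):
        for i in range(P):
            field = tau[i] + states @ W[:, i]
            states[:, i] = rng.random(states.shape[0]) < expit(field)
    return states


def sample_ising(
    network: IsingNetwork,
    n: int,
    seed: int | np.random.Generator = 0,
    method: str = "exact",
    burn_in: int = 100,
    thinning: int = 1,
) -> BinaryMatrix:
    """Draw ``n`` independent response vectors from an Ising model.

    ``exact`` samples from the enumerated distribution (P ≤ 15); ``gibbs``
    runs ``n`` independent sequential-scan chains from random starts for
    ``burn_in + thinning`` sweeps and records the final state of each chain.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "exact":
        states, p = enumerate_ising(network)
        idx = rng.choice(len(p), size=n, p=p)
        return BinaryMatrix(states[idx].astype(np.int8), network.labels)
    if method == "gibbs":
        P = network.n_nodes
        states = (rng.random((n, P)) < 0.5).astype(float)
        states = _gibbs_sweeps(
            states, network.thresholds, network.weights, burn_in + thinning, rng
        )
        return BinaryMatrix(states.astype(np.int8), network.labels)
    raise ValueError(f"unknown sampling method: {method!r}")
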
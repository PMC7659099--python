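"""Population scenarios and the synthetic-data generator.

Eight three-class populations observed at five occasions, differing in how
strongly the residual variances vary over time and across classes and how
strongly the random effects vary across classes (variance ratios from 1:2:3
up to 1:5:10). Class mean trajectories are linear; intercept means of
adjacent classes sit 1 outcome unit apart under *low* separation and 2 units
apart under *high* separation, all other values unchanged.

Registry conventions
--------------------
* Intercept/slope spreads are registered as standard deviations and squared
  into the random-effect covariance diagonals; the intercept-slope
  covariance ``psi_IS`` is zero in every generating population.
* Residual rows are registered as variances. Occasions 1-2 share one value
  and occasions 3-5 share another, per class.
* Scenario 7's class-1 slope SD follows the 1:2:3 pattern (0.10); scenario
  8's class-2 slope mean is -0.30 like every other scenario. Both cells are
  unreadable in the source table and were filled by the surrounding pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dataset import LongitudinalDataset
from .likelihood import build_design_matrices
from .parameters import GMMParameters

SCENARIO_IDS = tuple(range(1, 9))
SEPARATIONS = ("low", "high")

_INTERCEPT_MEANS = {"low": (3.0, 4.0, 5.0), "high": (3.0, 5.0, 7.0)}
_SLOPE_MEANS = (0.0, -0.3, 0.3)

# per scenario: class SDs of the random intercept and random slope
_INTERCEPT_SD = {
    1: (0.30, 0.60, 0.90),
    2: (0.30, 0.60, 0.90),
    3: (0.12, 0.60, 1.20),
    4: (0.12, 0.60, 1.20),
    5: (0.30, 0.60, 0.90),
    6: (0.12, 0.60, 1.20),
    7: (0.30, 0.60, 0.90),
    8: (0.12, 0.60, 1.20),
}
_SLOPE_SD = {
    1: (0.10, 0.20, 0.30),
    2: (0.10, 0.20, 0.30),
    3: (0.04, 0.20, 0.40),
    4: (0.04, 0.20, 0.40),
    5: (0.10, 0.20, 0.30),
    6: (0.04, 0.20, 0.40),
    7: (0.10, 0.20, 0.30),
    8: (0.04, 0.20, 0.40),
}
# per scenario: residual variances for occasions (1, 2) and (3, 4, 5), per class
_RESIDUAL_VAR = {
    1: ((0.25, 0.50, 0.75), (0.50, 1.00, 1.50)),
    2: ((0.10, 0.20, 0.30), (0.50, 1.00, 1.50)),
    3: ((0.25, 0.50, 0.75), (0.50, 1.00, 1.50)),
    4: ((0.10, 0.20, 0.30), (0.50, 1.00, 1.50)),
    5: ((0.10, 0.50, 1.00), (0.20, 1.00, 2.00)),
    6: ((0.10, 0.50, 1.00), (0.20, 1.00, 2.00)),
    7: ((0.04, 0.20, 0.40), (0.20, 1.00, 2.00)),
    8: ((0.04, 0.20, 0.40), (0.20, 1.00, 2.00)),
}

DEFAULT_TIME_SCORES = np.arange(5.0)


@dataclass
class ScenarioConfig:
    """One cell of the simulation grid.

    ``n_subjects`` takes 100, 300 or 1000 in the study grid but any positive
    value is accepted. Mixing proportions default to equal thirds.
    """

    scenario_id: int
    separation: str = "low"
    n_subjects: int = 1000
    mixing_proportions: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0)
    )
    time_scores: np.ndarray = field(default_factory=lambda: DEFAULT_TIME_SCORES.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(f"scenario_id must be in 1..8, got {self.scenario_id}")
        if self.separation not in SEPARATIONS:
            raise ValueError("separation must be 'low' or 'high'")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        self.mixing_proportions = np.asarray(self.mixing_proportions, dtype=float)
        if self.mixing_proportions.shape != (3,) or abs(self.mixing_proportions.sum() - 1) > 1e-10:
            raise ValueError("mixing_proportions must be a length-3 simplex vector")
        self.time_scores = np.asarray(self.time_scores, dtype=float)


def scenario_parameters(
    scenario_id: int,
    separation: str = "low",
    mixing_proportions: np.ndarray | None = None,
    n_timepoints: int = 5,
) -> GMMParameters:
    """True generating parameters of one scenario as a GMMParameters.

    SDs from the registry are squared into the random-effect covariance
    diagonals; residual entries are variances as registered.
    """
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario {scenario_id}")
    if separation not in SEPARATIONS:
        raise ValueError(f"unknown separation {separation!r}")
    if mixing_proportions is None:
        mixing_proportions = np.full(3, 1.0 / 3.0)
    beta = np.column_stack([_INTERCEPT_MEANS[separation], _SLOPE_MEANS])
    psi = np.zeros((3, 2, 2))
    psi[:, 0, 0] = np.square(_INTERCEPT_SD[scenario_id])
    psi[:, 1, 1] = np.square(_SLOPE_SD[scenario_id])
    early, late = _RESIDUAL_VAR[scenario_id]
    theta = np.empty((3, n_timepoints))
    theta[:, :2] = np.asarray(early)[:, None]
    theta[:, 2:] = np.asarray(late)[:, None]
    return GMMParameters(np.asarray(mixing_proportions, float), beta, psi, theta)


def generate_dataset(
    config: ScenarioConfig, params: GMMParameters | None = None
) -> LongitudinalDataset:
    """Draw one replicated dataset with known class labels.

    For each subject: class ``c ~ Categorical(proportions)``, random effects
    ``(b_I, b_S) ~ N(0, Psi_c)``, then
    ``y_t = beta_c0 + beta_c1 * time_t + b_I + b_S * time_t + eps_t`` with
    independent ``eps_t ~ N(0, theta_ct)``. The RNG is consumed in the fixed
    order classes -> random effects -> residuals so a seed reproduces the
    dataset bit-for-bit on any platform.
    """
    if params is None:
        params = scenario_parameters(
            config.scenario_id,
            config.separation,
            config.mixing_proportions,
            n_timepoints=config.time_scores.shape[0],
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    t = config.time_scores.shape[0]
    X, Z = build_design_matrices(config.time_scores, params.n_growth_terms)

    classes = rng.choice(params.n_classes, size=n, p=params.class_probs)
    # lower Cholesky factors of each Psi_k (tolerating exactly-zero matrices)
    chols = np.zeros_like(params.re_cov)
    for k in range(params.n_classes):
        psi = params.re_cov[k] + 1e-300 * np.eye(2)
        w, v = np.linalg.eigh(psi)
        chols[k] = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    b = np.einsum("nij,nj->ni", chols[classes], rng.standard_normal((n, 2)))
    eps = rng.standard_normal((n, t)) * np.sqrt(params.residual_vars[classes])

    y = params.fixed_effects[classes] @ X.T + b @ Z.T + eps
    return LongitudinalDataset(
        y, config.time_scores, true_labels=classes + 1
    )


def write_sidecar(config: ScenarioConfig, params: GMMParameters, path: str | Path) -> None:
    """Write a YAML sidecar recording the full generating configuration."""
    doc = {
        "scenario_id": int(config.scenario_id),
        "separation": config.separation,
        "n_subjects": int(config.n_subjects),
        "seed": int(config.seed),
        "time_scores": [float(v) for v in config.time_scores],
        "population_parameters": params.to_dict(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_sidecar_time_scores(path: str | Path) -> np.ndarray:
    doc = yaml.safe_load(Path(path).read_text())
    return np.asarray(doc["time_scores"], dtype=float)
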
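"""Growth mixture model parameter container and free-parameter counting."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .schemes import ConstraintScheme


@dataclass
class GMMParameters:
    """Parameters of a K-class growth mixture model.

    Attributes
    ----------
    class_probs : (K,) array
        Mixing proportions; non-negative, summing to one.
    fixed_effects : (K, P) array
        Per-class growth-curve coefficients (intercept, linear slope, and
        optionally quadratic/cubic terms; P <= 4). Random effects are always
        on the intercept and linear slope only.
    re_cov : (K, 2, 2) array
        Per-class random-effect covariance matrices
        ``[[psi_I, psi_IS], [psi_IS, psi_S]]``.
    residual_vars : (K, T) array
        Occasion- and class-specific residual variances. Under a constraint
        scheme the tied entries are numerically identical.
    """

    class_probs: np.ndarray
    fixed_effects: np.ndarray
    re_cov: np.ndarray
    residual_vars: np.ndarray

    def __post_init__(self) -> None:
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        self.fixed_effects = np.atleast_2d(np.asarray(self.fixed_effects, dtype=float))
        self.re_cov = np.asarray(self.re_cov, dtype=float)
        if self.re_cov.ndim == 2:
            self.re_cov = self.re_cov[None, :, :]
        self.residual_vars = np.atleast_2d(np.asarray(self.residual_vars, dtype=float))
        k = self.class_probs.shape[0]
        if self.fixed_effects.shape[0] != k or self.re_cov.shape[0] != k:
            raise ValueError("per-class arrays disagree on the number of classes")
        if self.residual_vars.shape[0] != k:
            raise ValueError("residual_vars must have one row per class")
        if self.re_cov.shape[1:] != (2, 2):
            raise ValueError("re_cov must be K x 2 x 2")
        if abs(self.class_probs.sum() - 1.0) > 1e-10 or (self.class_probs < -1e-12).any():
            raise ValueError("class_probs must be a probability vector")
        if not np.allclose(self.re_cov, np.swapaxes(self.re_cov, 1, 2), atol=1e-10):
            raise ValueError("re_cov matrices must be symmetric")

    @property
    def n_classes(self) -> int:
        return self.class_probs.shape[0]

    @property
    def n_growth_terms(self) -> int:
        return self.fixed_effects.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.residual_vars.shape[1]

    def permuted(self, order: np.ndarray) -> "GMMParameters":
        """Return a copy with classes reordered by ``order``."""
        order = np.asarray(order)
        return GMMParameters(
            self.class_probs[order],
            self.fixed_effects[order],
            self.re_cov[order],
            self.residual_vars[order],
        )

    def sorted_by_intercept(self) -> tuple["GMMParameters", np.ndarray]:
        """Canonical presentation order: ascending fitted intercept mean."""
        order = np.argsort(self.fixed_effects[:, 0], kind="stable")
        return self.permuted(order), order

    # ---- JSON serialization (variances stored as variances, never SDs) ----

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "class_probs": self.class_probs.tolist(),
            "fixed_effects": self.fixed_effects.tolist(),
            "re_cov": self.re_cov.tolist(),
            "residual_vars": self.residual_vars.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "GMMParameters":
        return cls(
            np.asarray(d["class_probs"], dtype=float),
            np.asarray(d["fixed_effects"], dtype=float),
            np.asarray(d["re_cov"], dtype=float),
            np.asarray(d["residual_vars"], dtype=float),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GMMParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def count_free_parameters(scheme: ConstraintScheme, K: int, T: int, P: int) -> int:
    """Number of free parameters of a K-class, T-occasion model under ``scheme``.

    Counts K-1 mixing proportions, K*P growth coefficients, 3 random-effect
    (co)variances per distinct covariance matrix, and one residual variance
    per distinct (class, occasion) cell after applying the equality ties.
    """
    n_pi = K - 1
    n_beta = K * P
    n_psi = 3 * (1 if scheme.random_effects_tied_over_classes else K)
    n_theta = (1 if scheme.residual_tied_over_classes else K) * (
        1 if scheme.residual_tied_over_time else T
    )
    return n_pi + n_beta + n_psi + n_theta
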
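"""The seven variance-constraint schemes studied for growth mixture models.

Each scheme declares which variance parameters are tied by equality
constraints: residual variances over time, residual variances across latent
classes, and the random-effect covariance matrix across classes. ``M0`` is
the fully unconstrained model; ``M2C`` (random effects and residual
variances both tied across classes) is the common software default.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ConstraintScheme:
    """Equality ties imposed on the variance parameters of a GMM.

    Attributes
    ----------
    id : str
        One of ``M0, M1A, M1B, M1C, M2A, M2B, M2C``.
    residual_tied_over_time : bool
        Residual variances equal across the T occasions (within class).
    residual_tied_over_classes : bool
        Residual variances equal across the K classes (within occasion).
    random_effects_tied_over_classes : bool
        One shared random-effect covariance matrix for all classes.
    """

    id: str
    residual_tied_over_time: bool
    residual_tied_over_classes: bool
    random_effects_tied_over_classes: bool

    def __str__(self) -> str:
        return self.id


_FLAGS = {
    "M0": (False, False, False),
    "M1A": (True, False, False),
    "M1B": (False, True, False),
    "M1C": (False, False, True),
    "M2A": (True, True, False),
    "M2B": (True, False, True),
    "M2C": (False, True, True),
}

#: The seven study schemes, keyed by id. The eighth flag combination
#: (everything tied) is constructible via ConstraintScheme directly but is
#: not part of the study grid.
SCHEMES: dict[str, ConstraintScheme] = {
    sid: ConstraintScheme(sid, *flags) for sid, flags in _FLAGS.items()
}

SCHEME_IDS = tuple(SCHEMES)


def get_scheme(scheme: "str | ConstraintScheme") -> ConstraintScheme:
    """Resolve a scheme id or pass an existing scheme through."""
    if isinstance(scheme, ConstraintScheme):
        return scheme
    try:
        return SCHEMES[scheme.upper()]
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {', '.join(SCHEME_IDS)}"
        ) from None
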
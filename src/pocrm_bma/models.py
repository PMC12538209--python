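"""One-parameter power working models for dose-toxicity curves.

Two parametrizations of the power model are supported.  ``power_exp`` is the
default used for inference::

    psi(alpha, a) = alpha ** exp(a),        a in R,  a ~ Normal(mean, var)

so every real ``a`` yields a valid probability.  ``power_plain``::

    psi(alpha, a) = alpha ** a,             a in (0, inf)

keeps the exponent itself as the parameter; its prior is the same Normal
truncated to the positive half-line.  The plain form is the parametrization
under which the closed-form 2x2 coherency conditions are stated (there the
exponent estimate is simply log R / log alpha), so the theory checkers in
:mod:`pocrm_bma.coherency` require it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["WorkingModelConfig"]

# Probabilities are clipped to this band inside logs; skeleton values live
# well inside it, so clipping only guards extreme exponents.
PROB_CLIP = 1e-12


@dataclass(frozen=True)
class WorkingModelConfig:
    """Parametrization and prior of the one-parameter power model."""

    parametrization: str = "power_exp"
    prior_mean: float = 0.0
    prior_var: float = 1.34

    def __post_init__(self) -> None:
        if self.parametrization not in ("power_exp", "power_plain"):
            raise InvalidParameterError(
                f"unknown parametrization {self.parametrization!r}"
            )
        if self.prior_var <= 0:
            raise InvalidParameterError("prior_var must be positive")

    @property
    def prior_sd(self) -> float:
        return float(np.sqrt(self.prior_var))

    def exponent(self, a):
        """Map the model parameter to the power-model exponent."""
        a = np.asarray(a, dtype=float)
        if self.parametrization == "power_exp":
            return np.exp(np.clip(a, -700.0, 700.0))
        return a

    def psi(self, alpha, a):
        """Toxicity probability ``alpha ** exponent(a)``, clipped to (0, 1).

        Broadcasts ``alpha`` against ``a``; callers shape the arrays.
        """
        alpha = np.asarray(alpha, dtype=float)
        e = self.exponent(a)
        with np.errstate(over="ignore", under="ignore"):
            p = alpha ** e
        return np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)

    def inverse(self, alpha: float, r):
        """Solve psi(alpha, a) = r for a."""
        r = np.asarray(r, dtype=float)
        t = np.log(r) / np.log(alpha)  # the exponent, > 0
        if self.parametrization == "power_exp":
            return np.log(t)
        return t

    def dinverse_dr(self, alpha: float, r):
        """|da/dr| of the inverse map, the change-of-variables Jacobian."""
        r = np.asarray(r, dtype=float)
        if self.parametrization == "power_exp":
            # a = log(log r / log alpha) => |da/dr| = 1 / (r |log r|)
            return 1.0 / (r * np.abs(np.log(r)))
        # a = log r / log alpha => |da/dr| = 1 / (r |log alpha|)
        return 1.0 / (r * np.abs(np.log(alpha)))

    def to_dict(self) -> dict:
        return {
            "parametrization": self.parametrization,
            "prior_mean": self.prior_mean,
            "prior_var": self.prior_var,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WorkingModelConfig":
        return cls(
            parametrization=d.get("parametrization", "power_exp"),
            prior_mean=float(d.get("prior_mean", 0.0)),
            prior_var=float(d.get("prior_var", 1.34)),
        )
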
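"""Parameter containers for the univariate and bivariate causal mixture models.

The univariate model assumes per-variant additive effects follow a point-normal
mixture ``beta ~ (1-pi1) N(0,0) + pi1 N(0, sigma_beta2)`` and GWAS z-scores add
a residual "variance distortion" ``N(0, sigma0_2)`` absorbing cryptic
relatedness and uncontrolled confounding (the analogue of the LD-score
regression intercept).

The bivariate model classifies variants into four components: null for both
traits, causal for trait 1 only, for trait 2 only, or for both; the shared
component carries an effect-size correlation ``rho12``, and residuals of the
two GWAS carry a correlation ``rho0`` produced by sample overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class UnivariateParams:
    """Univariate point-normal mixture parameters.

    Attributes
    ----------
    pi1 : float
        Fraction of reference variants causal for the trait, in (0, 1].
    sigma_beta2 : float
        Variance of the per-allele effect size among causal variants.
    sigma0_2 : float
        Variance of the z-score residual (1.0 for a perfectly calibrated GWAS).
    """

    pi1: float
    sigma_beta2: float
    sigma0_2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pi1 <= 1.0):
            raise ValueError(f"pi1 must be in (0, 1], got {self.pi1}")
        if self.sigma_beta2 < 0.0:
            raise ValueError(f"sigma_beta2 must be >= 0, got {self.sigma_beta2}")
        if self.sigma0_2 <= 0.0:
            raise ValueError(f"sigma0_2 must be > 0, got {self.sigma0_2}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "UnivariateParams":
        return cls(pi1=d["pi1"], sigma_beta2=d["sigma_beta2"], sigma0_2=d["sigma0_2"])


@dataclass(frozen=True)
class BivariateParams:
    """Four-component bivariate mixture parameters.

    Component weights ``pi1``, ``pi2`` (trait-specific) and ``pi12`` (shared)
    must sum to at most 1; the remainder is the null weight. ``rho12`` is the
    effect-size correlation inside the shared component; ``rho0`` the residual
    correlation between the two GWAS.
    """

    pi1: float
    pi2: float
    pi12: float
    sigma1_2: float
    sigma2_2: float
    rho12: float = 0.0
    sigma01_2: float = 1.0
    sigma02_2: float = 1.0
    rho0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pi1", "pi2", "pi12"):
            v = getattr(self, name)
            if v < 0.0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.pi1 + self.pi2 + self.pi12 > 1.0 + 1e-12:
            raise ValueError("pi1 + pi2 + pi12 must be <= 1")
        for name in ("sigma1_2", "sigma2_2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma01_2", "sigma02_2"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rho12", "rho0"):
            if abs(getattr(self, name)) > 1.0:
                raise ValueError(f"|{name}| must be <= 1")

    @property
    def pi0(self) -> float:
        return max(0.0, 1.0 - self.pi1 - self.pi2 - self.pi12)

    @property
    def pi1u(self) -> float:
        """Total polygenicity of trait 1: pi1 + pi12."""
        return self.pi1 + self.pi12

    @property
    def pi2u(self) -> float:
        """Total polygenicity of trait 2: pi2 + pi12."""
        return self.pi2 + self.pi12

    def trait(self, which: int) -> UnivariateParams:
        """Marginal univariate parameters for trait 1 or 2."""
        if which == 1:
            return UnivariateParams(max(self.pi1u, 1e-300), self.sigma1_2, self.sigma01_2)
        if which == 2:
            return UnivariateParams(max(self.pi2u, 1e-300), self.sigma2_2, self.sigma02_2)
        raise ValueError("which must be 1 or 2")

    def with_(self, **kw) -> "BivariateParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BivariateParams":
        keys = (
            "pi1",
            "pi2",
            "pi12",
            "sigma1_2",
            "sigma2_2",
            "rho12",
            "sigma01_2",
            "sigma02_2",
            "rho0",
        )
        return cls(**{k: d[k] for k in keys})


def save_params(params, path) -> None:
    """Serialize parameters (with their class tag) to a JSON file."""
    payload = {"class": type(params).__name__, "params": params.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_params(path):
    with open(path) as fh:
        payload = json.load(fh)
    cls = {"UnivariateParams": UnivariateParams, "BivariateParams": BivariateParams}[
        payload["class"]
    ]
    return cls.from_dict(payload["params"])
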
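"""Pure model mathematics for the mean-variance scale effect.

The scale effect is the statistical relationship whereby a trait with a
larger mean also shows a larger standard deviation; a constant coefficient
of variation (CV) across the trait range is the extreme case.  This module
implements the deterministic pieces of the simulation that quantifies the
genetic mean-variability correlation generated by that effect:

1. reference (homogeneous) variance components from ``mu``, ``CV`` and the
   heritability ``h2``;
2. a homoscedastic base draw ``y = mu + a + e`` from supplied
   standard-normal deviates (the RNG lives in :mod:`varscale.engine`);
3. the per-individual scale-effect transformation that makes every
   standard deviation proportional to the individual's own record;
4. the breeding-value constructions: the rescaled trait breeding value
   ``u_i = a_i * sigma_ui / sigma_u`` and the environmental (log residual
   variance) breeding value ``v_i = 2 * r * ln(sigma_ei / sigma_e)``, where
   ``0 < r <= 1`` attenuates the strength of the scale effect;
5. the two summary statistics of a simulated population: the Pearson
   correlation of ``(u, v)`` and the genetic coefficient of variation of
   the environmental variance, ``GCV ~ sqrt(Var(v))``.

Everything here is a pure function of its inputs: given the same deviate
vectors the output is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "ScenarioConfig",
    "VarianceComponents",
    "PopulationDraw",
    "NegativeHandling",
    "derive_variance_components",
    "simulate_base_records",
    "scale_deviations",
    "environmental_breeding_values",
    "rescale_trait_breeding_values",
    "pearson_correlation",
    "gcv_from_v",
    "simulate_population",
]

#: How records with a negative phenotype are folded back to positive
#: standard deviations.  ``"fold_phenotype"`` applies the absolute value at
#: the level of the scaled phenotypic SD (sigma_pi = CV * |y_i|), which
#: keeps sigma_ei, sigma_ui and v consistently positive and finite.
#: ``"flip_residual"`` flips only the residual SD to positive and leaves
#: sigma_pi and sigma_ui signed; it is exposed for sensitivity analysis.
NegativeHandling = Literal["fold_phenotype", "flip_residual"]


def _check_cv_h2(cv: float, h2: float) -> None:
    if not cv > 0:
        raise ValueError(f"cv must be positive, got {cv}")
    if not 0 < h2 < 1:
        raise ValueError(f"h2 must lie strictly in (0, 1), got {h2}")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    Parameters
    ----------
    cv
        Coefficient of variation of the trait (dimensionless).
    h2
        Narrow-sense heritability, strictly inside (0, 1).
    mu
        Trait mean, in trait units.  Must be positive.
    r
        Strength of the scale effect, 0 < r <= 1.  r = 1 means the CV is
        constant across the whole trait range; smaller r attenuates how
        fully the trait level determines the residual variance.
    n_individuals
        Records simulated per replicate.
    n_replicates
        Independent replicates averaged within the scenario.
    seed
        Master seed for the scenario's random streams.
    """

    cv: float
    h2: float
    mu: float = 100.0
    r: float = 1.0
    n_individuals: int = 100_000
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        _check_cv_h2(self.cv, self.h2)
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not 0 < self.r <= 1:
            raise ValueError(f"r must lie in (0, 1], got {self.r}")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be at least 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass(frozen=True)
class VarianceComponents:
    """Reference (homogeneous) variance components and their roots."""

    sigma_p2: float
    sigma_u2: float
    sigma_e2: float
    sigma_p: float
    sigma_u: float
    sigma_e: float


@dataclass(frozen=True)
class PopulationDraw:
    """All per-individual vectors of one simulated replicate.

    ``v`` is on the log-variance scale (dimensionless); every other vector
    is in trait units.  ``n_negative`` counts records with ``y < 0`` (they
    arise for large CV and are folded positive before taking logs).
    """

    a: np.ndarray
    e: np.ndarray
    y: np.ndarray
    sigma_pi: np.ndarray
    sigma_ei: np.ndarray
    sigma_ui: np.ndarray
    u: np.ndarray
    v: np.ndarray
    n_negative: int


def derive_variance_components(mu: float, cv: float, h2: float) -> VarianceComponents:
    """Derive the homogeneous variance components of the base model.

    The phenotypic variance is fixed by the mean and the coefficient of
    variation, ``sigma_p^2 = (cv * mu)^2``, and split by the heritability
    into additive-genetic and residual parts::

        sigma_u^2 = h2 * sigma_p^2
        sigma_e^2 = (1 - h2) * sigma_p^2
    """
    _check_cv_h2(cv, h2)
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    sigma_p = cv * mu
    sigma_p2 = sigma_p**2
    sigma_u2 = h2 * sigma_p2
    sigma_e2 = (1.0 - h2) * sigma_p2
    # roots are built in the same floating-point form as the elementwise
    # scaled SDs, so a record at |y| = mu reproduces them bit for bit
    return VarianceComponents(
        sigma_p2=sigma_p2,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        sigma_p=sigma_p,
        sigma_u=sigma_p * np.sqrt(h2),
        sigma_e=sigma_p * np.sqrt(1.0 - h2),
    )


def simulate_base_records(
    vc: VarianceComponents,
    mu: float,
    z_a: np.ndarray,
    z_e: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Homoscedastic base draw ``y = mu + a + e``.

    ``a = sigma_u * z_a`` and ``e = sigma_e * z_e`` with ``z_a``, ``z_e``
    standard-normal deviate vectors supplied by the caller, so the result
    is deterministic given the deviates.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_e = np.asarray(z_e, dtype=float)
    if z_a.shape != z_e.shape:
        raise ValueError(
            f"deviate vectors must have the same shape, got {z_a.shape} and {z_e.shape}"
        )
    a = vc.sigma_u * z_a
    e = vc.sigma_e * z_e
    y = mu + a + e
    return a, e, y


def scale_deviations(
    y: np.ndarray,
    cv: float,
    h2: float,
    *,
    negative_handling: NegativeHandling = "fold_phenotype",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-individual scaled standard deviations under the scale effect.

    Each individual's phenotypic SD becomes proportional to its own record,
    ``sigma_pi = cv * y_i``, and the heritability split is preserved
    elementwise: ``sigma_ei = sigma_pi * sqrt(1 - h2)`` and
    ``sigma_ui = sigma_pi * sqrt(h2)``.

    Occasional negative records (large CV only) would give negative SDs;
    they are folded positive according to ``negative_handling`` and counted
    in the returned ``n_negative``.

    Returns
    -------
    (sigma_pi, sigma_ei, sigma_ui, n_negative)
    """
    _check_cv_h2(cv, h2)
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("y must be non-empty")
    if np.any(y == 0.0):
        raise ValueError(
            "a record is exactly 0: its log-scale environmental breeding value "
            "is undefined"
        )
    n_negative = int(np.count_nonzero(y < 0))
    if negative_handling == "fold_phenotype":
        sigma_pi = cv * np.abs(y)
        sigma_ei = sigma_pi * np.sqrt(1.0 - h2)
        sigma_ui = sigma_pi * np.sqrt(h2)
    elif negative_handling == "flip_residual":
        sigma_pi = cv * y
        sigma_ei = np.abs(sigma_pi) * np.sqrt(1.0 - h2)
        sigma_ui = sigma_pi * np.sqrt(h2)
    else:
        raise ValueError(f"unknown negative_handling {negative_handling!r}")
    return sigma_pi, sigma_ei, sigma_ui, n_negative


def environmental_breeding_values(
    sigma_ei: np.ndarray,
    sigma_e: float,
    r: float = 1.0,
) -> np.ndarray:
    """Environmental breeding values ``v_i = 2 * r * ln(sigma_ei / sigma_e)``.

    Under the exponential model for the residual variance, ``v_i`` is the
    additive genetic effect on the log residual variance implied by the
    individual's scaled residual SD relative to the homogeneous reference
    ``sigma_e``.  The strength ``r`` (0 < r <= 1) attenuates the scale
    effect; r = 1 leaves it at full strength.  Note that the sample mean of
    ``v`` is not expected to be 0, a consequence of the exponential nature
    of the model.
    """
    sigma_ei = np.asarray(sigma_ei, dtype=float)
    if not sigma_e > 0:
        raise ValueError(f"sigma_e must be positive, got {sigma_e}")
    if not 0 < r <= 1:
        raise ValueError(f"r must lie in (0, 1], got {r}")
    if np.any(sigma_ei <= 0):
        raise ValueError("all sigma_ei must be strictly positive")
    return (2.0 * r) * np.log(sigma_ei / sigma_e)


def rescale_trait_breeding_values(
    a: np.ndarray,
    sigma_ui: np.ndarray,
    sigma_u: float,
) -> np.ndarray:
    """Rescaled trait breeding values ``u_i = a_i * sigma_ui / sigma_u``.

    The base additive effect ``a_i`` was drawn under the homogeneous
    variance ``sigma_u^2``; multiplying by the individual's own genetic SD
    ratio carries the scale effect into the trait breeding value.
    """
    a = np.asarray(a, dtype=float)
    sigma_ui = np.asarray(sigma_ui, dtype=float)
    if a.shape != sigma_ui.shape:
        raise ValueError(
            f"a and sigma_ui must have the same shape, got {a.shape} and {sigma_ui.shape}"
        )
    if not sigma_u > 0:
        raise ValueError(f"sigma_u must be positive, got {sigma_u}")
    if np.any(sigma_ui == 0):
        raise ValueError("sigma_ui must be non-zero everywhere")
    return a * sigma_ui / sigma_u


def pearson_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Sample Pearson product-moment correlation of two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must have the same shape")
    if u.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    return float(np.corrcoef(u, v)[0, 1])


def gcv_from_v(v: np.ndarray) -> float:
    """Genetic coefficient of variation of the environmental variance.

    Approximated as the square root of the sample variance (n - 1
    denominator) of the environmental breeding values ``v``.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(v) == 0:
        return 0.0
    return float(np.sqrt(np.var(v, ddof=1)))


def simulate_population(
    config: ScenarioConfig,
    z_a: np.ndarray,
    z_e: np.ndarray,
    *,
    negative_handling: NegativeHandling = "fold_phenotype",
) -> PopulationDraw:
    """Run the full deterministic chain for one replicate.

    Base draw -> per-individual scaling -> breeding values, from supplied
    standard-normal deviates.
    """
    vc = derive_variance_components(config.mu, config.cv, config.h2)
    a, e, y = simulate_base_records(vc, config.mu, z_a, z_e)
    sigma_pi, sigma_ei, sigma_ui, n_negative = scale_deviations(
        y, config.cv, config.h2, negative_handling=negative_handling
    )
    v = environmental_breeding_values(sigma_ei, vc.sigma_e, config.r)
    u = rescale_trait_breeding_values(a, sigma_ui, vc.sigma_u)
    return PopulationDraw(
        a=a,
        e=e,
        y=y,
        sigma_pi=sigma_pi,
        sigma_ei=sigma_ei,
        sigma_ui=sigma_ui,
        u=u,
        v=v,
        n_negative=n_negative,
    )
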
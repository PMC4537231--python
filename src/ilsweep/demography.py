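"""Coalescent expectations for incomplete lineage sorting (ILS).

For three species with two speciation events in quick succession (e.g. human,
chimpanzee and gorilla), a locus shows ILS whenever the two most closely
related lineages fail to coalesce in their own ancestral population and
instead coalesce deeper, where each of the three rooted topologies is equally
likely.  With speciation-time difference ``delta_tau`` and ancestral diversity
``theta`` (both scaled by the per-generation mutation rate) the probability of
no coalescence over the interval is ``exp(-delta_tau/theta)``, and two of the
three deep topologies are discordant, giving

    Pr(ILS) = 2/3 * exp(-delta_tau / theta).

The same quantity can be written in generation units: if ``pi`` is the
population-scaled diversity of the ancestor (the expected pairwise coalescence
time in generations, i.e. ``2*Ne_A``) and ``delta_T_years / g`` the number of
generations between the two speciation events, then for a chromosome whose
effective size is a factor ``x_factor`` of the autosomal one,

    ILS = 2/3 * exp(-(delta_T_years/g) / (x_factor * pi)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MAX_ILS",
    "ScaledDemography",
    "GenerationDemography",
    "expected_ils",
    "ils_from_pi",
    "pi_from_ils",
    "relative_ils",
]

#: Maximal possible ILS fraction: simultaneous speciations leave all three
#: topologies equally likely, two of which are discordant.
MAX_ILS = 2.0 / 3.0


@dataclass(frozen=True)
class ScaledDemography:
    """Two-speciation demography in mutation-scaled units.

    Speciation times are scaled as ``2*Ne*u*g`` and ancestral diversities as
    ``2*Ne*u`` (``u`` mutation rate per generation, ``g`` generation time,
    ``Ne`` a reference extant population size used only for scaling).

    Attributes
    ----------
    tau_hc, tau_hcg:
        Speciation times of the (human, chimpanzee) and (HC ancestor, gorilla)
        splits.  ``tau_hcg`` must exceed ``tau_hc``.
    theta_hc, theta_hcg:
        Ancestral diversities of the HC and HCG ancestral populations.
    rho:
        Recombination rate (scaled by ``u``); carried along for generators.
    """

    tau_hc: float
    tau_hcg: float
    theta_hc: float
    theta_hcg: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_hc", "tau_hcg", "theta_hc", "theta_hcg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.tau_hcg <= self.tau_hc:
            raise ValueError("tau_hcg must exceed tau_hc")

    @property
    def delta_tau(self) -> float:
        """Scaled time between the two speciation events."""
        return self.tau_hcg - self.tau_hc

    def expected_ils(self) -> float:
        return expected_ils(self.delta_tau, self.theta_hc)


@dataclass(frozen=True)
class GenerationDemography:
    """Demography in years/generations, for the generation-unit ILS formula.

    Defaults are the human–chimpanzee ancestor values used throughout:
    2.25 Myr between the HC and HCG speciations, 20-year generations, an
    ancestral (X) effective population size of 73,200 diploids, mutation rate
    1e-9 per site per generation, recombination 1 cM/Mb, and the 3/4 male
    hemizygosity factor for the X chromosome.
    """

    delta_T_years: float = 2_250_000.0
    g: float = 20.0
    Ne: float = 73_200.0
    u: float = 1e-9
    r_per_bp: float = 1e-8
    x_factor: float = 0.75

    def __post_init__(self) -> None:
        for name in ("delta_T_years", "g", "Ne", "u", "r_per_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.x_factor <= 1.0):
            raise ValueError("x_factor must lie in (0, 1]")

    @property
    def delta_tau_generations(self) -> float:
        """Generations between the two speciation events (``delta_T_years/g``)."""
        return self.delta_T_years / self.g


def expected_ils(delta_tau: float, theta: float) -> float:
    """Expected ILS fraction ``2/3 * exp(-delta_tau/theta)``.

    Parameters
    ----------
    delta_tau:
        Scaled time between the two speciation events (>= 0).
    theta:
        Scaled ancestral diversity of the two most closely related species
        (> 0).  For an X chromosome with effective size 3/4 of the autosomes
        pass ``0.75 * theta_autosomal``.

    Returns
    -------
    float
        ILS fraction in (0, 2/3].
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if delta_tau < 0:
        raise ValueError("delta_tau must be non-negative")
    return MAX_ILS * math.exp(-delta_tau / theta)


def ils_from_pi(pi: float, demog: GenerationDemography) -> float:
    """ILS fraction implied by ancestral diversity ``pi`` (generation units).

    ``pi`` is the population-scaled diversity playing the role of ``2*Ne_A``
    (expected pairwise coalescence time in generations).  Monotone increasing
    in ``pi``; approaches 2/3 as ``pi`` grows.
    """
    if pi <= 0:
        raise ValueError("pi must be positive")
    return MAX_ILS * math.exp(-demog.delta_tau_generations / (demog.x_factor * pi))


def pi_from_ils(ils: float, demog: GenerationDemography) -> float:
    """Invert :func:`ils_from_pi`: diversity implied by an observed ILS level."""
    if not (0.0 < ils < MAX_ILS):
        raise ValueError("ils must lie strictly between 0 and 2/3")
    return demog.delta_tau_generations / (demog.x_factor * (-math.log(ils / MAX_ILS)))


def relative_ils(pi0: float, pi: float, demog: GenerationDemography) -> float:
    """Ratio ILS(pi)/ILS(pi0) = exp((ΔT/g)/x_factor * (1/pi0 − 1/pi)).

    Equals :func:`ils_from_pi`(pi)/:func:`ils_from_pi`(pi0); the closed form
    avoids evaluating the common 2/3 prefactor.
    """
    if pi0 <= 0 or pi <= 0:
        raise ValueError("pi0 and pi must be positive")
    scale = demog.delta_tau_generations / demog.x_factor
    return math.exp(scale * (1.0 / pi0 - 1.0 / pi))
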
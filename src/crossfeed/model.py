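"""Analytic model of amino-acid cross-feeding in dense microbial communities.

Two auxotrophic strains grow as a densely packed community and exchange the
amino acids each of them cannot synthesize.  Each exchanged amino acid defines
a producer->consumer direction: the producer leaks it passively at rate ``l``
while maintaining a constant internal concentration ``I_C``; every cell takes
it up with a non-saturating rate ``u``; the consumer's growth follows Monod
kinetics ``mu = mu_n * I / (I + 1)`` with the internal concentration ``I``
measured in units of the Monod constant.  Molecules diffuse only through the
space between cells, so the bulk diffusion constant ``D`` is reduced to an
effective value that depends on the cell volume fraction ``rho``.

From these ingredients the model yields closed forms for

* the interaction range ``R_int`` over which a leaked amino acid couples
  consumer growth to producer location,
* the number of interaction partners ``N`` within that range (cells modelled
  as spherocylinders of length ``L`` and width ``W``),
* the maximal growth rate ``mu_hat`` a consumer can reach when fully
  surrounded by producers,
* the equilibrium strain frequency of the two-strain community, and
* the community growth rate relative to growth on supplemented medium.

Units are fixed package-wide: rates in 1/h, lengths in um, diffusion in
um^2/h, concentrations in units of the Monod constant.  Loss of leaked
molecules into the agar below the colony is represented by supplying a lower
*effective* leakage rate; no separate correction is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "StrainRates",
    "ExchangePairParams",
    "EnvironmentParams",
    "InteractionRangeResult",
    "GrowthCap",
    "CommunityPrediction",
    "ModelDomainError",
    "InteractionRangeUndefinedError",
    "effective_diffusion",
    "interaction_range",
    "partner_count",
    "growth_cap",
    "equilibrium_frequency",
    "relative_growth",
    "predict_community",
]


class ModelDomainError(ValueError):
    """Raised when inputs fall outside the model's domain of validity."""


class InteractionRangeUndefinedError(ModelDomainError):
    """The closed-form interaction range is undefined for these parameters.

    Carries the offending intermediate quantities so that fitting code can
    diagnose (and penalize) the trial point instead of receiving a NaN.
    """

    def __init__(self, message: str, *, l_tilde_n: float, delta: float,
                 numerator: float, denominator: float):
        super().__init__(
            f"{message} (l_tilde_n={l_tilde_n:.6g}, delta={delta:.6g}, "
            f"numerator={numerator:.6g}, denominator={denominator:.6g})"
        )
        self.l_tilde_n = l_tilde_n
        self.delta = delta
        self.numerator = numerator
        self.denominator = denominator


@dataclass(frozen=True)
class StrainRates:
    """Kinetic parameters of one strain with respect to one amino acid.

    Parameters
    ----------
    uptake : float
        Non-saturating import rate ``u`` (1/h).
    leakage : float
        Passive (effective) export rate ``l`` (1/h).  Must be below
        ``uptake``; the fitting layer enforces the stronger ``l <= u/1000``
        bound used for inference.
    max_growth : float
        Maximal growth rate ``mu_n`` of the auxotroph when the amino acid is
        plentiful (1/h).
    producer_internal_conc : float
        Internal concentration ``I_C`` maintained when this strain is the
        producer, in units of the Monod constant.
    """

    uptake: float
    leakage: float
    max_growth: float
    producer_internal_conc: float

    def __post_init__(self) -> None:
        for name in ("uptake", "leakage", "max_growth", "producer_internal_conc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"StrainRates.{name} must be strictly positive")
        if not self.leakage < self.uptake:
            raise ValueError("leakage must be smaller than uptake")


@dataclass(frozen=True)
class ExchangePairParams:
    """Producer/consumer parameter pair for one exchanged amino acid.

    ``consumer`` is the auxotroph that requires this amino acid (subscript
    ``n``); ``producer`` is the strain that synthesizes and leaks it
    (subscript ``p``).  A two-strain community has two records, one per
    exchange direction.
    """

    consumer: StrainRates
    producer: StrainRates


@dataclass(frozen=True)
class EnvironmentParams:
    """Physical environment of the packed community.

    ``cell_density`` is the cell volume fraction ``rho`` in [0, 1);
    ``diffusion_D`` the amino-acid diffusion constant in solution (um^2/h);
    ``cell_length``/``cell_width`` the spherocylinder dimensions ``L`` and
    ``W`` (um), with ``L >= W``.
    """

    cell_density: float
    diffusion_D: float
    cell_length: float
    cell_width: float

    def __post_init__(self) -> None:
        if not 0 <= self.cell_density < 1:
            raise ValueError("cell_density must lie in [0, 1)")
        if not self.diffusion_D > 0:
            raise ValueError("diffusion_D must be positive")
        if not self.cell_width > 0:
            raise ValueError("cell_width must be positive")
        if self.cell_length < self.cell_width:
            raise ValueError("cell_length must be >= cell_width")

    @property
    def alpha(self) -> float:
        """Intra- to extracellular volume ratio ``rho / (1 - rho)``."""
        return self.cell_density / (1.0 - self.cell_density)


@dataclass(frozen=True)
class InteractionRangeResult:
    """Interaction range ``R_int`` with its intermediate length/ratio scales."""

    R_int: float
    r_0: float
    delta: float
    l_tilde_n: float


@dataclass(frozen=True)
class GrowthCap:
    """Growth ceiling of a consumer fully surrounded by producers.

    ``E_hat`` and ``I_hat`` are the external and internal amino-acid
    concentrations in Monod units; ``mu_hat`` the resulting growth rate.
    """

    E_hat: float
    I_hat: float
    mu_hat: float


@dataclass(frozen=True)
class CommunityPrediction:
    """Full prediction for a two-strain cross-feeding community.

    ``range_dP`` / ``N_dP`` / ``cap_dP`` refer to the amino acid the focal
    strain (by convention the proline auxotroph, dP) consumes; the dT fields
    to the partner's direction.  ``f_dP`` is the equilibrium frequency of the
    focal strain (clamped to [0, 1] with a flag if the raw closed form falls
    outside), ``r_rel`` the predicted community growth rate relative to
    growth with supplemented amino acids.
    """

    range_dP: InteractionRangeResult
    range_dT: InteractionRangeResult
    N_dP: float
    N_dT: float
    cap_dP: GrowthCap
    cap_dT: GrowthCap
    f_dP: float
    f_dP_raw: float
    r_rel: float
    validity_flags: tuple[str, ...] = field(default_factory=tuple)


def effective_diffusion(D: float, rho: float) -> float:
    """Effective diffusion constant in a suspension of volume fraction ``rho``.

    Molecules diffuse only through the extracellular space, giving
    ``D_eff = (1 - rho) / (1 + rho/2) * D``.  Strictly decreasing in ``rho``,
    equal to ``D`` at ``rho = 0`` and vanishing as ``rho -> 1``.
    """
    if not D > 0:
        raise ModelDomainError("diffusion constant must be positive")
    if not 0 <= rho < 1:
        raise ModelDomainError("cell density must lie in [0, 1)")
    return (1.0 - rho) / (1.0 + rho / 2.0) * D


def interaction_range(pair: ExchangePairParams,
                      env: EnvironmentParams) -> InteractionRangeResult:
    """Closed-form interaction range for one exchange direction.

    With ``l_tilde = l_n / mu_n``, ``alpha = rho / (1 - rho)`` and
    ``r_0 = sqrt(D_eff / (alpha (u_n + l_n)))`` the range is

        R_int = r_0 * ln( [ (2 lt - d) sqrt(4 d + (lt + d)^2)
                            - d (4 + d) + lt (2 lt - 3 d) ]
                          / [ 2 lt (lt - d) - d ] )

    where ``d`` (delta) aggregates the producer's leakage flux ``l_p I_C``
    relative to the consumer's growth rate.  No low-leakage approximation is
    made.  Outside the expression's domain (log argument <= 1) an
    :class:`InteractionRangeUndefinedError` is raised rather than returning a
    number.
    """
    if not env.cell_density > 0:
        raise ModelDomainError("interaction range requires cell_density > 0")
    n, p = pair.consumer, pair.producer
    mu_n = n.max_growth
    lt = n.leakage / mu_n
    s_n = math.sqrt(n.uptake + n.leakage)
    s_p = math.sqrt(p.uptake + p.leakage)
    delta = (p.leakage * p.producer_internal_conc / (2.0 * mu_n)) \
        * (2.0 * s_p / (s_n + s_p)) \
        * ((n.uptake + n.leakage) / (p.uptake + p.leakage))
    d_eff = effective_diffusion(env.diffusion_D, env.cell_density)
    r_0 = math.sqrt(d_eff / (env.alpha * (n.uptake + n.leakage)))

    num = (2.0 * lt - delta) * math.sqrt(4.0 * delta + (lt + delta) ** 2) \
        - delta * (4.0 + delta) + lt * (2.0 * lt - 3.0 * delta)
    den = 2.0 * lt * (lt - delta) - delta
    # Numerator and denominator share their root in delta (a removable
    # singularity), so both-negative is a valid region; only den == 0 exactly
    # or a log argument <= 1 is outside the expression's domain.
    if den == 0 or num / den <= 1.0:
        raise InteractionRangeUndefinedError(
            "interaction range undefined for these parameters",
            l_tilde_n=lt, delta=delta, numerator=num, denominator=den,
        )
    return InteractionRangeResult(
        R_int=r_0 * math.log(num / den), r_0=r_0, delta=delta, l_tilde_n=lt,
    )


def partner_count(R_int: float, env: EnvironmentParams) -> float:
    """Expected number of cells within ``R_int`` of a cell's surface.

    Cells are spherocylinders (cylinders with hemispherical caps) of total
    length ``L`` and width ``W``.  The count is the volume of the shell of
    thickness ``R_int`` around the cell surface divided by the cell volume,
    times the volume fraction ``rho``:

        N = rho * [ R (R + W) (L - W) + 4/3 ((R + W/2)^3 - (W/2)^3) ]
                / [ (L - W) (W/2)^2 + 4/3 (W/2)^3 ]

    Returned as a continuous quantity (an expectation, not an integer).
    """
    if R_int < 0:
        raise ModelDomainError("R_int must be non-negative")
    if not 0 < env.cell_density < 1:
        raise ModelDomainError("partner count requires cell_density in (0, 1)")
    L, W = env.cell_length, env.cell_width
    R = R_int
    num = R * (R + W) * (L - W) + 4.0 / 3.0 * ((R + W / 2.0) ** 3 - (W / 2.0) ** 3)
    den = (L - W) * (W / 2.0) ** 2 + 4.0 / 3.0 * (W / 2.0) ** 3
    return num / den * env.cell_density


def growth_cap(pair: ExchangePairParams) -> GrowthCap:
    """Maximal consumer growth rate when fully surrounded by producers.

    ``E_hat = l_p / (u_p + l_p) * I_C`` is the external concentration in a
    region fully occupied by producers; ``I_hat`` the internal concentration
    of an isolated consumer there (root of the uptake/leakage/growth dilution
    balance); ``mu_hat = mu_n * I_hat / (1 + I_hat)``.
    """
    n, p = pair.consumer, pair.producer
    E_hat = p.leakage / (p.uptake + p.leakage) * p.producer_internal_conc
    un_ln = n.uptake + n.leakage
    I_hat = (un_ln * E_hat - n.leakage
             + math.sqrt((un_ln * E_hat + n.leakage) ** 2
                         + 4.0 * un_ln * n.max_growth * E_hat)) \
        / (2.0 * (n.max_growth + n.leakage))
    mu_hat = n.max_growth * I_hat / (1.0 + I_hat)
    return GrowthCap(E_hat=E_hat, I_hat=I_hat, mu_hat=mu_hat)


def equilibrium_frequency(cap_dP: GrowthCap, cap_dT: GrowthCap,
                          N_dP: float, N_dT: float) -> tuple[float, float, tuple[str, ...]]:
    """Equilibrium frequency of the focal (dP) strain.

    The closed form (death-birth dynamics on the interaction graph) is

        f = [ muP (N_P - 2)/N_P + (muP/N_P - muT/N_T) ]
            / [ muP (N_P - 2)/N_P + muT (N_T - 2)/N_T ]

    with ``muP = cap_dP.mu_hat`` etc.  Because the derivation assumes amino
    acids are always growth-limiting, the raw value can leave [0, 1] (e.g.
    for overproducers); it is then clamped and flagged.

    Returns
    -------
    (f_clamped, f_raw, flags)
    """
    if N_dP <= 2 or N_dT <= 2:
        raise ModelDomainError(
            "partner count too small for composition formula (need N > 2)")
    muP, muT = cap_dP.mu_hat, cap_dT.mu_hat
    if muP == 0 and muT == 0:
        raise ModelDomainError("composition undefined: both growth caps are zero")
    num = muP * (N_dP - 2.0) / N_dP + (muP / N_dP - muT / N_dT)
    den = muP * (N_dP - 2.0) / N_dP + muT * (N_dT - 2.0) / N_dT
    raw = num / den
    flags: tuple[str, ...] = ()
    clamped = raw
    if raw < 0.0 or raw > 1.0:
        clamped = min(max(raw, 0.0), 1.0)
        flags = ("composition_out_of_bounds",)
    return clamped, raw, flags


def relative_growth(f_dP: float, cap_dP: GrowthCap, cap_dT: GrowthCap,
                    N_dP: float, N_dT: float, mu_n: float) -> float:
    """Community growth rate relative to growth on supplemented medium.

        r_rel = f (1 - f) / mu_n * [ (N_P - 2)/(N_P - 1) muP
                                     + (N_T - 2)/(N_T - 1) muT ]

    Vanishes at ``f`` in {0, 1} and is maximal at ``f = 1/2`` for fixed caps.
    """
    if not 0.0 <= f_dP <= 1.0:
        raise ModelDomainError("f_dP must lie in [0, 1]")
    if N_dP <= 1 or N_dT <= 1:
        raise ModelDomainError("relative growth requires N > 1")
    return f_dP * (1.0 - f_dP) / mu_n * (
        (N_dP - 2.0) / (N_dP - 1.0) * cap_dP.mu_hat
        + (N_dT - 2.0) / (N_dT - 1.0) * cap_dT.mu_hat
    )


def predict_community(pair_dP: ExchangePairParams, pair_dT: ExchangePairParams,
                      env: EnvironmentParams) -> CommunityPrediction:
    """Compose the closed forms into a full two-strain community prediction.

    ``pair_dP`` is the exchange direction feeding the focal strain (the amino
    acid it consumes); ``pair_dT`` the direction feeding the partner.  All
    intermediate quantities are exposed on the returned record; flags from
    sub-operations propagate with direction labels.

    The relative-growth normalization uses the mean of the two consumers'
    ``mu_n`` (they coincide for isogenic auxotroph pairs).
    """
    flags: list[str] = []
    try:
        rng_dP = interaction_range(pair_dP, env)
    except InteractionRangeUndefinedError as exc:
        raise ModelDomainError(f"dP direction: {exc}") from exc
    try:
        rng_dT = interaction_range(pair_dT, env)
    except InteractionRangeUndefinedError as exc:
        raise ModelDomainError(f"dT direction: {exc}") from exc
    N_dP = partner_count(rng_dP.R_int, env)
    N_dT = partner_count(rng_dT.R_int, env)
    cap_dP = growth_cap(pair_dP)
    cap_dT = growth_cap(pair_dT)
    f, f_raw, f_flags = equilibrium_frequency(cap_dP, cap_dT, N_dP, N_dT)
    flags.extend(f_flags)
    if N_dP <= 2 or N_dT <= 2:  # unreachable after equilibrium_frequency, kept for clarity
        flags.append("partner_count_le_2")
    mu_n = 0.5 * (pair_dP.consumer.max_growth + pair_dT.consumer.max_growth)
    r_rel = relative_growth(f, cap_dP, cap_dT, N_dP, N_dT, mu_n)
    return CommunityPrediction(
        range_dP=rng_dP, range_dT=rng_dT, N_dP=N_dP, N_dT=N_dT,
        cap_dP=cap_dP, cap_dT=cap_dT, f_dP=f, f_dP_raw=f_raw, r_rel=r_rel,
        validity_flags=tuple(flags),
    )
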
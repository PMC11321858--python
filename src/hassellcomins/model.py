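"""Two-species resource competition at the individual level and the
discrete-time population maps it induces.

The model: ``N1`` individuals of species 1 and ``N2`` of species 2 compete for
a resource pool ``R``.  An individual of species ``i`` can only ever acquire a
fixed quantum ``u_i`` of resource at a time (its *resource unit*) and needs at
least ``s_i`` full units to reproduce, in which case it leaves ``lam_i``
offspring on average.  Individuals are drawn one at a time with probabilities
proportional to per-individual selection weights ``alpha_i``; each draw hands
the selected individual one unit of its species' size, until the remainder is
smaller than the selected individual's unit, which that individual consumes as
an uncounted *leftover*.  When only the mean ``Rbar`` of the pool is known, the
maximum-entropy assumption makes ``R`` exponential, and the expected
next-generation population sizes come out in closed form as a Hassell–Comins
map

    f_i(N1, N2) = lam_i N_i [1 + a_i (N_i + b_ij N_j)]^(-s_i),

with intraspecific coefficient ``a_i = e^{u_i/Rbar} - 1`` and interspecific
coefficients ``b_ij`` determined by unit sizes and selection weights
(``b12 * b21 = 1``).  The exponent ``s_i`` measures (inversely) the inequality
of resource allocation within species ``i``: ``s_i = 1`` is ideal contest
(Beverton–Holt-like saturation), ``s_i -> infinity`` at fixed ``w_i = u_i s_i``
is ideal scramble (Ricker-like overcompensation).

This module contains, in the order the method runs:

1.  parameter containers and validation;
2.  the closed-form maps (all variants), derived population-level
    coefficients, fixed points and reproduction-curve sweeps;
3.  the exact probability laws of the allocation process (joint, marginal and
    per-individual unit-count distributions, inequality metrics) plus a
    truncated-enumeration oracle for the expected next generation;
4.  the stochastic individual-based simulator and a Monte-Carlo harness;
5.  a verification registry cross-checking 1–4 against each other;
6.  config / table I/O helpers used by the command line in ``__main__``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import integrate, optimize, special, stats

__all__ = [
    "ValidationError",
    # containers
    "SpeciesParams", "CommunityParams", "PopulationState", "DerivedCoefficients",
    "HassellParams", "ConstrainedSpec", "ModelVariant", "VARIANTS",
    # maps
    "derive_coefficients", "hassell_map", "hassell_comins_map",
    "single_species_expectation", "expected_next_generation",
    "constrained_params", "fixed_point", "a_from_fixed_point",
    "reproduction_curve", "CurveResult", "PeakReport",
    # distributions
    "SelectionProbs", "Pmf", "JointPmf", "InequalityReport",
    "selection_probabilities", "conditional_unit_pmf", "total_units_pmf",
    "joint_allocation_pmf_fixed_R", "joint_allocation_pmf",
    "marginal_allocation_pmf", "marginal_unit_pmf", "inequality_metrics",
    "enumeration_expectation", "EnumerationExpectation",
    # simulator
    "AllocationOutcome", "GenerationResult", "SimConfig", "MonteCarloResult",
    "simulate_allocation_sequential", "simulate_allocation_predivided",
    "reproduce", "monte_carlo_next_generation", "empirical_summary",
    "EmpiricalSummary",
    # verification
    "IdentityCheck", "verify_identities", "COVERED_EQUATION_COUNT",
    # io
    "load_config", "write_table",
]

logger = logging.getLogger("hassellcomins")

#: default upper bound on probability mass omitted by pmf truncation
DEFAULT_TAIL_BOUND = 1e-12
#: refuse to materialise truncated joint pmfs larger than this many cells
MAX_JOINT_CELLS = 4_000_000


class ValidationError(ValueError):
    """Raised when model parameters or states violate their invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# 1. Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesParams:
    """Individual-level parameters of one species.

    Parameters
    ----------
    u : float
        Resource-unit size (resource units): the fixed quantum an individual
        acquires per selection.  Larger ``u`` at fixed mean resource means
        lumpier allocation and greater within-species inequality.
    s : int
        Number of full units required to reproduce (``>= 1``).  The actual
        resource requirement is ``w = u * s`` (derived, never stored).
    lam : float
        Expected offspring per reproducing individual.
    alpha : float
        Per-individual selection weight; only ratios between species matter.
    """

    u: float
    s: int
    lam: float
    alpha: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        _require(self.u > 0, f"u must be > 0, got {self.u}")
        _require(float(self.s) == int(self.s) and self.s >= 1,
                 f"s must be an integer >= 1, got {self.s}")
        _require(self.lam > 0, f"lam must be > 0, got {self.lam}")
        _require(self.alpha > 0, f"alpha must be > 0, got {self.alpha}")
        object.__setattr__(self, "s", int(self.s))

    @property
    def w(self) -> float:
        """Actual resource amount required for reproduction, ``u * s``."""
        return self.u * self.s


@dataclass(frozen=True)
class CommunityParams:
    """Two competing species plus the expected total resource ``Rbar``."""

    sp1: SpeciesParams
    sp2: SpeciesParams
    Rbar: float

    def __post_init__(self) -> None:
        _require(self.Rbar > 0, f"Rbar must be > 0, got {self.Rbar}")

    def species(self, i: int) -> SpeciesParams:
        _require(i in (1, 2), f"species index must be 1 or 2, got {i}")
        return self.sp1 if i == 1 else self.sp2


@dataclass(frozen=True)
class PopulationState:
    """Current population sizes.  Real-valued: the maps are smooth functions;
    integrality is enforced only by the simulator."""

    N1: float
    N2: float

    def __post_init__(self) -> None:
        _require(self.N1 >= 0 and self.N2 >= 0,
                 f"population sizes must be >= 0, got ({self.N1}, {self.N2})")

    def as_integers(self) -> tuple[int, int]:
        _require(float(self.N1).is_integer() and float(self.N2).is_integer(),
                 f"integer state required, got ({self.N1}, {self.N2})")
        return int(self.N1), int(self.N2)


@dataclass(frozen=True)
class DerivedCoefficients:
    """Population-level coefficients induced by individual-level parameters.

    ``a_i = e^{u_i/Rbar} - 1`` is the intraspecific coefficient, the
    reciprocal of ``Mbar_i_max``, the expected maximum number of species-i
    units extractable from the pool.  ``b12`` (effect of a species-2
    individual on species 1, relative to a conspecific) factorises as
    ``(Mbar1max / Mbar2max) * c12`` where ``c12`` is the ratio of per-draw
    unit-acquisition success probabilities.  Always ``b12 * b21 = 1``.
    """

    a1: float
    a2: float
    b12: float
    b21: float
    c12: float
    Mbar1max: float
    Mbar2max: float


@dataclass(frozen=True)
class HassellParams:
    """Parameters of the single-species map ``X' = lam X / (1 + a X)^theta``."""

    lam: float
    a: float
    theta: float

    def __post_init__(self) -> None:
        _require(self.lam > 0 and self.a > 0 and self.theta > 0,
                 "lam, a, theta must all be > 0")


@dataclass(frozen=True)
class ConstrainedSpec:
    """Inequality-sweep constraint: vary ``s1`` (hence ``u1``) holding the
    expected maximum number of reproducers ``k1`` and the interspecific
    coefficient ``b12`` fixed, i.e. ``s1 (e^{u1/Rbar} - 1) = 1 / k1``."""

    s1: int
    k1: float
    b12: float

    def __post_init__(self) -> None:
        _require(int(self.s1) == self.s1 and self.s1 >= 1, "s1 must be integer >= 1")
        _require(self.k1 > 0, "k1 must be > 0")
        _require(self.b12 > 0, "b12 must be > 0")


ModelVariant = Literal[
    "general", "equal_unit", "small_unit", "constrained",
    "scramble_contest", "double_scramble",
    "hassell_single", "hassell_comins_phenomenological",
]

VARIANTS: tuple[str, ...] = (
    "general", "equal_unit", "small_unit", "constrained",
    "scramble_contest", "double_scramble",
    "hassell_single", "hassell_comins_phenomenological",
)


# ---------------------------------------------------------------------------
# 2. Closed-form maps and derived coefficients
# ---------------------------------------------------------------------------

def _a_coeff(u: float, Rbar: float) -> float:
    # e^{u/Rbar} - 1, stable for u/Rbar down to ~1e-300
    return math.expm1(u / Rbar)


def _one_minus_exp_neg(u: float, Rbar: float) -> float:
    # 1 - e^{-u/Rbar}, stable small-argument form
    return -math.expm1(-u / Rbar)


def derive_coefficients(params: CommunityParams) -> DerivedCoefficients:
    """Population-level coefficients from individual-level parameters.

    ``b12 = [(1 - e^{-u2/Rbar}) / (1 - e^{-u1/Rbar})] * (alpha2/alpha1)`` and
    symmetrically for ``b21``; ``c12 = e^{-(u2-u1)/Rbar} * alpha2/alpha1``.
    All exponentials use small-argument-stable primitives so the coefficients
    stay accurate for ``u/Rbar`` down to 1e-12 and far below.
    """
    sp1, sp2, R = params.sp1, params.sp2, params.Rbar
    a1 = _a_coeff(sp1.u, R)
    a2 = _a_coeff(sp2.u, R)
    g1 = _one_minus_exp_neg(sp1.u, R)
    g2 = _one_minus_exp_neg(sp2.u, R)
    ratio_alpha = sp2.alpha / sp1.alpha
    b12 = (g2 / g1) * ratio_alpha
    b21 = (g1 / g2) / ratio_alpha
    c12 = math.exp(-(sp2.u - sp1.u) / R) * ratio_alpha
    return DerivedCoefficients(
        a1=a1, a2=a2, b12=b12, b21=b21, c12=c12,
        Mbar1max=1.0 / a1, Mbar2max=1.0 / a2,
    )


def _hassell_factor(density: float, a: float, theta: float) -> float:
    # (1 + a*density)^(-theta) computed in log space: stable for large theta
    return math.exp(-theta * math.log1p(a * density))


def hassell_map(N: float, hp: HassellParams) -> float:
    """Single-species map ``lam N / (1 + a N)^theta``."""
    _require(N >= 0, f"population size must be >= 0, got {N}")
    return hp.lam * N * _hassell_factor(N, hp.a, hp.theta)


def hassell_comins_map(state: PopulationState, hp1: HassellParams,
                       hp2: HassellParams, b12: float, b21: float,
                       ) -> PopulationState:
    """Two-species phenomenological map: each species' density term is the
    linear combination ``N_i + b_ij N_j``.  With ``b12 = b21 = 0`` the two
    components decouple into independent single-species maps."""
    _require(b12 >= 0 and b21 >= 0, "b12, b21 must be >= 0")
    X, Y = state.N1, state.N2
    return PopulationState(
        N1=hp1.lam * X * _hassell_factor(X + b12 * Y, hp1.a, hp1.theta),
        N2=hp2.lam * Y * _hassell_factor(Y + b21 * X, hp2.a, hp2.theta),
    )


def single_species_expectation(N: float, sp: SpeciesParams, Rbar: float) -> float:
    """Expected next generation of one species alone:
    ``lam N [1 + (e^{u/Rbar} - 1) N]^{-s}``.

    For ``s = 1`` this increases monotonically to the asymptote
    ``lam / (e^{u/Rbar} - 1)`` (ideal contest); larger ``s`` gives an interior
    peak (overcompensation).
    """
    _require(N >= 0, f"population size must be >= 0, got {N}")
    _require(Rbar > 0, "Rbar must be > 0")
    return sp.lam * N * _hassell_factor(N, _a_coeff(sp.u, Rbar), sp.s)


def expected_next_generation(params: CommunityParams, state: PopulationState,
                             variant: ModelVariant = "general",
                             ) -> PopulationState:
    """Expected next-generation population sizes under the selected closed
    form.

    Variants
    --------
    general
        ``f_i = lam_i N_i [1 + a_i (N_i + b_ij N_j)]^{-s_i}`` with the derived
        coefficients.  This is the reference form; all others are special
        cases or limits.
    equal_unit
        Requires ``u1 == u2``; the interspecific coefficient reduces exactly
        to the weight ratio ``alpha_j / alpha_i``.
    small_unit
        First-order Taylor form in ``u_i/Rbar``: density coefficient
        ``u_i/Rbar`` and interspecific weight ``(u_j/u_i)(alpha_j/alpha_i)``.
    constrained
        The general map rewritten through ``k_i = 1/(s_i a_i)``, the expected
        maximum number of reproducers: ``f_i = lam_i N_i
        [1 + (N_i + b_ij N_j)/(s_i k_i)]^{-s_i}`` (numerically identical to
        ``general``).
    scramble_contest
        Species 1 at the zero-inequality limit ``s1 -> inf`` holding
        ``w1 = u1 s1`` fixed (Ricker form), species 2 unchanged; the limit's
        ``b12 = (1 - e^{-u2/Rbar}) Rbar alpha2 / (u1 alpha1)``.
    double_scramble
        Both species at that limit; ``b12 = u2 alpha2 / (u1 alpha1)``.
    hassell_single
        Each species mapped alone (no interspecific term): two independent
        single-species expectations.
    hassell_comins_phenomenological
        The general map routed through :func:`hassell_comins_map` with the
        derived coefficients as phenomenological parameters.
    """
    _require(variant in VARIANTS, f"unknown variant {variant!r}")
    sp1, sp2, R = params.sp1, params.sp2, params.Rbar
    N1, N2 = state.N1, state.N2

    if variant in ("general", "constrained"):
        co = derive_coefficients(params)
        f1 = sp1.lam * N1 * _hassell_factor(N1 + co.b12 * N2, co.a1, sp1.s)
        f2 = sp2.lam * N2 * _hassell_factor(N2 + co.b21 * N1, co.a2, sp2.s)
        return PopulationState(f1, f2)

    if variant == "equal_unit":
        _require(sp1.u == sp2.u,
                 "equal_unit variant requires u1 == u2 "
                 f"(got u1={sp1.u}, u2={sp2.u})")
        a = _a_coeff(sp1.u, R)
        f1 = sp1.lam * N1 * _hassell_factor(N1 + (sp2.alpha / sp1.alpha) * N2, a, sp1.s)
        f2 = sp2.lam * N2 * _hassell_factor(N2 + (sp1.alpha / sp2.alpha) * N1, a, sp2.s)
        return PopulationState(f1, f2)

    if variant == "small_unit":
        f1 = sp1.lam * N1 * _hassell_factor(
            N1 + (sp2.u / sp1.u) * (sp2.alpha / sp1.alpha) * N2, sp1.u / R, sp1.s)
        f2 = sp2.lam * N2 * _hassell_factor(
            N2 + (sp1.u / sp2.u) * (sp1.alpha / sp2.alpha) * N1, sp2.u / R, sp2.s)
        return PopulationState(f1, f2)

    if variant == "scramble_contest":
        w1 = sp1.w  # validated > 0 by SpeciesParams
        b12 = _one_minus_exp_neg(sp2.u, R) * R * sp2.alpha / (sp1.u * sp1.alpha)
        b21 = 1.0 / b12
        f1 = sp1.lam * N1 * math.exp(-(w1 / R) * (N1 + b12 * N2))
        f2 = sp2.lam * N2 * _hassell_factor(N2 + b21 * N1, _a_coeff(sp2.u, R), sp2.s)
        return PopulationState(f1, f2)

    if variant == "double_scramble":
        w1, w2 = sp1.w, sp2.w
        b12 = (sp2.u * sp2.alpha) / (sp1.u * sp1.alpha)
        b21 = 1.0 / b12
        f1 = sp1.lam * N1 * math.exp(-(w1 / R) * (N1 + b12 * N2))
        f2 = sp2.lam * N2 * math.exp(-(w2 / R) * (N2 + b21 * N1))
        return PopulationState(f1, f2)

    if variant == "hassell_single":
        return PopulationState(
            single_species_expectation(N1, sp1, R),
            single_species_expectation(N2, sp2, R),
        )

    # hassell_comins_phenomenological
    co = derive_coefficients(params)
    hp1 = HassellParams(lam=sp1.lam, a=co.a1, theta=sp1.s)
    hp2 = HassellParams(lam=sp2.lam, a=co.a2, theta=sp2.s)
    return hassell_comins_map(state, hp1, hp2, co.b12, co.b21)


def constrained_params(spec: ConstrainedSpec, Rbar: float, sp2: SpeciesParams,
                       alpha1: float = 1.0, lam1: float = 2.0,
                       ) -> CommunityParams:
    """Community parameters realising the inequality-sweep constraint.

    Inverts ``s1 (e^{u1/Rbar} - 1) = 1/k1`` for ``u1`` and chooses ``alpha2``
    so the derived interspecific coefficient equals ``spec.b12``.  The general
    map then takes the constrained form
    ``f1 = lam1 N1 [1 + (N1 + b12 N2)/(s1 k1)]^{-s1}``.
    """
    _require(Rbar > 0, "Rbar must be > 0")
    _require(alpha1 > 0, "alpha1 must be > 0")
    u1 = Rbar * math.log1p(1.0 / (spec.s1 * spec.k1))
    _require(u1 > 0, "infeasible constraint: induced u1 is not positive")
    g1 = _one_minus_exp_neg(u1, Rbar)
    g2 = _one_minus_exp_neg(sp2.u, Rbar)
    alpha2 = spec.b12 * alpha1 * g1 / g2
    sp1 = SpeciesParams(u=u1, s=spec.s1, lam=lam1, alpha=alpha1, name="constrained")
    return CommunityParams(sp1=sp1, sp2=replace(sp2, alpha=alpha2), Rbar=Rbar)


def fixed_point(hp: HassellParams) -> float:
    """Positive fixed point ``X* = (lam^{1/theta} - 1)/a`` of the
    single-species map; exists only for ``lam > 1``."""
    _require(hp.lam > 1, f"no positive fixed point for lam <= 1 (lam={hp.lam})")
    return math.expm1(math.log(hp.lam) / hp.theta) / hp.a


def a_from_fixed_point(lam: float, theta: float, Xstar: float) -> float:
    """Density coefficient ``a`` placing the positive fixed point at
    ``Xstar``: inverse of :func:`fixed_point` in ``a``."""
    _require(lam > 1, f"no positive fixed point for lam <= 1 (lam={lam})")
    _require(theta > 0 and Xstar > 0, "theta and Xstar must be > 0")
    return math.expm1(math.log(lam) / theta) / Xstar


@dataclass(frozen=True)
class PeakReport:
    """Location and height of an interior maximum of a reproduction curve."""
    N1_at_max: float
    f1_max: float


@dataclass(frozen=True)
class CurveResult:
    table: pd.DataFrame
    peak: PeakReport | None


def reproduction_curve(params: CommunityParams, variant: ModelVariant,
                       sweep: Sequence[float], N2: float = 0.0,
                       normalize: bool = False, refine_peak: bool = False,
                       ) -> CurveResult:
    """Species-1 reproduction curve ``f1(N1, N2)`` over a grid of ``N1``.

    With ``normalize`` the column holds ``f1 / lam1`` (reproduction
    probability times ``N1``).  With ``refine_peak`` an interior grid argmax
    is refined by bounded scalar optimisation (relative tolerance 1e-10, ties
    broken toward smaller ``N1``); monotone curves (grid argmax on the
    boundary) report no peak.
    """
    sweep = np.asarray(list(sweep), dtype=float)
    _require(sweep.size > 0, "sweep must be non-empty")
    _require(np.all(sweep >= 0), "sweep values must be >= 0")
    _require(N2 >= 0, "N2 must be >= 0")

    def f1(n1: float) -> float:
        return expected_next_generation(
            params, PopulationState(n1, N2), variant).N1

    values = np.array([f1(n) for n in sweep])
    col = "f1_over_lam1" if normalize else "f1"
    table = pd.DataFrame({"N1": sweep,
                          col: values / params.sp1.lam if normalize else values})

    peak: PeakReport | None = None
    if refine_peak:
        i = int(np.argmax(values))  # first occurrence -> smaller N1 on ties
        if 0 < i < sweep.size - 1:
            lo, hi = sweep[i - 1], sweep[i + 1]
            res = optimize.minimize_scalar(
                lambda n: -f1(n), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10 * max(1.0, hi)})
            peak = PeakReport(N1_at_max=float(res.x), f1_max=float(-res.fun))
    return CurveResult(table=table, peak=peak)


# ---------------------------------------------------------------------------
# 3. Exact allocation laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionProbs:
    """Per-draw selection probabilities.  ``rho_i`` is the probability a
    *particular* species-i individual is drawn, ``q_i = rho_i N_i`` the
    probability the draw lands in species i at all."""

    rho1: float
    rho2: float
    q1: float
    q2: float


def selection_probabilities(params: CommunityParams, state: PopulationState,
                            ) -> SelectionProbs:
    """``rho1 = alpha1 / (alpha1 N1 + alpha2 N2)`` and the species-level
    shares ``q_i``; requires at least one individual present."""
    N1, N2 = state.as_integers()
    _require(N1 + N2 >= 1, "no individual to select (N1 = N2 = 0)")
    a1, a2 = params.sp1.alpha, params.sp2.alpha
    denom = a1 * N1 + a2 * N2
    return SelectionProbs(rho1=a1 / denom, rho2=a2 / denom,
                          q1=a1 * N1 / denom, q2=a2 * N2 / denom)


@dataclass(frozen=True)
class Pmf:
    """Probability mass function on contiguous support ``0..K``.

    ``tail_bound`` bounds the mass omitted by truncation (0 for exact finite
    support).  ``mean`` is the closed-form mean where one is known.
    """

    p: np.ndarray
    tail_bound: float
    mean: float | None = None

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.p.size)

    def total_mass(self) -> float:
        return float(self.p.sum())

    def numeric_mean(self) -> float:
        return float(self.support @ self.p)

    def tail_sum(self, k: int) -> float:
        """Mass at or above ``k`` (within the truncated support)."""
        return float(self.p[k:].sum())


@dataclass(frozen=True)
class JointPmf:
    """Joint pmf over unit counts ``(M1, M2)`` on ``0..K1 x 0..K2``."""

    p: np.ndarray  # shape (K1+1, K2+1)
    tail_bound: float

    def total_mass(self) -> float:
        return float(self.p.sum())

    def marginal(self, species: int) -> np.ndarray:
        _require(species in (1, 2), "species must be 1 or 2")
        return self.p.sum(axis=2 - species)


def conditional_unit_pmf(M: int, rho1: float) -> Pmf:
    """Binomial law of one individual's unit count given ``M`` units allocated
    in total: ``p(m; M) = C(M, m) rho1^m (1-rho1)^{M-m}`` on ``0..M``."""
    _require(M >= 0 and int(M) == M, f"M must be a non-negative integer, got {M}")
    _require(0.0 <= rho1 <= 1.0, f"rho1 must be a probability, got {rho1}")
    m = np.arange(int(M) + 1)
    return Pmf(p=stats.binom.pmf(m, int(M), rho1), tail_bound=0.0,
               mean=M * rho1)


def _geometric_truncation(ratio: float, tail: float) -> int:
    """Smallest K with ratio^(K+1) <= tail for a geometric pmf (1-r) r^k."""
    if ratio <= 0.0:
        return 0
    _require(ratio < 1.0, f"geometric ratio must be < 1, got {ratio}")
    return max(0, math.ceil(math.log(tail) / math.log(ratio)) - 1)


def _geometric_pmf(ratio: float, tail: float, mean: float | None) -> Pmf:
    K = _geometric_truncation(ratio, tail)
    k = np.arange(K + 1)
    if ratio == 0.0:
        p = np.array([1.0])
    else:
        p = (1.0 - ratio) * np.exp(k * math.log(ratio))
    return Pmf(p=p, tail_bound=tail, mean=mean)


def total_units_pmf(u: float, Rbar: float,
                    truncation: float = DEFAULT_TAIL_BOUND) -> Pmf:
    """Law of the total number of units ``M`` extractable from an exponential
    pool: geometric, ``P(M) = (1 - e^{-u/Rbar}) e^{-M u/Rbar}``, with mean
    ``Mbar_max = (e^{u/Rbar} - 1)^{-1}``."""
    _require(u > 0 and Rbar > 0, "u and Rbar must be > 0")
    ratio = math.exp(-u / Rbar)
    return _geometric_pmf(ratio, truncation, mean=1.0 / _a_coeff(u, Rbar))


def joint_allocation_pmf_fixed_R(params: CommunityParams,
                                 state: PopulationState, R: float) -> JointPmf:
    """Exact joint law of ``(M1, M2)`` for a known resource amount ``R``.

    Mass sits only on the feasibility band
    ``u1 M1 + u2 M2 <= R < u1 M1 + u2 M2 + max(u1, u2)``; each admissible pair
    receives ``C(M1+M2, M1) q1^M1 q2^M2`` times the share of termination
    routes (the leftover draw landing on species 1 and/or 2) whose half-open
    interval contains ``R``.  Finite support; mass is exactly 1.
    """
    _require(R > 0, f"R must be > 0, got {R}")
    sel = selection_probabilities(params, state)
    u1, u2 = params.sp1.u, params.sp2.u
    q1, q2 = sel.q1, sel.q2

    K1 = int(R // u1)
    K2 = int(R // u2)
    p = np.zeros((K1 + 1, K2 + 1))
    for M1 in range(K1 + 1):
        rem = R - u1 * M1
        if rem < 0:
            continue
        for M2 in range(int(rem // u2) + 1):
            base = rem - u2 * M2  # R - u1 M1 - u2 M2 >= 0
            weight = 0.0
            if base < u1:   # termination route (i): species-1 leftover
                weight += q1
            if base < u2:   # termination route (ii): species-2 leftover
                weight += q2
            if weight == 0.0 or (M1 and q1 == 0.0) or (M2 and q2 == 0.0):
                continue
            logc = (special.gammaln(M1 + M2 + 1) - special.gammaln(M1 + 1)
                    - special.gammaln(M2 + 1))
            lq1 = M1 * math.log(q1) if M1 else 0.0
            lq2 = M2 * math.log(q2) if M2 else 0.0
            p[M1, M2] = weight * math.exp(logc + lq1 + lq2)
    return JointPmf(p=p, tail_bound=0.0)


def _xy(params: CommunityParams, state: PopulationState) -> tuple[float, float]:
    """Per-draw 'successful unit acquisition' weights
    ``x = e^{-u1/Rbar} q1`` and ``y = e^{-u2/Rbar} q2`` of the exponential-R
    joint law."""
    sel = selection_probabilities(params, state)
    x = math.exp(-params.sp1.u / params.Rbar) * sel.q1
    y = math.exp(-params.sp2.u / params.Rbar) * sel.q2
    return x, y


def joint_allocation_pmf(params: CommunityParams, state: PopulationState,
                         truncation: float = DEFAULT_TAIL_BOUND) -> JointPmf:
    """Joint law of ``(M1, M2)`` with exponentially distributed ``R``:

    ``P(M1, M2) = C(M1+M2, M1) x^M1 y^M2 (1 - x - y)`` with
    ``x = e^{-u1/Rbar} q1``, ``y = e^{-u2/Rbar} q2``.  Truncated adaptively so
    that the omitted mass (bounded through the two geometric marginals) is at
    most ``truncation``.
    """
    _require(0 < truncation < 1, "truncation must be in (0, 1)")
    x, y = _xy(params, state)
    g1 = x / (1.0 - y)   # marginal geometric ratio of M1
    g2 = y / (1.0 - x)
    K1 = _geometric_truncation(g1, truncation / 2.0)
    K2 = _geometric_truncation(g2, truncation / 2.0)
    if (K1 + 1) * (K2 + 1) > MAX_JOINT_CELLS:
        raise ValidationError(
            f"truncation {truncation} needs a {K1 + 1} x {K2 + 1} grid, over "
            f"the {MAX_JOINT_CELLS}-cell cap; achievable tail at the cap is "
            f"larger")
    M1 = np.arange(K1 + 1)[:, None]
    M2 = np.arange(K2 + 1)[None, :]
    logc = (special.gammaln(M1 + M2 + 1) - special.gammaln(M1 + 1)
            - special.gammaln(M2 + 1))
    lx = (M1 * math.log(x) if x > 0
          else np.where(M1 == 0, 0.0, -np.inf))
    ly = (M2 * math.log(y) if y > 0
          else np.where(M2 == 0, 0.0, -np.inf))
    p = np.exp(logc + lx + ly) * (1.0 - x - y)
    return JointPmf(p=p, tail_bound=truncation)


def marginal_allocation_pmf(params: CommunityParams, state: PopulationState,
                            species: int = 1,
                            truncation: float = DEFAULT_TAIL_BOUND) -> Pmf:
    """Marginal law of ``M_i`` under exponential ``R``: geometric with ratio
    ``x/(1-y)`` (species 1; symmetrically for 2), mean
    ``N_i / ((e^{u_i/Rbar} - 1)(N_i + b_ij N_j))``.

    The mean is the self-consistent form: it equals the exact mean
    ``x/(1-x-y)`` of the geometric law and reduces to ``Mbar_max`` at
    ``N_j = 0``.  An alternative display with ``(1 - e^{-u_i/Rbar})`` in place
    of ``(e^{u_i/Rbar} - 1)`` is larger by ``e^{u_i/Rbar}`` and inconsistent
    with the closed-form map; see :func:`verify_identities`.
    """
    _require(species in (1, 2), "species must be 1 or 2")
    x, y = _xy(params, state)
    if species == 2:
        x, y = y, x
    ratio = x / (1.0 - y)
    mean = x / (1.0 - x - y)
    return _geometric_pmf(ratio, truncation, mean=mean)


def marginal_unit_pmf(params: CommunityParams, state: PopulationState,
                      species: int = 1,
                      truncation: float = DEFAULT_TAIL_BOUND) -> Pmf:
    """Law of one individual's unit count ``m_i`` under exponential ``R``,
    computed by compounding the binomial conditional (success probability
    ``1/N_i``) over the marginal law of ``M_i``.

    The result is geometric with mean
    ``mbar_i = ((e^{u_i/Rbar} - 1)(N_i + b_ij N_j))^{-1}``; its tail from
    ``s_i`` is the closed-form reproduction probability
    ``[1 + (e^{u_i/Rbar} - 1)(N_i + b_ij N_j)]^{-s_i}``.
    """
    N1, N2 = state.as_integers()
    Ni = N1 if species == 1 else N2
    _require(Ni >= 1, f"species {species} has no individuals")
    M_law = marginal_allocation_pmf(params, state, species, truncation)
    K = M_law.p.size - 1
    m = np.arange(K + 1)
    # B[m, M] = Binom(m; M, 1/Ni); compound: p(m) = sum_M B[m, M] P(M)
    B = stats.binom.pmf(m[:, None], m[None, :], 1.0 / Ni)
    p = B @ M_law.p
    mean = M_law.mean / Ni if M_law.mean is not None else None
    return Pmf(p=p, tail_bound=truncation, mean=mean)


@dataclass(frozen=True)
class InequalityReport:
    """Within-species-1 allocation inequality.

    ``eta1`` replaces ``M1`` in the fixed-``M1`` squared coefficient of
    variation ``(CV1)^2 = (N1/M1)(1 - 1/N1)`` by the mean ``Mbar1`` (the
    harmonic-average convention: the inverse of the averaged inverse), giving
    ``eta1 = (e^{u1/Rbar} - 1)(N1 + b12 N2)(1 - 1/N1)``.
    """

    cv_squared_at_mean: float
    eta1: float
    mbar1: float
    Mbar1: float
    eta1_constrained: float | None = None


def inequality_metrics(params: CommunityParams, state: PopulationState,
                       constrained: ConstrainedSpec | None = None,
                       ) -> InequalityReport:
    """Inequality index of species 1 at the given state; with a
    :class:`ConstrainedSpec` attached the constrained form
    ``(N1 + b12 N2)(1 - 1/N1)/(s1 k1)`` — inversely proportional to ``s1`` —
    is reported as well."""
    N1, N2 = state.N1, state.N2
    _require(N1 >= 1, "inequality metrics require N1 >= 1")
    co = derive_coefficients(params)
    dens = N1 + co.b12 * N2
    Mbar1 = N1 / (co.a1 * dens)
    eta1 = co.a1 * dens * (1.0 - 1.0 / N1)
    cv2 = (N1 / Mbar1) * (1.0 - 1.0 / N1)
    eta_c = None
    if constrained is not None:
        eta_c = (N1 + constrained.b12 * N2) * (1.0 - 1.0 / N1) / (
            constrained.s1 * constrained.k1)
    return InequalityReport(cv_squared_at_mean=cv2, eta1=eta1,
                            mbar1=Mbar1 / N1, Mbar1=Mbar1,
                            eta1_constrained=eta_c)


@dataclass(frozen=True)
class EnumerationExpectation:
    """Brute-force expected next generation plus truncation error bounds."""

    f1: float
    f2: float
    error_bound1: float
    error_bound2: float

    @property
    def state(self) -> PopulationState:
        return PopulationState(self.f1, self.f2)


def enumeration_expectation(params: CommunityParams, state: PopulationState,
                            truncation: float = DEFAULT_TAIL_BOUND,
                            ) -> EnumerationExpectation:
    """Expected next generation by explicit truncated summation — the
    independent oracle for the closed-form maps.

    For each species the joint law of ``(M1, M2)`` (evaluated entry by entry,
    never through the closed-form map) is row-summed to the ``M_i`` law, and
    the reproduction probability is accumulated as the binomial survival
    ``P(m_i >= s_i | M_i)`` weighted by that law.  The omitted tail mass is
    folded into an error bound ``lam_i N_i * truncation`` on each component.
    """
    N1, N2 = state.as_integers()
    _require(N1 + N2 >= 1, "empty community")

    def one_species(i: int) -> tuple[float, float]:
        sp = params.species(i)
        Ni = N1 if i == 1 else N2
        if Ni == 0:
            return 0.0, 0.0
        joint = joint_allocation_pmf(params, state, truncation)
        law = joint.marginal(i)          # truncated row sums, not closed form
        M = np.arange(law.size)
        surv = stats.binom.sf(sp.s - 1, M, 1.0 / Ni)
        f = sp.lam * Ni * float(surv @ law)
        return f, sp.lam * Ni * truncation

    f1, e1 = one_species(1)
    f2, e2 = one_species(2)
    return EnumerationExpectation(f1=f1, f2=f2, error_bound1=e1, error_bound2=e2)


# ---------------------------------------------------------------------------
# 4. Stochastic individual-based simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AllocationOutcome:
    """One realisation of the allocation process.

    ``units1``/``units2`` hold full-unit counts per individual;
    ``leftover_recipient`` is ``(species, index)`` for the individual that
    consumed the terminal sub-unit residue (``None`` on exact exhaustion).
    The leftover never counts toward reproduction.
    """

    units1: np.ndarray
    units2: np.ndarray
    M1: int
    M2: int
    leftover_amount: float
    leftover_recipient: tuple[int, int] | None
    R_used: float


@dataclass(frozen=True)
class GenerationResult:
    reproducers1: int
    reproducers2: int
    next1: float
    next2: float
    mode: Literal["expected", "sampled"]


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo harness configuration.  ``resource_mode='exponential'``
    draws ``R`` afresh each replicate from the exponential law with mean
    ``Rbar``; ``'fixed'`` uses the supplied ``R`` throughout."""

    reps: int
    seed: int
    resource_mode: Literal["exponential", "fixed"] = "exponential"
    R: float | None = None
    offspring_mode: Literal["expected", "sampled"] = "expected"

    def __post_init__(self) -> None:
        _require(self.reps >= 1, "reps must be >= 1")
        _require(self.resource_mode in ("exponential", "fixed"),
                 f"unknown resource_mode {self.resource_mode!r}")
        _require(self.offspring_mode in ("expected", "sampled"),
                 f"unknown offspring_mode {self.offspring_mode!r}")
        if self.resource_mode == "fixed":
            _require(self.R is not None and self.R > 0,
                     "fixed resource_mode requires R > 0")


def simulate_allocation_sequential(params: CommunityParams,
                                   state: PopulationState, R: float,
                                   rng: np.random.Generator,
                                   ) -> AllocationOutcome:
    """One realisation of sequential allocation: individuals are drawn with
    per-draw probabilities proportional to their species' ``alpha``; a drawn
    individual takes a full unit of its species' size while the remainder
    allows (remainder exactly equal to the unit counts as full), otherwise it
    consumes the whole remainder as leftover and the process ends.

    Implementation note: the species sequence of the draws is independent of
    the running remainder, so a block of at most ``floor(R/u_min) + 1`` draws
    is generated up front, the termination draw located on the cumulative
    resource consumption, and the counted units assigned to individuals
    multinomially (uniform within species) — distributionally identical to
    the one-draw-at-a-time loop.
    """
    N1, N2 = state.as_integers()
    _require(N1 + N2 >= 1, "no individual to select (N1 = N2 = 0)")
    _require(R > 0, f"R must be > 0, got {R}")
    sel = selection_probabilities(params, state)
    u1, u2 = params.sp1.u, params.sp2.u
    u_min = min([u for u, n in ((u1, N1), (u2, N2)) if n > 0])

    # floor(R/u_min) full units plus one terminal draw always suffice; +2
    # absorbs floating rounding of the cumulative sum
    n_draws = int(R // u_min) + 2
    if N1 == 0:
        is_sp2 = np.ones(n_draws, dtype=bool)
    elif N2 == 0:
        is_sp2 = np.zeros(n_draws, dtype=bool)
    else:
        is_sp2 = rng.random(n_draws) >= sel.q1
    u_seq = np.where(is_sp2, u2, u1)
    consumed = np.cumsum(u_seq)
    # first draw whose full unit would overshoot R
    stop = int(np.searchsorted(consumed, R, side="right"))
    if stop >= n_draws:  # unreachable by construction; defensive
        raise RuntimeError("allocation draw block exhausted")
    remaining = R - (consumed[stop - 1] if stop > 0 else 0.0)

    M2 = int(np.count_nonzero(is_sp2[:stop]))
    M1 = stop - M2
    units1 = (rng.multinomial(M1, np.full(N1, 1.0 / N1)) if N1 > 0
              else np.zeros(0, dtype=np.int64))
    units2 = (rng.multinomial(M2, np.full(N2, 1.0 / N2)) if N2 > 0
              else np.zeros(0, dtype=np.int64))

    if remaining > 0.0:
        rec_species = 2 if is_sp2[stop] else 1
        rec_index = int(rng.integers(N2 if rec_species == 2 else N1))
        recipient: tuple[int, int] | None = (rec_species, rec_index)
        leftover = float(remaining)
    else:  # exact exhaustion: no leftover recipient
        recipient, leftover = None, 0.0
    return AllocationOutcome(units1=units1, units2=units2, M1=M1, M2=M2,
                             leftover_amount=leftover,
                             leftover_recipient=recipient, R_used=float(R))


def simulate_allocation_predivided(params: CommunityParams,
                                   state: PopulationState, M: int,
                                   rng: np.random.Generator,
                                   ) -> AllocationOutcome:
    """Equal-unit scenario: ``M`` pre-divided units independently assigned to
    individuals with probabilities ``rho1``/``rho2``.  Requires
    ``u1 == u2``; there is no leftover concept."""
    _require(params.sp1.u == params.sp2.u,
             "pre-divided allocation requires u1 == u2")
    _require(M >= 0 and int(M) == M, f"M must be a non-negative integer, got {M}")
    N1, N2 = state.as_integers()
    sel = selection_probabilities(params, state)
    probs = np.concatenate([np.full(N1, sel.rho1), np.full(N2, sel.rho2)])
    counts = rng.multinomial(int(M), probs) if M > 0 else np.zeros(
        N1 + N2, dtype=np.int64)
    units1, units2 = counts[:N1], counts[N1:]
    return AllocationOutcome(units1=units1, units2=units2,
                             M1=int(units1.sum()), M2=int(units2.sum()),
                             leftover_amount=0.0, leftover_recipient=None,
                             R_used=float(M) * params.sp1.u)


def reproduce(outcome: AllocationOutcome, params: CommunityParams,
              mode: Literal["expected", "sampled"] = "expected",
              rng: np.random.Generator | None = None) -> GenerationResult:
    """Threshold reproduction: an individual reproduces iff its full-unit
    count reaches its species' ``s`` (the leftover never counts).  Expected
    mode returns ``lam_i * reproducers_i``; sampled mode draws per-reproducer
    offspring from a Poisson law with mean ``lam_i`` (an extension: only the
    mean is part of the model)."""
    r1 = int(np.count_nonzero(outcome.units1 >= params.sp1.s))
    r2 = int(np.count_nonzero(outcome.units2 >= params.sp2.s))
    if mode == "expected":
        n1, n2 = params.sp1.lam * r1, params.sp2.lam * r2
    elif mode == "sampled":
        _require(rng is not None, "sampled mode requires an rng")
        n1 = float(rng.poisson(params.sp1.lam, r1).sum()) if r1 else 0.0
        n2 = float(rng.poisson(params.sp2.lam, r2).sum()) if r2 else 0.0
    else:
        raise ValidationError(f"unknown offspring mode {mode!r}")
    return GenerationResult(reproducers1=r1, reproducers2=r2,
                            next1=n1, next2=n2, mode=mode)


@dataclass(frozen=True)
class MonteCarloResult:
    mean1: float
    mean2: float
    se1: float
    se2: float
    frac_repro1: float
    frac_repro2: float
    closed1: float
    closed2: float
    z1: float
    z2: float
    reps: int
    next1: np.ndarray = field(repr=False)
    next2: np.ndarray = field(repr=False)


def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    # deterministic substream per replicate: reps are order-independent
    return np.random.default_rng([seed, r])


def monte_carlo_next_generation(params: CommunityParams,
                                state: PopulationState, config: SimConfig,
                                ) -> MonteCarloResult:
    """Monte-Carlo estimate of the next-generation population sizes.

    Each replicate draws its own resource pool (exponential with mean
    ``Rbar`` unless fixed), runs the sequential allocation, applies threshold
    reproduction, and uses a substream derived from ``(seed, replicate)`` so
    results are reproducible and order-independent.  Reports means, standard
    errors, reproducer fractions and z-scores against the closed-form map.
    """
    N1, N2 = state.as_integers()
    next1 = np.empty(config.reps)
    next2 = np.empty(config.reps)
    repro1 = np.empty(config.reps)
    repro2 = np.empty(config.reps)
    for r in range(config.reps):
        rng = _replicate_rng(config.seed, r)
        R = (config.R if config.resource_mode == "fixed"
             else float(rng.exponential(params.Rbar)))
        out = simulate_allocation_sequential(params, state, R, rng)
        gen = reproduce(out, params, config.offspring_mode, rng)
        next1[r], next2[r] = gen.next1, gen.next2
        repro1[r], repro2[r] = gen.reproducers1, gen.reproducers2

    closed = expected_next_generation(params, state, "general")
    mean1, mean2 = float(next1.mean()), float(next2.mean())
    if config.reps > 1:
        se1 = float(next1.std(ddof=1) / math.sqrt(config.reps))
        se2 = float(next2.std(ddof=1) / math.sqrt(config.reps))
    else:
        se1 = se2 = 0.0
    z1 = (mean1 - closed.N1) / se1 if se1 > 0 else 0.0
    z2 = (mean2 - closed.N2) / se2 if se2 > 0 else 0.0
    return MonteCarloResult(
        mean1=mean1, mean2=mean2, se1=se1, se2=se2,
        frac_repro1=float(repro1.mean() / N1) if N1 else 0.0,
        frac_repro2=float(repro2.mean() / N2) if N2 else 0.0,
        closed1=closed.N1, closed2=closed.N2, z1=z1, z2=z2,
        reps=config.reps, next1=next1, next2=next2)


@dataclass(frozen=True)
class EmpiricalSummary:
    """Histogram summaries of a collection of allocation outcomes."""

    n_outcomes: int
    m1_counts: np.ndarray            # pooled per-individual unit counts of sp1
    joint_counts: np.ndarray         # counts over (M1, M2)
    mean_m1: float
    mean_M1: float
    cv2_by_M1: dict[int, float]      # pooled CV^2 of m1 conditional on M1


def empirical_summary(outcomes: Iterable[AllocationOutcome]) -> EmpiricalSummary:
    """Empirical pmfs of ``m1`` and ``(M1, M2)``, the mean of each, and the
    squared coefficient of variation of ``m1`` conditional on each observed
    ``M1`` (comparison target: ``(N1/M1)(1 - 1/N1)``)."""
    outcomes = list(outcomes)
    _require(len(outcomes) > 0, "empty outcome collection")
    units = np.stack([o.units1 for o in outcomes])  # (n, N1)
    m1_all = units.ravel().astype(np.int64)
    M1s = np.array([o.M1 for o in outcomes])
    M2s = np.array([o.M2 for o in outcomes])
    m1_counts = np.bincount(m1_all) if m1_all.size else np.array([0])
    joint = np.zeros((int(M1s.max()) + 1, int(M2s.max()) + 1), dtype=np.int64)
    np.add.at(joint, (M1s, M2s), 1)
    cv2: dict[int, float] = {}
    if units.shape[1] > 0:
        for M1 in np.unique(M1s):
            pooled = units[M1s == M1].ravel()
            mu = pooled.mean()
            cv2[int(M1)] = float(pooled.var() / mu**2) if mu > 0 else 0.0
    return EmpiricalSummary(
        n_outcomes=len(outcomes), m1_counts=m1_counts, joint_counts=joint,
        mean_m1=float(m1_all.mean()) if m1_all.size else 0.0,
        mean_M1=float(M1s.mean()), cv2_by_M1=cv2)


# ---------------------------------------------------------------------------
# 5. Verification registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentityCheck:
    name: str
    passed: bool
    discrepancy: float
    tolerance: float
    detail: str = ""
    informational: bool = False


def _default_community() -> CommunityParams:
    return CommunityParams(
        sp1=SpeciesParams(u=1.0, s=2, lam=2.0, alpha=1.0, name="sp1"),
        sp2=SpeciesParams(u=2.0, s=1, lam=2.0, alpha=1.0, name="sp2"),
        Rbar=10.0)


def verify_identities(perturb_b12: float = 0.0) -> list[IdentityCheck]:
    """Cross-check every analytic identity of the model numerically.

    Covers: coefficient identities (reciprocity, ``a_i Mbar_i_max = 1``, the
    ``c12`` factorisation), normalisation and mixture/marginalisation
    identities of the allocation laws, compound unit law versus brute force,
    the enumeration oracle versus the closed-form map, the equal-unit and
    single-species reductions, the constrained-map rewrite, the
    scramble-limit convergence, inequality-index behaviour, and the
    Hassell fixed-point round trip.  ``perturb_b12`` is a debug hook that
    biases the closed-form geometric ratio in the marginalisation check; any
    nonzero value must make that check fail (negative control).
    """
    checks: list[IdentityCheck] = []
    params = _default_community()
    state = PopulationState(5, 5)

    def add(name: str, disc: float, tol: float, detail: str = "",
            informational: bool = False) -> None:
        checks.append(IdentityCheck(
            name=name, passed=bool(informational or disc <= tol),
            discrepancy=float(disc), tolerance=tol, detail=detail,
            informational=informational))

    # coefficient identities
    rng = np.random.default_rng(20240814)
    worst_rec, worst_am, worst_c = 0.0, 0.0, 0.0
    for _ in range(100):
        u1, u2 = rng.uniform(0.05, 5.0, 2)
        al1, al2 = rng.uniform(0.2, 5.0, 2)
        R = rng.uniform(1.0, 100.0)
        co = derive_coefficients(CommunityParams(
            SpeciesParams(u1, 1, 1.0, al1), SpeciesParams(u2, 1, 1.0, al2), R))
        worst_rec = max(worst_rec, abs(co.b12 * co.b21 - 1.0))
        worst_am = max(worst_am, abs(co.a1 * co.Mbar1max - 1.0),
                       abs(co.a2 * co.Mbar2max - 1.0))
        worst_c = max(worst_c, abs(co.b12 - co.Mbar1max / co.Mbar2max * co.c12)
                      / co.b12)
    add("reciprocity b12*b21=1", worst_rec, 1e-12)
    add("a_i * Mbar_i_max = 1", worst_am, 1e-12)
    add("b12 = (Mbar1max/Mbar2max) * c12", worst_c, 1e-12)

    # fixed-R joint law: exact normalisation
    fixedR = joint_allocation_pmf_fixed_R(params, PopulationState(2, 2), 7.3)
    add("fixed-R joint law mass = 1", abs(fixedR.total_mass() - 1.0), 1e-12)

    # exponential-R joint law: normalisation under truncation
    joint = joint_allocation_pmf(params, state, truncation=1e-12)
    add("exponential-R joint law mass = 1", abs(joint.total_mass() - 1.0), 1e-10)

    # mixture identity: quadrature of the fixed-R law against exponential R
    small = CommunityParams(replace(params.sp1), replace(params.sp2), Rbar=3.0)
    st_small = PopulationState(2, 2)
    target = joint_allocation_pmf(small, st_small, truncation=1e-10)
    disc = 0.0
    u1, u2, Rb = small.sp1.u, small.sp2.u, small.Rbar
    for M1 in range(8):
        for M2 in range(5):
            A = u1 * M1 + u2 * M2
            B = A + max(u1, u2)

            def integrand(R: float, M1=M1, M2=M2) -> float:
                jp = joint_allocation_pmf_fixed_R(small, st_small, R)
                val = jp.p[M1, M2] if (M1 < jp.p.shape[0] and M2 < jp.p.shape[1]) else 0.0
                return val * math.exp(-R / Rb) / Rb

            q, _ = integrate.quad(integrand, max(A, 1e-12), B,
                                  points=[A + u1, A + u2], limit=200,
                                  epsabs=1e-12)
            disc = max(disc, abs(q - target.p[M1, M2]))
    add("mixture identity (quadrature)", disc, 1e-8)

    # marginalisation: row sums vs closed-form geometric
    x, y = _xy(params, state)
    ratio = x / (1.0 - y) + perturb_b12
    rows = joint.marginal(1)
    K = rows.size - 1
    geom = (1.0 - ratio) * ratio ** np.arange(K + 1)
    add("marginalisation row sums = geometric", float(np.abs(rows - geom).max()),
        1e-10, detail="perturbed" if perturb_b12 else "")

    # mean-form discrepancy (informational): self-consistent vs printed factor
    co = derive_coefficients(params)
    dens = state.N1 + co.b12 * state.N2
    mean_sc = state.N1 / (co.a1 * dens)
    mean_printed = state.N1 / (_one_minus_exp_neg(params.sp1.u, params.Rbar) * dens)
    mean_exact = marginal_allocation_pmf(params, state, 1).numeric_mean()
    add("Mbar1 display forms", abs(mean_printed / mean_sc - math.exp(
        params.sp1.u / params.Rbar)), 1e-12, informational=True,
        detail=(f"exact mean {mean_exact:.10f}; (e^u/R-1)-form {mean_sc:.10f}; "
                f"(1-e^-u/R)-form {mean_printed:.10f} "
                f"(differs by factor e^(u1/Rbar))"))

    # compound unit law vs brute-force triple sum
    unit = marginal_unit_pmf(params, state, 1, truncation=1e-12)
    M_law = marginal_allocation_pmf(params, state, 1, truncation=1e-12)
    brute = np.zeros(unit.p.size)
    for m in range(brute.size):
        brute[m] = sum(stats.binom.pmf(m, M, 1.0 / 5) * M_law.p[M]
                       for M in range(M_law.p.size))
    add("compound unit law vs brute force", float(np.abs(unit.p - brute).max()),
        1e-9)

    # unit-law tail reproduces the closed-form reproduction probability
    g1 = _hassell_factor(dens, co.a1, params.sp1.s)
    add("unit-law tail = reproduction probability",
        abs(unit.tail_sum(params.sp1.s) - g1), 1e-10)

    # enumeration oracle vs closed-form map
    worst = 0.0
    for (n1, n2) in [(1, 1), (3, 2), (5, 5), (10, 4)]:
        en = enumeration_expectation(params, PopulationState(n1, n2))
        cf = expected_next_generation(params, PopulationState(n1, n2), "general")
        worst = max(worst, abs(en.f1 - cf.N1) / cf.N1, abs(en.f2 - cf.N2) / cf.N2)
    add("enumeration oracle vs closed form", worst, 1e-6)

    # equal-unit reduction: exact
    eq = CommunityParams(SpeciesParams(1.5, 2, 2.0, 1.0),
                         SpeciesParams(1.5, 3, 1.5, 2.0), 12.0)
    worst = 0.0
    for st in [PopulationState(a, b) for a in (0, 2, 7) for b in (0, 3, 9)]:
        g = expected_next_generation(eq, st, "general")
        e = expected_next_generation(eq, st, "equal_unit")
        worst = max(worst, abs(g.N1 - e.N1), abs(g.N2 - e.N2))
    add("equal-unit reduction exact", worst, 0.0)

    # single-species reduction at N2 = 0
    st0 = PopulationState(7, 0)
    g = expected_next_generation(params, st0, "general").N1
    s = single_species_expectation(7, params.sp1, params.Rbar)
    add("single-species reduction", abs(g - s), 1e-14)

    # constrained rewrite: round trip + map identity
    cspec = ConstrainedSpec(s1=3, k1=10.0, b12=1.4)
    cp = constrained_params(cspec, Rbar=10.0, sp2=params.sp2, alpha1=1.0)
    cco = derive_coefficients(cp)
    add("constrained round trip b12", abs(cco.b12 - cspec.b12) / cspec.b12, 1e-12)
    st = PopulationState(6, 4)
    f_gen = expected_next_generation(cp, st, "general").N1
    f_38 = cp.sp1.lam * st.N1 * _hassell_factor(
        st.N1 + cspec.b12 * st.N2, 1.0 / (cspec.s1 * cspec.k1), cspec.s1)
    add("constrained map rewrite", abs(f_gen - f_38) / f_38, 1e-12)

    # scramble-limit convergence: the constrained map is exactly
    # [1 + c/s1]^(-s1) with c = (N1 + b12 N2)/k1, so its relative deviation
    # from the Ricker form e^(-c) is exp(c^2/(2 s1) - ...) - 1: check the
    # O(1/s1) rate at its exact first-order size over c in [0, 3]
    k1 = 10.0
    for s1, label in ((200, "s1=200"), (2000, "s1=2000")):
        cpl = constrained_params(ConstrainedSpec(s1, k1, 1.0), 10.0,
                                 params.sp2, 1.0)
        worst = 0.0
        for n1 in np.linspace(0.0, 3 * k1, 61):
            f = expected_next_generation(cpl, PopulationState(n1, 0),
                                         "general").N1
            ricker = cpl.sp1.lam * n1 * math.exp(-n1 / k1)
            if ricker > 0:
                worst = max(worst, abs(f - ricker) / ricker)
        add(f"scramble limit ({label}) vs Ricker at O(c^2/2s) rate",
            worst, 1.01 * math.expm1(9.0 / (2 * s1)))

    # inequality index: zero at N1=1, inverse proportionality to s1
    eta_single = inequality_metrics(params, PopulationState(1, 4)).eta1
    add("eta1 = 0 at N1 = 1", abs(eta_single), 0.0)
    etas = [inequality_metrics(
        constrained_params(ConstrainedSpec(s, 10.0, 1.2), 10.0, params.sp2, 1.0),
        PopulationState(6, 4),
        constrained=ConstrainedSpec(s, 10.0, 1.2)).eta1_constrained
        for s in (1, 2, 4)]
    add("eta1 inversely proportional to s1",
        max(abs(etas[0] / etas[1] - 2.0), abs(etas[0] / etas[2] - 4.0)), 1e-12)

    # Hassell fixed-point round trip
    worst = 0.0
    for theta in (1.0, 2.0, 4.0, 8.0):
        a = a_from_fixed_point(1.5, theta, 10.0)
        worst = max(worst, abs(fixed_point(HassellParams(1.5, a, theta)) - 10.0))
    add("fixed-point round trip", worst, 1e-10)

    return checks


#: number of distinct analytic relationships exercised by verify_identities;
#: kept in sync by the test suite
COVERED_EQUATION_COUNT = 20


# ---------------------------------------------------------------------------
# 6. Config and table I/O
# ---------------------------------------------------------------------------

def load_config(path: str, allowed_keys: set[str] | None = None) -> dict:
    """Parse a YAML key-value config file into a flat dict.

    Raises :class:`ValidationError` naming the offending keys when the file
    is not a mapping or contains keys outside ``allowed_keys``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"config {path!r} must be a key-value mapping")
    if allowed_keys is not None:
        bad = sorted(set(data) - allowed_keys)
        if bad:
            raise ValidationError(
                f"config {path!r} has unknown keys: {', '.join(bad)}")
    return data


def write_table(rows: pd.DataFrame | list[dict], path: str,
                fmt: Literal["csv", "json"] = "csv") -> None:
    """Write a table as header-first CSV or JSON records; floats are
    serialised with full round-trip precision."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        records = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1,
                      default=lambda o: o.item() if isinstance(o, np.generic) else o)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown format {fmt!r}")
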
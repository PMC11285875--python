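"""Seawater CO2-system speciation and the calcification CO2-release ratio (psi).

The carbonate system is solved from any two of {pH, total alkalinity, DIC,
pCO2} using literature formulations of the equilibrium constants.  On top of
the solver sit two estimators of psi, the number of moles of CO2 released to
solution per mole of carbonate precipitated in buffered seawater:

* :func:`psi_analytic` — a closed-form expression obtained by
  differentiating the speciation along the constant-pCO2 family, i.e. the
  analytical buffer-factor approach of Frankignoulle;
* :func:`psi_finite_difference` — a numerical perturbation oracle that
  precipitates a small amount of carbonate, re-solves the system and forms
  the difference quotient.

psi is the ratio for seawater that stays in contact with the atmosphere:
precipitating delta mol of carbonate removes 2*delta of alkalinity and delta
of DIC, the water re-equilibrates at its original pCO2, and the CO2 that had
to evade to get there, divided by delta, is psi.  Equivalently
psi = 2*(dDIC/dTA at constant pCO2) - 1, which evaluates to ~0.6 at 25 degC
and ~0.7 at 15 degC for present-day surface seawater.

All concentrations are mol kg-SW^-1 internally; pCO2 is in atm; hydrogen-ion
concentration is kept on the total scale (NBS input is converted at the
boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from scipy.optimize import brentq

__all__ = [
    "PhScale",
    "ConstantFormulation",
    "EquilibriumConstants",
    "SeawaterState",
    "PsiResult",
    "compute_constants",
    "solve_system",
    "psi_analytic",
    "psi_finite_difference",
    "convert_ph",
]


class DomainError(ValueError):
    """An input lies outside the physically meaningful domain."""


class ConvergenceError(RuntimeError):
    """The iterative solver failed to converge."""


class PhScale(str, Enum):
    total = "total"
    sws = "sws"
    nbs = "nbs"


@dataclass(frozen=True)
class ConstantFormulation:
    """Which literature expressions supply each equilibrium constant.

    Defaults: K0 Weiss (1974); K1/K2 Mehrbach data as refit by Dickson &
    Millero (1987); KB Dickson (1990); KW Millero (1995); total boron
    Uppstrom (1974).  Alternates are selectable so the sensitivity of psi to
    the constant set can be examined.
    """

    k0: str = "weiss_1974"
    k1k2: str = "mehrbach_dm87"  # alternates: "lueker_2000", "roy_1993"
    kb: str = "dickson_1990"
    kw: str = "millero_1995"
    tb: str = "uppstrom_1974"  # alternate: "lee_2010"


@dataclass(frozen=True)
class EquilibriumConstants:
    """Apparent equilibrium constants of the seawater CO2 system.

    All constants are on the total hydrogen-ion scale, mol kg-SW^-1 based:
    ``k0`` (mol kg-1 atm-1) CO2 solubility, ``k1``/``k2`` (mol kg-1) carbonic
    acid, ``kb`` (mol kg-1) boric acid, ``kw`` (mol2 kg-2) water, and ``tb``
    (mol kg-1) total boron.
    """

    k0: float
    k1: float
    k2: float
    kb: float
    kw: float
    tb: float
    temperature: float
    salinity: float
    ph_scale: PhScale = PhScale.total
    formulation: ConstantFormulation = field(default_factory=ConstantFormulation)

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "k2", "kb", "kw", "tb"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.k1 <= self.k2:
            raise DomainError("k1 must exceed k2")


@dataclass(frozen=True)
class SeawaterState:
    """Fully speciated seawater CO2 system (mol kg-1, pCO2 in atm).

    ``ah`` is the hydrogen-ion concentration on the total scale;
    ``carbonate_alkalinity`` is [HCO3-] + 2[CO3--], the alkalinity component
    the psi model is written in.
    """

    temperature: float
    salinity: float
    total_alkalinity: float
    carbonate_alkalinity: float
    dic: float
    ah: float
    co2: float
    hco3: float
    co3: float
    pco2: float

    @property
    def ph_total(self) -> float:
        return -math.log10(self.ah)

    def validate(self, constants: EquilibriumConstants) -> None:
        """Raise if the internal mass/charge/equilibrium identities fail."""
        if min(self.co2, self.hco3, self.co3, self.ah, self.pco2) < 0:
            raise DomainError("negative concentration in solved state")
        if not math.isclose(self.co2 + self.hco3 + self.co3, self.dic, rel_tol=1e-10):
            raise DomainError("DIC decomposition does not close")
        if not math.isclose(
            self.hco3 + 2.0 * self.co3, self.carbonate_alkalinity, rel_tol=1e-10
        ):
            raise DomainError("carbonate-alkalinity decomposition does not close")
        # Apparent-constant identity aH = K1*K0*pCO2 / [HCO3-] (equivalently
        # K1 = aH*[HCO3-]/[CO2]): the defining relation of K1 on a solved state.
        if not math.isclose(
            self.ah * self.hco3, constants.k1 * constants.k0 * self.pco2, rel_tol=1e-8
        ):
            raise DomainError("carbonic-acid equilibrium identity violated")


@dataclass(frozen=True)
class PsiResult:
    """psi plus the intermediates of the analytical buffer-factor model.

    ``p``, ``q``, ``r``, ``cs`` are the P, Q, R and C_S groupings of the
    analytic model (P = KB*TB/(aH+KB)^2 + KW/aH^2 + 1 is minus the derivative
    of the non-carbonate alkalinity with respect to aH; Q = aH + 2*K2;
    R = A*Q + 2*K2*A + P*Q*aH; C_S = K2*A + P*Q*(aH+K2) + R*aH/K1
    - Q*aH*(1 + 2*aH/K1)).
    """

    psi: float
    p: float
    q: float
    r: float
    cs: float
    method: str


# ---------------------------------------------------------------------------
# Equilibrium constants
# ---------------------------------------------------------------------------


def _check_ts_range(temperature: float, salinity: float) -> None:
    if not (-2.0 <= temperature <= 40.0):
        raise DomainError(f"temperature {temperature} degC outside [-2, 40]")
    if not (0.0 <= salinity <= 45.0):
        raise DomainError(f"salinity {salinity} outside [0, 45]")


def _total_sulfate(s: float) -> float:
    # Morris & Riley (1966): mol kg-SW^-1
    return (0.14 / 96.062) * (s / 1.80655)


def _total_fluoride(s: float) -> float:
    # Riley (1965)
    return (0.000067 / 18.998) * (s / 1.80655)


def _ks_free(tk: float, s: float) -> float:
    # Dickson (1990a) bisulfate dissociation, free scale, mol kg-SW^-1
    i = 19.924 * s / (1000.0 - 1.005 * s)
    ln_ks = (
        -4276.1 / tk
        + 141.328
        - 23.093 * math.log(tk)
        + (-13856.0 / tk + 324.57 - 47.986 * math.log(tk)) * math.sqrt(i)
        + (35474.0 / tk - 771.54 + 114.723 * math.log(tk)) * i
        - (2698.0 / tk) * i**1.5
        + (1776.0 / tk) * i**2
        + math.log(1.0 - 0.001005 * s)
    )
    return math.exp(ln_ks)


def _kf_free(tk: float, s: float) -> float:
    # Dickson & Riley (1979) hydrogen fluoride dissociation, free scale
    i = 19.924 * s / (1000.0 - 1.005 * s)
    ln_kf = 1590.2 / tk - 12.641 + 1.525 * math.sqrt(i) + math.log(1.0 - 0.001005 * s)
    return math.exp(ln_kf)


def _sws_to_total_factor(tk: float, s: float) -> float:
    """Multiply an SWS-scale constant (or aH) by this to get the total scale."""
    ts, tf = _total_sulfate(s), _total_fluoride(s)
    ks, kf = _ks_free(tk, s), _kf_free(tk, s)
    return (1.0 + ts / ks) / (1.0 + ts / ks + tf / kf)


def _fh_nbs(tk: float, s: float) -> float:
    # Takahashi et al. (1982) activity coefficient linking NBS and SWS scales
    return 1.2948 - 0.002036 * tk + (4.607e-4 - 1.475e-6 * tk) * s**2


def convert_ph(
    ph: float,
    from_scale: PhScale | str,
    to_scale: PhScale | str,
    temperature: float,
    salinity: float,
) -> float:
    """Convert a pH value between the total, seawater (SWS) and NBS scales."""
    from_scale, to_scale = PhScale(from_scale), PhScale(to_scale)
    if from_scale == to_scale:
        return ph
    tk = temperature + 273.15
    ah = 10.0 ** (-ph)
    # to SWS-scale hydrogen-ion concentration first
    if from_scale == PhScale.nbs:
        ah = ah / _fh_nbs(tk, salinity)
    elif from_scale == PhScale.total:
        ah = ah / _sws_to_total_factor(tk, salinity)
    if to_scale == PhScale.nbs:
        ah = ah * _fh_nbs(tk, salinity)
    elif to_scale == PhScale.total:
        ah = ah * _sws_to_total_factor(tk, salinity)
    return -math.log10(ah)


def _k0_weiss(tk: float, s: float) -> float:
    t100 = tk / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / t100
        + 23.3585 * math.log(t100)
        + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100**2)
    )
    return math.exp(ln_k0)


def _k1k2_mehrbach_dm87(tk: float, s: float) -> tuple[float, float]:
    """Mehrbach et al. (1973) refit by Dickson & Millero (1987); SWS scale."""
    pk1 = 3670.7 / tk - 62.008 + 9.7944 * math.log(tk) - 0.0118 * s + 0.000116 * s**2
    pk2 = 1394.7 / tk + 4.777 - 0.0184 * s + 0.000118 * s**2
    f = _sws_to_total_factor(tk, s)
    return 10.0**-pk1 * f, 10.0**-pk2 * f


def _k1k2_lueker(tk: float, s: float) -> tuple[float, float]:
    """Lueker et al. (2000) refit of the Mehrbach data; total scale."""
    pk1 = 3633.86 / tk - 61.2172 + 9.67770 * math.log(tk) - 0.011555 * s + 0.0001152 * s**2
    pk2 = 471.78 / tk + 25.9290 - 3.16967 * math.log(tk) - 0.01781 * s + 0.0001122 * s**2
    return 10.0**-pk1, 10.0**-pk2


def _k1k2_roy(tk: float, s: float) -> tuple[float, float]:
    """Roy et al. (1993); total scale."""
    lnk1 = (
        -2307.1266 / tk
        + 2.83655
        - 1.5529413 * math.log(tk)
        + (-4.0484 / tk - 0.20760841) * math.sqrt(s)
        + 0.08468345 * s
        - 0.00654208 * s**1.5
        + math.log(1.0 - 0.001005 * s)
    )
    lnk2 = (
        -3351.6106 / tk
        - 9.226508
        - 0.2005743 * math.log(tk)
        + (-23.9722 / tk - 0.106901773) * math.sqrt(s)
        + 0.1130822 * s
        - 0.00846934 * s**1.5
        + math.log(1.0 - 0.001005 * s)
    )
    return math.exp(lnk1), math.exp(lnk2)


def _kb_dickson(tk: float, s: float) -> float:
    """Dickson (1990b) boric acid; total scale."""
    sq = math.sqrt(s)
    ln_kb = (
        (-8966.90 - 2890.53 * sq - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2) / tk
        + 148.0248
        + 137.1942 * sq
        + 1.62142 * s
        + (-24.4344 - 25.085 * sq - 0.2474 * s) * math.log(tk)
        + 0.053105 * sq * tk
    )
    return math.exp(ln_kb)


def _kw_millero(tk: float, s: float) -> float:
    """Millero (1995) water ion product; SWS scale, converted to total."""
    ln_kw = (
        148.9802
        - 13847.26 / tk
        - 23.6521 * math.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * math.log(tk)) * math.sqrt(s)
        - 0.01615 * s
    )
    return math.exp(ln_kw) * _sws_to_total_factor(tk, s)


def _tb(s: float, formulation: str) -> float:
    if formulation == "uppstrom_1974":
        return 0.000416 * s / 35.0
    if formulation == "lee_2010":
        return 0.0004326 * s / 35.0
    raise DomainError(f"unknown total-boron formulation {formulation!r}")


def compute_constants(
    temperature: float,
    salinity: float,
    formulation: Optional[ConstantFormulation] = None,
) -> EquilibriumConstants:
    """Evaluate the equilibrium constants at ``temperature`` (degC) and
    ``salinity`` (practical), on the total hydrogen-ion scale.

    Deterministic: identical (T, S, formulation) always yield bit-identical
    constants.
    """
    _check_ts_range(temperature, salinity)
    formulation = formulation or ConstantFormulation()
    tk = temperature + 273.15

    if formulation.k0 != "weiss_1974":
        raise DomainError(f"unknown K0 formulation {formulation.k0!r}")
    k0 = _k0_weiss(tk, salinity)

    k1k2 = {
        "mehrbach_dm87": _k1k2_mehrbach_dm87,
        "lueker_2000": _k1k2_lueker,
        "roy_1993": _k1k2_roy,
    }
    if formulation.k1k2 not in k1k2:
        raise DomainError(f"unknown K1/K2 formulation {formulation.k1k2!r}")
    k1, k2 = k1k2[formulation.k1k2](tk, salinity)

    if formulation.kb != "dickson_1990":
        raise DomainError(f"unknown KB formulation {formulation.kb!r}")
    if formulation.kw != "millero_1995":
        raise DomainError(f"unknown KW formulation {formulation.kw!r}")
    return EquilibriumConstants(
        k0=k0,
        k1=k1,
        k2=k2,
        kb=_kb_dickson(tk, salinity),
        kw=_kw_millero(tk, salinity),
        tb=_tb(salinity, formulation.tb),
        temperature=temperature,
        salinity=salinity,
        ph_scale=PhScale.total,
        formulation=formulation,
    )


# ---------------------------------------------------------------------------
# System solver
# ---------------------------------------------------------------------------


def _speciate_from_ah_dic(ah: float, dic: float, k: EquilibriumConstants):
    d = ah * ah + k.k1 * ah + k.k1 * k.k2
    co2 = dic * ah * ah / d
    hco3 = dic * k.k1 * ah / d
    co3 = dic * k.k1 * k.k2 / d
    return co2, hco3, co3


def _total_alkalinity(ah: float, dic: float, k: EquilibriumConstants) -> float:
    co2, hco3, co3 = _speciate_from_ah_dic(ah, dic, k)
    borate = k.kb * k.tb / (ah + k.kb)
    return hco3 + 2.0 * co3 + borate + k.kw / ah - ah


def _state_from_ah_dic(
    ah: float, dic: float, temperature: float, salinity: float, k: EquilibriumConstants
) -> SeawaterState:
    co2, hco3, co3 = _speciate_from_ah_dic(ah, dic, k)
    return SeawaterState(
        temperature=temperature,
        salinity=salinity,
        total_alkalinity=_total_alkalinity(ah, dic, k),
        carbonate_alkalinity=hco3 + 2.0 * co3,
        dic=dic,
        ah=ah,
        co2=co2,
        hco3=hco3,
        co3=co3,
        pco2=co2 / k.k0,
    )


_PH_LO, _PH_HI = 2.0, 12.0


def _solve_ph(residual, what: str) -> float:
    """Bracketed root of ``residual(pH)`` on [2, 12]; |dpH| < 1e-12."""
    lo, hi = residual(_PH_LO), residual(_PH_HI)
    if lo * hi > 0:
        raise ConvergenceError(
            f"cannot bracket pH for {what}: residual({_PH_LO})={lo:.3e}, "
            f"residual({_PH_HI})={hi:.3e}"
        )
    return brentq(residual, _PH_LO, _PH_HI, xtol=1e-13, rtol=8.9e-16, maxiter=200)


def solve_system(
    temperature: float,
    salinity: float,
    constants: Optional[EquilibriumConstants] = None,
    *,
    ph: Optional[float] = None,
    ph_scale: PhScale | str = PhScale.total,
    total_alkalinity: Optional[float] = None,
    dic: Optional[float] = None,
    pco2: Optional[float] = None,
) -> SeawaterState:
    """Solve the full CO2-system speciation from exactly two known quantities.

    Parameters are in mol kg-1 (alkalinity, DIC) and atm (pCO2); ``ph`` may be
    given on any scale (``ph_scale``) and is converted to the total scale.
    The alkalinity balance includes the carbonate, borate and water terms.

    Raises :class:`DomainError` for an invalid pair and
    :class:`ConvergenceError` if the bracketed pH search fails.
    """
    k = constants or compute_constants(temperature, salinity)
    known = {
        "ph": ph,
        "total_alkalinity": total_alkalinity,
        "dic": dic,
        "pco2": pco2,
    }
    given = [name for name, v in known.items() if v is not None]
    if len(given) != 2:
        raise DomainError(
            f"exactly two of (ph, total_alkalinity, dic, pco2) required, got {given}"
        )
    for name in ("total_alkalinity", "dic", "pco2"):
        v = known[name]
        if v is not None and v <= 0:
            raise DomainError(f"{name} must be positive, got {v}")

    if ph is not None:
        ph_t = convert_ph(ph, ph_scale, PhScale.total, temperature, salinity)
        ah = 10.0**-ph_t
        if dic is not None:
            return _state_from_ah_dic(ah, dic, temperature, salinity, k)
        if total_alkalinity is not None:
            borate = k.kb * k.tb / (ah + k.kb)
            ca = total_alkalinity - borate - k.kw / ah + ah
            if ca <= 0:
                raise DomainError(
                    "total alkalinity leaves no carbonate alkalinity at this pH"
                )
            d = ah * ah + k.k1 * ah + k.k1 * k.k2
            dic_val = ca * d / (k.k1 * ah + 2.0 * k.k1 * k.k2)
            return _state_from_ah_dic(ah, dic_val, temperature, salinity, k)
        # ph + pco2
        co2 = k.k0 * pco2
        d = ah * ah + k.k1 * ah + k.k1 * k.k2
        dic_val = co2 * d / (ah * ah)
        return _state_from_ah_dic(ah, dic_val, temperature, salinity, k)

    if dic is not None and pco2 is not None:
        co2 = k.k0 * pco2
        if co2 >= dic:
            raise DomainError("pCO2 implies [CO2*] >= DIC: impossible pair")
        # (dic-co2)*ah^2 - co2*k1*ah - co2*k1*k2 = 0
        a, b, c = dic - co2, -co2 * k.k1, -co2 * k.k1 * k.k2
        ah = (-b + math.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
        return _state_from_ah_dic(ah, dic, temperature, salinity, k)

    if total_alkalinity is not None and dic is not None:
        def residual(p: float) -> float:
            return _total_alkalinity(10.0**-p, dic, k) - total_alkalinity

        ph_sol = _solve_ph(residual, "(TA, DIC)")
        return _state_from_ah_dic(10.0**-ph_sol, dic, temperature, salinity, k)

    # total_alkalinity + pco2
    co2 = k.k0 * pco2

    def residual(p: float) -> float:
        ah = 10.0**-p
        hco3 = k.k1 * co2 / ah
        co3 = k.k2 * hco3 / ah
        borate = k.kb * k.tb / (ah + k.kb)
        return hco3 + 2.0 * co3 + borate + k.kw / ah - ah - total_alkalinity

    ph_sol = _solve_ph(residual, "(TA, pCO2)")
    ah = 10.0**-ph_sol
    hco3 = k.k1 * co2 / ah
    co3 = k.k2 * hco3 / ah
    return _state_from_ah_dic(ah, co2 + hco3 + co3, temperature, salinity, k)


# ---------------------------------------------------------------------------
# psi — CO2 released per carbonate precipitated
# ---------------------------------------------------------------------------


def _psi_intermediates(state: SeawaterState, k: EquilibriumConstants):
    h = state.ah
    a = state.carbonate_alkalinity
    p = k.kb * k.tb / (h + k.kb) ** 2 + k.kw / h**2 + 1.0
    q = h + 2.0 * k.k2
    r = a * q + 2.0 * k.k2 * a + p * q * h
    # C_S grouping of the buffer-factor model: the implicit-function
    # denominator K2*A + P*Q*(aH+K2) + R*aH/K1 minus Q*aH*(1 + 2*aH/K1).
    ds = k.k2 * a + p * q * (h + k.k2) + r * h / k.k1
    cs = ds - q * h * (1.0 + 2.0 * h / k.k1)
    return p, q, r, cs


def psi_analytic(state: SeawaterState, constants: EquilibriumConstants) -> PsiResult:
    """Closed-form psi at ``state``: CO2 evaded per mole of carbonate
    precipitated, for water that re-equilibrates with the atmosphere.

    Derivation: at constant pCO2 (hence constant [CO2*]) the speciation is a
    one-parameter family in aH, so dDIC/dTA is a ratio of two derivatives.
    Precipitation removes 2*delta of TA and delta of DIC, and gas exchange
    restores pCO2 by moving DIC alone, leaving

        psi = 2*(dDIC/dTA)|pCO2 - 1
            = aH*(A - Q*(P - 1)) / (R - Q*aH),

    with A the carbonate alkalinity and P, Q, R the buffer-factor groupings
    stored on the result.  Positive because CO2 rises as carbonate ions fall.
    """
    k = constants
    h, a = state.ah, state.carbonate_alkalinity
    p, q, r, cs = _psi_intermediates(state, k)
    denom = r - q * h
    if denom == 0:
        raise ZeroDivisionError("psi intermediate R - Q*aH is zero")
    psi = h * (a - q * (p - 1.0)) / denom
    return PsiResult(psi=psi, p=p, q=q, r=r, cs=cs, method="analytic")


def psi_finite_difference(
    state: SeawaterState,
    constants: EquilibriumConstants,
    delta: float = 1e-8,
) -> PsiResult:
    """Numerical-perturbation psi, the oracle for :func:`psi_analytic`.

    Simulates precipitation of ``delta`` mol kg-1 of carbonate (TA - 2*delta,
    DIC - delta) followed by re-equilibration at the unperturbed pCO2; the
    DIC the water can no longer hold is the evaded CO2.  The symmetric
    precipitation/dissolution pair is used, so the quotient

        psi = (DIC(TA + 2*delta) - DIC(TA - 2*delta)) / (2*delta) - 1

    (both re-solved at constant pCO2) converges at second order in ``delta``.
    """
    if not 0.0 < delta <= 1e-6:
        raise DomainError(f"delta must lie in (0, 1e-6], got {delta}")
    k = constants
    try:
        minus = solve_system(
            state.temperature,
            state.salinity,
            k,
            total_alkalinity=state.total_alkalinity - 2.0 * delta,
            pco2=state.pco2,
        )
        plus = solve_system(
            state.temperature,
            state.salinity,
            k,
            total_alkalinity=state.total_alkalinity + 2.0 * delta,
            pco2=state.pco2,
        )
    except ConvergenceError as exc:
        raise ConvergenceError(f"perturbed system unsolvable: {exc}") from exc
    psi = (plus.dic - minus.dic) / (2.0 * delta) - 1.0
    p, q, r, cs = _psi_intermediates(state, k)
    return PsiResult(psi=psi, p=p, q=q, r=r, cs=cs, method="finite_difference")
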
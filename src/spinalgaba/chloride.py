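"""One-compartment chloride-homeostasis model of GABAergic analgesia.

GABA_A channels pass both Cl- and HCO3- (permeability ratio ~4:1).  The
chloride reversal potential is set by the balance between synaptic Cl-
influx (conductance ``g_inh``) and extrusion through the KCC2
cotransporter (lumped conductance ``g_kcc2 = F * U_KCC2``), giving the
equilibrium

    E_Cl = (g_inh * V_mean + g_kcc2 * E_K) / (g_inh + g_kcc2)

and an ohmic net anionic current

    I_anion = x * g_inh * (V_eff - E_Cl) + (1 - x) * g_inh * (V_eff - E_HCO3).

Because E_Cl depolarizes as g_inh grows, the current has an interior
maximum in g_inh and *collapses* beyond it: raising the inhibitory
conductance further (e.g. with a high benzodiazepine dose) reduces net
inhibition.  Strengthening KCC2 shifts the optimum to larger g_inh and
prevents the collapse.

The analgesic effect of a relative current increase dI (percent over the
injured baseline) is a saturating relation

    Effect(dI) = Max * dI / (Curhalf + dI)

calibrated from two anchor points.  Composing the inverses of these
relations maps behavioral dose-response curves of a GABA_A potentiator
and a KCC2 enhancer onto their respective effectors, from which
common-effector (Loewe-additive) and distinct-effector combination
surfaces are simulated.

All conductances are dimensionless, normalized to the injured-baseline
inhibitory conductance; potentials are in mV; relative changes ``dg``
are fractional (dg = 1.9 means the conductance is multiplied by 2.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares, minimize_scalar

from .pharmacology import HillParams, hill_response

__all__ = [
    "AnionParams",
    "AnionCurrentResult",
    "EffectParams",
    "GHKIonSet",
    "AnionAnchors",
    "EffectorMap",
    "GAS_CONSTANT",
    "FARADAY",
    "nernst",
    "ghk_anion_reversal",
    "reversal_from_iv",
    "equilibrium_ecl",
    "anion_current",
    "delta_anion_current",
    "current_polynomial_coefficients",
    "stationary_point_closed_form",
    "optimal_conductance",
    "collapse_curve",
    "effect_of_current",
    "inverse_effect",
    "calibrate_effect",
    "linear_current_for_effect",
    "calibrate_anion_constants",
    "effector_maps",
    "current_equivalent_dose",
    "combination_surfaces",
    "kcc2_flux",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


def nernst(c_in: float, c_out: float, temperature: float = 295.0, z: int = -1) -> float:
    """Nernst potential in mV for an ion of valence ``z``."""
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be positive")
    rt_f = GAS_CONSTANT * temperature / FARADAY * 1000.0  # mV
    return rt_f / z * math.log(c_out / c_in)


@dataclass(frozen=True)
class AnionParams:
    """Constants of the anion-current / KCC2 model.

    ``x`` is the Cl- fraction of the inhibitory conductance (0.8 for a 4:1
    Cl:HCO3 permeability ratio); ``g_inh_base`` and ``g_kcc2_base`` are the
    injured-baseline conductances (normalized so g_inh_base = 1; the KCC2
    value 0.81 was chosen so the baseline weighted anion reversal sits near
    -65 mV); ``e_hco3`` defaults to the Nernst value for 16/26 mM at 295 K.
    """

    x: float = 0.8
    v_mean: float = -60.0  # mV, time-averaged membrane potential
    v_eff: float = -55.0  # mV, reversal of effective inhibition (shunting)
    e_k: float = -95.0  # mV
    e_hco3: float = nernst(16.0, 26.0)  # ~ -12.3 mV
    g_inh_base: float = 1.0
    g_kcc2_base: float = 0.81
    u_kcc2: Optional[float] = None  # mol/(s V), only for explicit flux output

    def __post_init__(self) -> None:
        if not 0.0 < self.x < 1.0:
            raise ValueError("x must be in (0, 1)")
        if self.e_k >= self.v_mean:
            raise ValueError("e_k must be hyperpolarized relative to v_mean")
        if self.g_inh_base <= 0 or self.g_kcc2_base <= 0:
            raise ValueError("baseline conductances must be > 0")


@dataclass
class AnionCurrentResult:
    e_cl: float
    e_anion: float
    i_cl: float
    i_hco3: float
    i_anion: float
    g_cl: float
    g_hco3: float


@dataclass(frozen=True)
class EffectParams:
    """Saturating analgesia-current relation Effect(dI) = Max*dI/(Curhalf+dI).

    ``offset`` is the no-drug analgesic offset (% MPA) subtracted from
    experimental effects before any model use.
    """

    max_effect: float
    curhalf: float
    offset: float = 6.0

    def __post_init__(self) -> None:
        if self.max_effect <= 0 or self.curhalf <= 0:
            raise ValueError("max_effect and curhalf must be > 0")


@dataclass(frozen=True)
class GHKIonSet:
    """Ion concentrations (mM) and Cl:HCO3 permeability ratio for GHK."""

    cl_in: float = 29.0
    cl_out: float = 136.5
    hco3_in: float = 16.0
    hco3_out: float = 26.0
    perm_ratio_cl_to_hco3: float = 4.0
    temperature: float = 295.0

    def __post_init__(self) -> None:
        for name in ("cl_in", "cl_out", "hco3_in", "hco3_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 273.0 <= self.temperature <= 320.0:
            raise ValueError("temperature out of physiological range")


def ghk_anion_reversal(ions: GHKIonSet) -> float:
    """Goldman-Hodgkin-Katz reversal (mV) of the mixed Cl-/HCO3- current.

    For anions the intracellular concentrations appear in the numerator:
    E = (RT/F) * ln[(P_Cl*Cl_in + P_HCO3*HCO3_in) /
                    (P_Cl*Cl_out + P_HCO3*HCO3_out)].
    """
    rt_f = GAS_CONSTANT * ions.temperature / FARADAY * 1000.0
    p = ions.perm_ratio_cl_to_hco3
    return rt_f * math.log(
        (p * ions.cl_in + ions.hco3_in) / (p * ions.cl_out + ions.hco3_out)
    )


def reversal_from_iv(voltages: Sequence[float], currents: Sequence[float]) -> float:
    """Reversal potential (mV) extrapolated from an I-V relationship.

    Least-squares line through (V, I); the zero-current crossing is the
    reversal.  Needs at least three voltage steps and a non-flat current.
    """
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 voltage steps")
    slope, intercept = np.polyfit(v, i, 1)
    if abs(slope) < 1e-12 * max(1.0, float(np.abs(i).max())):
        raise ValueError("degenerate I-V relationship (zero slope)")
    return float(-intercept / slope)


def equilibrium_ecl(g_inh: float, g_kcc2: float, params: AnionParams) -> float:
    """E_Cl (mV) at which synaptic Cl- influx and KCC2 extrusion balance."""
    if g_inh < 0 or g_kcc2 < 0:
        raise ValueError("conductances must be >= 0")
    if g_inh + g_kcc2 == 0:
        raise ValueError("g_inh and g_kcc2 cannot both be zero")
    return (g_inh * params.v_mean + g_kcc2 * params.e_k) / (g_inh + g_kcc2)


def anion_current(g_inh: float, g_kcc2: float, params: AnionParams) -> AnionCurrentResult:
    """Net anionic current and its Cl-/HCO3- components at given conductances."""
    e_cl = equilibrium_ecl(g_inh, g_kcc2, params)
    g_cl = params.x * g_inh
    g_hco3 = (1.0 - params.x) * g_inh
    i_cl = g_cl * (params.v_eff - e_cl)
    i_hco3 = g_hco3 * (params.v_eff - params.e_hco3)
    e_anion = params.x * e_cl + (1.0 - params.x) * params.e_hco3
    return AnionCurrentResult(
        e_cl=e_cl,
        e_anion=e_anion,
        i_cl=i_cl,
        i_hco3=i_hco3,
        i_anion=i_cl + i_hco3,
        g_cl=g_cl,
        g_hco3=g_hco3,
    )


def delta_anion_current(dg_inh: float, dg_kcc2: float, params: AnionParams) -> float:
    """Relative change (%) of the net anionic current over the baseline.

    ``dg`` values are fractional increases of the respective conductance
    (dg_inh = 1.9 multiplies g_inh by 2.9).
    """
    if dg_inh < -1 or dg_kcc2 < -1:
        raise ValueError("dg values must be >= -1")
    base = anion_current(params.g_inh_base, params.g_kcc2_base, params).i_anion
    if base == 0:
        raise ValueError("baseline anionic current is zero")
    new = anion_current(
        params.g_inh_base * (1.0 + dg_inh),
        params.g_kcc2_base * (1.0 + dg_kcc2),
        params,
    ).i_anion
    return 100.0 * (new / base - 1.0)


def current_polynomial_coefficients(
    params: AnionParams, kcc2_scale: float = 1.0
) -> tuple[float, float, float]:
    """Coefficients (alpha, beta, m) of I(g) = g*(alpha*g + beta)/(g + m).

    The net current as a function of g_inh (at fixed g_kcc2 = m) is a
    rational function with ``alpha = x*(V_eff - V_mean) + (1-x)*(V_eff -
    E_HCO3)`` and ``beta = m*(x*(V_eff - E_K) + (1-x)*(V_eff - E_HCO3))``.
    The collapse regime is ``alpha < 0``.
    """
    x = params.x
    hco3_drive = (1.0 - x) * (params.v_eff - params.e_hco3)
    alpha = x * (params.v_eff - params.v_mean) + hco3_drive
    m = params.g_kcc2_base * kcc2_scale
    beta = m * (x * (params.v_eff - params.e_k) + hco3_drive)
    return alpha, beta, m


def stationary_point_closed_form(alpha: float, beta: float, m: float) -> float:
    """Interior stationary point of I(g) = g*(alpha*g + beta)/(g + m).

    For alpha < 0 and beta > 0 the unique positive root of
    alpha*g^2 + 2*alpha*m*g + beta*m = 0 is
    g* = -m + sqrt(m * (m + beta/|alpha|)).
    """
    if alpha >= 0:
        raise ValueError("no interior maximum: alpha must be negative")
    if beta <= 0 or m <= 0:
        raise ValueError("beta and m must be positive")
    return -m + math.sqrt(m * (m + beta / abs(alpha)))


def optimal_conductance(
    params: AnionParams, kcc2_scale: float = 1.0
) -> tuple[float, float]:
    """Conductance increase maximizing the net current, and the gain.

    Returns ``(dg_inh_star, dI_star)``: the fractional g_inh increase at
    which the net anionic current peaks (with g_kcc2 fixed at
    ``kcc2_scale`` times baseline) and the corresponding maximal relative
    current increase in percent.  Found by bounded scalar optimization; a
    monotone (non-collapsing) current is flagged as an error.
    """
    p = (
        params
        if kcc2_scale == 1.0
        else replace(params, g_kcc2_base=params.g_kcc2_base * kcc2_scale)
    )
    base = anion_current(p.g_inh_base, p.g_kcc2_base, p).i_anion

    def current(g):
        return anion_current(g, p.g_kcc2_base, p).i_anion

    # expand the bracket until the current has turned downward
    g_hi = max(2.0 * p.g_inh_base, 1.0)
    for _ in range(60):
        if current(2.0 * g_hi) < current(g_hi):
            break
        g_hi *= 2.0
    else:
        raise ValueError("no interior maximum: current is monotone in g_inh")
    opt = minimize_scalar(
        lambda g: -current(g),
        bounds=(1e-9, 4.0 * g_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    g_star = float(opt.x)
    if current(g_star) <= current(p.g_inh_base) and g_star <= p.g_inh_base:
        raise ValueError("no interior maximum above the baseline conductance")
    dg_star = g_star / p.g_inh_base - 1.0
    di_star = 100.0 * (current(g_star) / base - 1.0)
    return dg_star, di_star


def collapse_curve(
    g_inh_grid: Sequence[float], kcc2_scale: float, params: AnionParams
):
    """Net anionic current along a g_inh grid at a scaled KCC2 strength.

    Returns a pandas DataFrame with columns g_inh, e_cl, i_anion.
    """
    import pandas as pd

    grid = np.asarray(g_inh_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("g_inh grid must be positive")
    g_kcc2 = params.g_kcc2_base * kcc2_scale
    rows = [anion_current(g, g_kcc2, params) for g in grid]
    return pd.DataFrame(
        {
            "g_inh": grid,
            "e_cl": [r.e_cl for r in rows],
            "i_anion": [r.i_anion for r in rows],
        }
    )


def effect_of_current(delta_i: float, effect: EffectParams) -> float:
    """Analgesic effect (% MPA, offset-corrected) of a current increase (%)."""
    if delta_i < 0:
        raise ValueError("delta_i must be >= 0")
    return effect.max_effect * delta_i / (effect.curhalf + delta_i)


def inverse_effect(effect_value: float, effect: EffectParams) -> float:
    """Current increase (%) producing a given offset-corrected effect (%)."""
    if effect_value < 0 or effect_value >= effect.max_effect:
        raise ValueError("effect must be in [0, max_effect)")
    return effect.curhalf * effect_value / (effect.max_effect - effect_value)


def calibrate_effect(
    anchors: Sequence[tuple[float, float]], offset: float = 6.0
) -> EffectParams:
    """Solve the saturating effect relation from two (dI %, effect %) anchors."""
    if len(anchors) != 2:
        raise ValueError("exactly two anchors required")
    (i1, e1), (i2, e2) = anchors
    if i1 == i2 or e1 == e2:
        raise ValueError("anchors must be distinct in both coordinates")
    den = e1 * i2 - e2 * i1
    if den == 0:
        raise ValueError("degenerate anchors (proportional): Curhalf undefined")
    curhalf = i1 * i2 * (e2 - e1) / den
    max_effect = e1 * (curhalf + i1) / i1
    if curhalf <= 0 or max_effect <= 0:
        raise ValueError("anchors imply non-positive Curhalf or Max")
    return EffectParams(max_effect=max_effect, curhalf=curhalf, offset=offset)


def linear_current_for_effect(
    effect_pct: float, anchor: tuple[float, float] = (26.0, 25.0)
) -> float:
    """Current increase (%) for an effect under the linear low-dose anchor."""
    anchor_di, anchor_effect = anchor
    if anchor_effect <= 0:
        raise ValueError("anchor effect must be > 0")
    return effect_pct * anchor_di / anchor_effect


@dataclass(frozen=True)
class AnionAnchors:
    """Calibration anchors for the anion-model constants.

    ``e_anion_base``: baseline permeability-weighted anion reversal (mV);
    ``dg_inh_star`` / ``di_star``: location (fractional) and size (%) of the
    maximal current increase along g_inh; optional ``kcc2_pair`` is a
    (dg_kcc2, dI %) point on the KCC2 axis.
    """

    e_anion_base: float = -65.0
    dg_inh_star: Optional[float] = 1.9
    di_star: Optional[float] = 26.0
    kcc2_pair: Optional[tuple[float, float]] = None


def calibrate_anion_constants(
    anchors: AnionAnchors, params: AnionParams = AnionParams()
) -> tuple[AnionParams, dict]:
    """Least-squares calibration of (x, E_K, E_HCO3) against printed anchors.

    ``v_mean``, ``v_eff`` and the baseline conductances stay fixed at their
    defaults.  Per-anchor residuals are always reported; with fewer active
    anchors than free constants the system is underdetermined and the
    report flags the rank deficiency instead of failing.  Infeasible anchor
    combinations (notably a ``di_star`` larger than the model can attain at
    the anchored stationary point) surface as nonzero residuals.
    """
    names = []
    if anchors.dg_inh_star is not None:
        names.append("dg_inh_star")
    if anchors.di_star is not None:
        names.append("di_star")
    if anchors.kcc2_pair is not None:
        names.append("kcc2_pair")
    names.insert(0, "e_anion_base")

    def build(theta):
        x, e_k, e_hco3 = theta
        return replace(params, x=x, e_k=e_k, e_hco3=e_hco3)

    def _closed_form_optimum(p):
        alpha, beta, m = current_polynomial_coefficients(p)
        if alpha >= 0:
            return 1e3, 1e3  # monotone current: far outside anchored region
        g_star = stationary_point_closed_form(alpha, beta, m)
        i_star = g_star * (alpha * g_star + beta) / (g_star + m)
        i_base = p.g_inh_base * (alpha * p.g_inh_base + beta) / (p.g_inh_base + m)
        return g_star / p.g_inh_base - 1.0, 100.0 * (i_star / i_base - 1.0)

    def residuals(theta):
        p = build(theta)
        res = []
        base = anion_current(p.g_inh_base, p.g_kcc2_base, p)
        res.append((base.e_anion - anchors.e_anion_base) / abs(anchors.e_anion_base))
        dg_star, di_star = _closed_form_optimum(p)
        if anchors.dg_inh_star is not None:
            res.append((dg_star - anchors.dg_inh_star) / anchors.dg_inh_star)
        if anchors.di_star is not None:
            res.append((di_star - anchors.di_star) / anchors.di_star)
        if anchors.kcc2_pair is not None:
            dg_k, di_k = anchors.kcc2_pair
            res.append((delta_anion_current(0.0, dg_k, p) - di_k) / abs(di_k))
        return np.asarray(res)

    theta0 = np.array([params.x, params.e_k, params.e_hco3])
    fit = least_squares(
        residuals,
        theta0,
        bounds=([0.05, -120.0, -40.0], [0.95, params.v_mean - 1.0, 0.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    fitted = build(fit.x)
    res = residuals(fit.x)
    rank = np.linalg.matrix_rank(fit.jac, tol=1e-8)
    report = {
        "residuals": dict(zip(names, res.tolist())),
        "cost": float(fit.cost),
        "underdetermined": bool(rank < 3),
        "jacobian_rank": int(rank),
        "fitted": {"x": fitted.x, "e_k": fitted.e_k, "e_hco3": fitted.e_hco3},
    }
    if anchors.dg_inh_star is not None:
        # the maximal relative current increase is fixed by the anchored
        # stationary point alone: with g* and baseline m it equals
        # I(g*)/I(1) - 1 for any alpha < 0 (beta is determined by g*)
        g_star = params.g_inh_base * (1.0 + anchors.dg_inh_star)
        m = params.g_kcc2_base
        beta_over_absalpha = (g_star**2 + 2.0 * m * g_star) / m
        i_star = g_star * (-g_star + beta_over_absalpha) / (g_star + m)
        i_base = (-1.0 + beta_over_absalpha) / (1.0 + m)
        report["attainable_di_star_pct"] = 100.0 * (i_star / i_base - 1.0)
    return fitted, report


@dataclass
class EffectorMap:
    """Invertible monotone dose->conductance maps for the two drugs.

    ``dg_inh(dose)`` maps a GABA_A-potentiator dose to the fractional
    increase in inhibitory conductance; ``dg_kcc2(dose)`` maps a KCC2
    enhancer dose to the fractional increase in extrusion strength.  Each
    map is the composition of the (offset-corrected) behavioral Hill curve,
    the inverse effect-current relation and the inverse single-effector
    current relation, and is valid only on the dose domain where every
    inversion exists.
    """

    dg_inh: Callable[[float], float]
    dg_kcc2: Callable[[float], float]
    inh_dose_max: float
    kcc2_dose_max: float
    dg_inh_max: float
    dg_kcc2_max: float
    di_of_dg_inh: Callable[[float], float]
    di_of_dg_kcc2: Callable[[float], float]
    dg_inh_of_di: Callable[[float], float]
    effect: EffectParams
    params: AnionParams


def _corrected_effect(dose: float, curve: HillParams, offset: float) -> float:
    return max(hill_response(dose, curve) - offset, 0.0)


def effector_maps(
    hill_inh: HillParams,
    hill_kcc2: HillParams,
    effect: EffectParams,
    params: AnionParams,
    dg_kcc2_cap: float = 50.0,
) -> EffectorMap:
    """Build the dose->effector maps from the single-drug behavioral curves.

    ``hill_inh`` is the dose-response of the GABA_A potentiator,
    ``hill_kcc2`` of the KCC2 enhancer; both on the raw % MPA scale (the
    no-drug offset stored in ``effect`` is subtracted here).  The g_inh
    branch is invertible only up to the collapse optimum; the KCC2 branch
    saturates, so it is capped at ``dg_kcc2_cap``.
    """
    dg_star, di_star = optimal_conductance(params)

    def di_inh(dg):
        return delta_anion_current(dg, 0.0, params)

    def di_kcc2(dg):
        return delta_anion_current(0.0, dg, params)

    di_inh_max = di_star
    di_kcc2_max = di_kcc2(dg_kcc2_cap)

    def dg_inh_of_di(di):
        if di < 0 or di > di_inh_max + 1e-12:
            raise ValueError(
                f"current increase {di:.3f}% outside the invertible g_inh range "
                f"[0, {di_inh_max:.3f}%]"
            )
        di = min(di, di_inh_max)
        if di == 0:
            return 0.0
        return brentq(lambda dg: di_inh(dg) - di, 0.0, dg_star, xtol=1e-9)

    def dg_kcc2_of_di(di):
        if di < 0 or di > di_kcc2_max + 1e-12:
            raise ValueError(
                f"current increase {di:.3f}% outside the attainable KCC2 range "
                f"[0, {di_kcc2_max:.3f}%]"
            )
        di = min(di, di_kcc2_max)
        if di == 0:
            return 0.0
        return brentq(lambda dg: di_kcc2(dg) - di, 0.0, dg_kcc2_cap, xtol=1e-9)

    def _dose_domain_max(curve: HillParams, di_max: float) -> float:
        """Largest dose whose corrected effect maps inside the current range."""
        effect_cap = effect_of_current(di_max, effect)
        top = curve.ymax - effect.offset
        if top <= effect_cap:  # whole curve invertible
            return math.inf
        # corrected Hill effect reaches effect_cap at a finite dose
        return brentq(
            lambda d: _corrected_effect(d, curve, effect.offset) - effect_cap,
            0.0,
            curve.ec50 * 1e6,
            xtol=1e-9,
        )

    inh_dose_max = _dose_domain_max(hill_inh, di_inh_max)
    kcc2_dose_max = _dose_domain_max(hill_kcc2, di_kcc2_max)

    def dg_inh(dose):
        if dose < 0 or dose > inh_dose_max:
            raise ValueError(
                f"dose {dose} outside the invertible domain [0, {inh_dose_max:.4g}]"
            )
        e = _corrected_effect(dose, hill_inh, effect.offset)
        return dg_inh_of_di(inverse_effect(e, effect))

    def dg_kcc2(dose):
        if dose < 0 or dose > kcc2_dose_max:
            raise ValueError(
                f"dose {dose} outside the invertible domain [0, {kcc2_dose_max:.4g}]"
            )
        e = _corrected_effect(dose, hill_kcc2, effect.offset)
        return dg_kcc2_of_di(inverse_effect(e, effect))

    return EffectorMap(
        dg_inh=dg_inh,
        dg_kcc2=dg_kcc2,
        inh_dose_max=inh_dose_max,
        kcc2_dose_max=kcc2_dose_max,
        dg_inh_max=dg_star,
        dg_kcc2_max=dg_kcc2_cap,
        di_of_dg_inh=di_inh,
        di_of_dg_kcc2=di_kcc2,
        dg_inh_of_di=dg_inh_of_di,
        effect=effect,
        params=params,
    )


def current_equivalent_dose(
    clp_dose: float, maps: EffectorMap, hill_inh: HillParams
) -> float:
    """KCC2-enhancer dose expressed as the potentiator dose of equal current.

    The KCC2-enhancer dose is mapped to its current increase, the g_inh
    current relation is inverted to the equivalent conductance increase,
    and the potentiator dose-response (offset-corrected) is inverted to a
    dose.  An image outside the invertible range raises with the bounding
    dose in the message.
    """
    if clp_dose == 0:
        return 0.0
    di = maps.di_of_dg_kcc2(maps.dg_kcc2(clp_dose))
    dg_eq = maps.dg_inh_of_di(di)  # raises if beyond the collapse optimum
    target = effect_of_current(maps.di_of_dg_inh(dg_eq), maps.effect)
    top = hill_inh.ymax - maps.effect.offset
    if target >= top:
        raise ValueError(
            f"equivalent effect {target:.2f}% exceeds the potentiator curve "
            f"ceiling {top:.2f}% (bounding dose {maps.inh_dose_max:.4g})"
        )
    return brentq(
        lambda d: _corrected_effect(d, hill_inh, maps.effect.offset) - target,
        0.0,
        hill_inh.ec50 * 1e6,
        xtol=1e-9,
    )


def combination_surfaces(
    inh_doses: Sequence[float],
    kcc2_doses: Sequence[float],
    maps: EffectorMap,
    hill_inh: HillParams,
):
    """Common-effector and distinct-effector combination effect surfaces.

    Returns two arrays of shape (len(inh_doses), len(kcc2_doses)) holding
    the offset-corrected effect (%) under each assumption.  Grid points
    where an inversion leaves its domain are NaN (masked, never
    extrapolated).
    """
    inh_doses = np.asarray(inh_doses, dtype=float)
    kcc2_doses = np.asarray(kcc2_doses, dtype=float)
    common = np.full((inh_doses.size, kcc2_doses.size), np.nan)
    distinct = np.full_like(common, np.nan)
    for j, c in enumerate(kcc2_doses):
        try:
            dose_eq = current_equivalent_dose(c, maps, hill_inh)
            dg_k = maps.dg_kcc2(c)
        except ValueError:
            continue
        for i, a in enumerate(inh_doses):
            try:
                dg_total = maps.dg_inh(a + dose_eq)
                common[i, j] = effect_of_current(
                    maps.di_of_dg_inh(dg_total), maps.effect
                )
            except ValueError:
                pass
            try:
                di = delta_anion_current(maps.dg_inh(a), dg_k, maps.params)
                distinct[i, j] = effect_of_current(di, maps.effect)
            except ValueError:
                pass
    return common, distinct


def kcc2_flux(e_cl: float, e_k: float, u_kcc2: float) -> tuple[float, float]:
    """Cl- flux through KCC2 and the equivalent current.

    ``J = U_KCC2 * (E_Cl - E_K)`` in mol/s (potentials in mV are converted
    to volts); the current is ``F * J`` in amperes.
    """
    if u_kcc2 < 0:
        raise ValueError("u_kcc2 must be >= 0")
    flux = u_kcc2 * (e_cl - e_k) / 1000.0
    return flux, FARADAY * flux
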
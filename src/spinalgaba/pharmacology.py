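"""Behavioral dose-response statistics for analgesia studies.

Withdrawal thresholds (WD50, grams of von Frey force) are normalized to
maximum possible analgesia (MPA):

    %MPA(t) = 100 * (WD50(t) - WD50(predrug)) / (WD50(prePNI) - WD50(predrug))

Dose-response curves of %MPA are fitted with the four-parameter Hill
equation, optionally multiplied by an inverse sigmoid describing the
collapse of analgesia at high doses.  Loewe dose-equivalence converts a
dose of one drug into the equally effective dose of another, from which
additive combination responses, isobolograms and the A50 combination
point follow; comparing an observed combination effect with the additive
expectation classifies the interaction as synergistic, additive or
antagonistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "WithdrawalSeries",
    "HillParams",
    "CollapseParams",
    "ComboDesign",
    "IsoboleResult",
    "EScore",
    "L838_HILL",
    "CLP257_HILL",
    "compute_mpa",
    "hill_response",
    "collapse_factor",
    "hill_collapse_response",
    "fit_hill",
    "fit_hill_collapse",
    "dose_equivalent",
    "additive_response",
    "classify_interaction",
    "isobole_a50",
    "escore",
]


@dataclass(frozen=True)
class HillParams:
    """Four-parameter Hill dose-response: y0, ymax (% MPA), slope h, ec50."""

    y0: float
    ymax: float
    h: float
    ec50: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.ymax < self.y0:
            raise ValueError("ymax must be >= y0")


@dataclass(frozen=True)
class CollapseParams:
    """High-dose collapse: half-collapse dose c50 and slope h_col."""

    c50: float
    h_col: float

    def __post_init__(self) -> None:
        if self.c50 <= 0 or self.h_col <= 0:
            raise ValueError("c50 and h_col must be > 0")


#: In-vivo fit of the GABA_A potentiator L838,417 (EC50 0.43 mg/kg,
#: MPA 31.2%, ~6% vehicle offset; slope not printed, taken as 1).
L838_HILL = HillParams(y0=6.0, ymax=31.2, h=1.0, ec50=0.43)
#: In-vivo fit of the KCC2 enhancer CLP257 (EC50 29.4 mg/kg, MPA 22.9%).
CLP257_HILL = HillParams(y0=6.0, ymax=22.9, h=1.0, ec50=29.4)


@dataclass
class WithdrawalSeries:
    """Per-animal WD50 thresholds (g) over timepoints, with baselines."""

    wd50: np.ndarray  # grams, any shape (e.g. timepoints or animals x timepoints)
    wd50_predrug: float
    wd50_prepni: float

    def __post_init__(self) -> None:
        self.wd50 = np.asarray(self.wd50, dtype=float)
        if self.wd50_prepni == self.wd50_predrug:
            raise ValueError("prePNI and predrug thresholds must differ")


@dataclass(frozen=True)
class ComboDesign:
    """Fixed-ratio combination design: dose_b = ratio_b_over_a * dose_a."""

    ratio_b_over_a: float

    def __post_init__(self) -> None:
        if self.ratio_b_over_a <= 0:
            raise ValueError("ratio must be > 0")


@dataclass
class IsoboleResult:
    curve_a: np.ndarray
    curve_b: np.ndarray
    a50_theoretical: tuple[float, float]
    a50_observed: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class EScore:
    """Cold-stimulus behavioral score: five per-application ratings in {0,1,2}."""

    ratings: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.ratings)


def compute_mpa(series: WithdrawalSeries, clip: bool = False) -> np.ndarray:
    """Maximum possible analgesia (%) from withdrawal thresholds.

    Unclipped by default: values below 0 (drug-worsening) or above 100 are
    meaningful and reported as-is; ``clip=True`` gives the [0, 100] view.
    """
    mpa = (
        100.0
        * (series.wd50 - series.wd50_predrug)
        / (series.wd50_prepni - series.wd50_predrug)
    )
    return np.clip(mpa, 0.0, 100.0) if clip else mpa


def hill_response(dose, params: HillParams):
    """Hill curve Y([X]) = Y0 + (Ymax - Y0) * [X]^H / ([X]^H + EC50^H)."""
    x = np.asarray(dose, dtype=float)
    xh = np.power(x, params.h, where=x > 0, out=np.zeros_like(x))
    y = params.y0 + (params.ymax - params.y0) * xh / (xh + params.ec50**params.h)
    return float(y) if np.isscalar(dose) else y


def collapse_factor(dose, params: CollapseParams):
    """Inverse sigmoid C50^H / ([X]^H + C50^H): 1 at zero dose, 1/2 at C50."""
    x = np.asarray(dose, dtype=float)
    c = params.c50**params.h_col
    out = c / (np.power(x, params.h_col, where=x > 0, out=np.zeros_like(x)) + c)
    return float(out) if np.isscalar(dose) else out


def hill_collapse_response(dose, hill: HillParams, collapse: CollapseParams):
    """Product model: Hill response times the high-dose collapse factor."""
    return hill_response(dose, hill) * collapse_factor(dose, collapse)


def _hill_start(doses: np.ndarray, responses: np.ndarray) -> tuple:
    positive = doses[doses > 0]
    ec50_0 = float(np.exp(np.median(np.log(positive)))) if positive.size else 1.0
    return float(responses.min()), float(responses.max()), 1.0, ec50_0


def fit_hill(
    doses: Sequence[float],
    responses: Sequence[float],
    exclude: Optional[Sequence[float]] = None,
    bounds: Optional[tuple] = None,
) -> tuple[HillParams, dict]:
    """Nonlinear least-squares fit of the four-parameter Hill equation.

    ``exclude`` drops listed doses before fitting (used when a high-dose
    point is known to collapse and would bias a plain Hill fit).  Returns
    fitted parameters plus diagnostics: standard errors, residuals, and
    the starting values used.  Needs >= 4 distinct doses after exclusion.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if exclude is not None:
        keep = ~np.isin(d, np.asarray(exclude, dtype=float))
        d, r = d[keep], r[keep]
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct doses after exclusion")
    p0 = _hill_start(d, r)
    if bounds is None:
        bounds = ((-100.0, -100.0, 0.1, 1e-6), (200.0, 200.0, 10.0, 1e4))

    def model(x, y0, ymax, h, ec50):
        return hill_response(x, HillParams(y0, max(ymax, y0), h, ec50))

    try:
        popt, pcov = curve_fit(model, d, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Hill fit did not converge (starting values {p0}): {err}"
        ) from err
    params = HillParams(popt[0], max(popt[1], popt[0]), popt[2], popt[3])
    resid = r - model(d, *popt)
    stderr = np.sqrt(np.diag(pcov))
    diagnostics = {
        "stderr": dict(zip(("y0", "ymax", "h", "ec50"), stderr.tolist())),
        "residuals": resid,
        "rss": float(resid @ resid),
        "start": p0,
        "n_points": int(d.size),
    }
    return params, diagnostics


def fit_hill_collapse(
    doses: Sequence[float],
    responses: Sequence[float],
    fixed_ymax: float,
) -> tuple[HillParams, CollapseParams, dict]:
    """Fit the Hill-times-collapse product model with a fixed amplitude.

    The amplitude (Ymax) is pinned to an independently measured
    non-collapsing maximum; free parameters are Y0, H, EC50 and the
    collapse C50, H_col.  A dataset with no high-dose decline leaves the
    collapse non-identifiable; this is flagged in the diagnostics (the
    fitted C50 escapes past the largest dose) rather than silently
    accepted.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.unique(d).size < 5:
        raise ValueError("need at least 5 distinct doses")
    dmax = float(d.max())

    def model(x, y0, h, ec50, c50, h_col):
        return hill_collapse_response(
            x, HillParams(y0, fixed_ymax, h, ec50), CollapseParams(c50, h_col)
        )

    p0 = (float(r.min()), 1.0, float(np.exp(np.median(np.log(d[d > 0])))), dmax, 2.0)
    bounds = (
        (-100.0, 0.1, 1e-6, 1e-6, 0.1),
        (fixed_ymax, 10.0, 1e4, 1e6, 10.0),
    )
    popt, pcov = curve_fit(model, d, r, p0=p0, bounds=bounds, maxfev=40000)
    hill = HillParams(popt[0], fixed_ymax, popt[1], popt[2])
    collapse = CollapseParams(popt[3], popt[4])
    resid = r - model(d, *popt)
    diagnostics = {
        "stderr": dict(
            zip(("y0", "h", "ec50", "c50", "h_col"), np.sqrt(np.diag(pcov)).tolist())
        ),
        "residuals": resid,
        "rss": float(resid @ resid),
        "collapse_identifiable": bool(collapse.c50 < 10.0 * dmax),
    }
    return hill, collapse, diagnostics


def dose_equivalent(b_dose: float, params_a: HillParams, params_b: HillParams) -> float:
    """Dose of drug a producing the same effect as ``b_dose`` of drug b.

    Closed-form Loewe dose equivalence for two Hill curves sharing Y0,
    valid when Ymax_a >= Ymax_b (drug a can always match drug b's effect).
    """
    if params_a.ymax < params_b.ymax:
        raise ValueError("requires ymax_a >= ymax_b (reference drug is stronger)")
    if b_dose < 0:
        raise ValueError("dose must be >= 0")
    if b_dose == 0:
        return 0.0
    ea = params_a.ymax - params_a.y0
    eb = params_b.ymax - params_b.y0
    bh = b_dose**params_b.h
    num = params_a.ec50**params_a.h * eb * bh
    den = ea * params_b.ec50**params_b.h - eb * bh + ea * bh
    if den <= 0:
        raise ValueError("b effect exceeds drug a's attainable range")
    return (num / den) ** (1.0 / params_a.h)


def additive_response(
    a_dose: float, b_dose: float, params_a: HillParams, params_b: HillParams
) -> float:
    """Loewe-additive combination effect: Y_a(a + a_eq(b))."""
    return hill_response(a_dose + dose_equivalent(b_dose, params_a, params_b), params_a)


def classify_interaction(observed: float, expected: float, uncertainty: float) -> str:
    """Synergistic / additive / antagonistic by the sign of (observed - expected).

    The difference must exceed the stated uncertainty band (e.g. the
    standard error of the observed mean) to leave the additive class.
    """
    if uncertainty < 0:
        raise ValueError("uncertainty must be >= 0")
    diff = observed - expected
    if diff > uncertainty:
        return "synergistic"
    if diff < -uncertainty:
        return "antagonistic"
    return "additive"


def isobole_a50(
    params_a: HillParams,
    params_b: HillParams,
    design: ComboDesign,
    n_points: int = 101,
    observed_combo: Optional[HillParams] = None,
) -> IsoboleResult:
    """Additivity isobole at drug a's half-maximal effect, and the A50.

    The isobole is the set of (a, b) pairs with ``a + a_eq(b) = EC50_a``,
    traced by root-finding over b for each a in [0, EC50_a].  The
    theoretical A50 is its intersection with the fixed-ratio ray
    ``b = ratio * a``; the observed A50, if a combination dose-response
    fit is supplied, is the mixture on the ray whose fitted effect equals
    drug a's half-maximal effect (doses expressed in drug-a units on the
    ray).
    """
    ec50_a = params_a.ec50
    target = hill_response(ec50_a, params_a)  # (y0 + ymax_a) / 2
    a_grid = np.linspace(0.0, ec50_a, n_points)

    def b_for(a):
        need = ec50_a - a
        if need <= 0:
            return 0.0
        f = lambda b: dose_equivalent(b, params_a, params_b) - need
        b_hi = params_b.ec50
        for _ in range(200):
            try:
                val = f(b_hi)
            except ValueError:  # beyond drug b's range: no finite b
                return np.nan
            if val >= 0:
                return brentq(f, 0.0, b_hi, xtol=1e-12)
            b_hi *= 2.0
        return np.nan

    curve_b = np.array([b_for(a) for a in a_grid])

    def ray_gap(a):
        return a + dose_equivalent(design.ratio_b_over_a * a, params_a, params_b) - ec50_a

    if ray_gap(ec50_a) < 0:
        raise ValueError("fixed-ratio ray does not reach the isobole")
    a50_a = brentq(ray_gap, 0.0, ec50_a, xtol=1e-12)
    a50 = (a50_a, design.ratio_b_over_a * a50_a)

    observed = None
    if observed_combo is not None:
        if target >= observed_combo.ymax:
            raise ValueError("combination fit never reaches drug a's half effect")
        a_obs = brentq(
            lambda a: hill_response(a, observed_combo) - target,
            1e-12,
            observed_combo.ec50 * 1e6,
            xtol=1e-12,
        )
        observed = (a_obs, design.ratio_b_over_a * a_obs)
    return IsoboleResult(
        curve_a=a_grid, curve_b=curve_b, a50_theoretical=a50, a50_observed=observed
    )


def escore(ratings: Sequence[int]) -> EScore:
    """Sum five cold-stimulus response ratings (each 0, 1 or 2) into 0-10."""
    if len(ratings) != 5:
        raise ValueError("exactly five ratings required")
    for r in ratings:
        if r not in (0, 1, 2):
            raise ValueError(f"rating {r} not in {{0, 1, 2}}")
    return EScore(ratings=tuple(int(r) for r in ratings))
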
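"""Biochemical analysis: catalytic efficiencies, double-mutant cycles, stability.

The central quantity is the catalytic efficiency k_cat/K_M of a phosphatase
variant against a fluorogenic substrate. Variant effects compose
multiplicatively, so replicate efficiencies are averaged geometrically and
compared as ratios (fold changes). A double-mutant cycle over four variants
(WT, two singles, the double) measures energetic coupling between two
positions as the deviation of the double mutant's effect from log-additivity:

    Ω = (v_WT · v_12) / (v_1 · v_2),      ΔΔG_int = −RT ln Ω

with Ω = 1 (ΔΔG_int = 0) when the two substitutions act independently.
Thermal stability enters through DSF melt curves, whose midpoint T_m is
extracted by a Boltzmann-sigmoid fit or the maximum of the smoothed
derivative; pull-down band intensities are double-normalized (IP/TCL, then to
the wild-type sample).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.signal import savgol_filter

from domainmotion.errors import (
    CycleError,
    DimensionError,
    DomainMotionError,
    FitError,
    NoTransitionError,
    StatisticsError,
)

#: Gas constant in kcal/(mol·K)
R_KCAL = 1.987204258640832e-3

_SUBSTITUTION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class VariantLabel:
    """A set of point substitutions; the empty set denotes wild type."""

    substitutions: frozenset[tuple[str, int, str]] = frozenset()

    def __post_init__(self) -> None:
        positions = [p for _, p, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise DomainMotionError(f"multiple substitutions at one position: {self}")

    @classmethod
    def parse(cls, text: str) -> "VariantLabel":
        """Parse e.g. ``"R4A+R5A+E139D"``; ``"WT"`` (any case) is wild type."""
        text = text.strip()
        if text.upper() in ("WT", "WILD-TYPE", "WILDTYPE", ""):
            return cls()
        subs = set()
        for token in text.split("+"):
            m = _SUBSTITUTION_RE.match(token.strip())
            if not m:
                raise DomainMotionError(f"cannot parse substitution {token!r}")
            subs.add((m.group(1), int(m.group(2)), m.group(3)))
        return cls(frozenset(subs))

    def __str__(self) -> str:
        if not self.substitutions:
            return "WT"
        ordered = sorted(self.substitutions, key=lambda s: s[1])
        return "+".join(f"{wt}{pos}{mut}" for wt, pos, mut in ordered)

    def __or__(self, other: "VariantLabel") -> "VariantLabel":
        return VariantLabel(self.substitutions | other.substitutions)


@dataclass
class ActivityRecord:
    """Replicate catalytic efficiencies (k_cat/K_M) for one variant."""

    variant: VariantLabel
    replicate_efficiencies: list[float]

    def __post_init__(self) -> None:
        values = [float(v) for v in self.replicate_efficiencies]
        if not values:
            raise DomainMotionError(f"{self.variant}: no replicates")
        if any(v <= 0 for v in values):
            raise DomainMotionError(f"{self.variant}: efficiencies must be positive")
        self.replicate_efficiencies = values

    @property
    def log_values(self) -> np.ndarray:
        return np.log(np.asarray(self.replicate_efficiencies))

    @property
    def geometric_mean(self) -> float:
        return float(np.exp(self.log_values.mean()))

    @property
    def arithmetic_mean(self) -> float:
        return float(np.mean(self.replicate_efficiencies))

    @property
    def log_sem(self) -> float:
        """Standard error of the mean log efficiency (0 for a single replicate)."""
        n = len(self.replicate_efficiencies)
        if n < 2:
            return 0.0
        return float(self.log_values.std(ddof=1) / math.sqrt(n))


@dataclass
class FoldChange:
    """Ratio of two variants' efficiencies with the SE of its natural log."""

    numerator_variant: VariantLabel
    denominator_variant: VariantLabel
    ratio: float
    log_se: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise DomainMotionError("fold-change ratio must be positive")


@dataclass
class CouplingResult:
    """Double-mutant-cycle coupling coefficient and interaction free energy."""

    omega: float
    delta_delta_g_interaction: float  # kcal/mol
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        expected = -R_KCAL * self.temperature_K * math.log(self.omega)
        if abs(expected - self.delta_delta_g_interaction) > 1e-9:
            raise DomainMotionError("delta_delta_g_interaction inconsistent with omega")


@dataclass
class MeltCurve:
    """A DSF fluorescence-vs-temperature trace, optionally with an extracted T_m."""

    temperatures: np.ndarray  # °C, strictly increasing
    signal: np.ndarray  # arbitrary fluorescence units
    tm: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.shape != self.signal.shape:
            raise DimensionError("temperatures and signal must have equal length")
        if self.temperatures.size < 10:
            raise DomainMotionError("melt curve needs >= 10 points spanning the transition")
        if not np.all(np.diff(self.temperatures) > 0):
            raise DomainMotionError("temperatures must be strictly increasing")


# ---------------------------------------------------------------------------
# Kinetics


def michaelis_menten_rate(s, k_cat: float, k_m: float, enzyme_concentration: float):
    """v = k_cat · [E] · [S] / (K_M + [S])."""
    s = np.asarray(s, dtype=float)
    return k_cat * enzyme_concentration * s / (k_m + s)


@dataclass
class KineticsFit:
    k_cat: float | None
    k_m: float | None
    efficiency: float  # k_cat / K_M
    k_cat_se: float | None
    k_m_se: float | None
    efficiency_se: float | None
    saturating: bool  # False -> linear sub-K_M regime fallback, efficiency only
    span_flag: bool  # True when [S] range poorly brackets the fitted K_M


def fit_michaelis_menten(
    substrate_concentrations: Sequence[float],
    initial_rates: Sequence[float],
    enzyme_concentration: float,
) -> KineticsFit:
    """Nonlinear least-squares fit of the Michaelis–Menten rate law.

    Returns k_cat, K_M and the efficiency k_cat/K_M with standard errors.
    When the data never approach saturation (all [S] well below the fitted
    K_M), k_cat and K_M are individually unidentifiable; the fit falls back
    to the linear regime v = (k_cat·[E]/K_M)·[S] and reports the efficiency
    only, with ``saturating=False``.
    """
    s = np.asarray(substrate_concentrations, dtype=float)
    v = np.asarray(initial_rates, dtype=float)
    if s.shape != v.shape:
        raise DimensionError("concentration and rate arrays must have equal length")
    if s.size < 5:
        raise FitError("need at least 5 concentration points")
    if np.any(v < 0) or np.any(s <= 0):
        raise FitError("rates must be >= 0 and concentrations > 0")
    if enzyme_concentration <= 0:
        raise FitError("enzyme concentration must be positive")

    vmax0 = float(v.max()) or 1.0
    km0 = float(np.median(s))
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, kcat, km: michaelis_menten_rate(x, kcat, km, enzyme_concentration),
            s,
            v,
            p0=[vmax0 / enzyme_concentration, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        k_cat, k_m = (float(p) for p in popt)
        converged = np.all(np.isfinite(pcov)) and k_cat > 0 and k_m > 0
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc

    sub_km_only = converged and s.max() < k_m / 5.0
    if not converged or sub_km_only:
        # Linear regime: slope through the origin estimates k_cat·[E]/K_M.
        slope = float(np.sum(s * v) / np.sum(s * s))
        resid = v - slope * s
        dof = max(s.size - 1, 1)
        slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(s * s)))
        eff = slope / enzyme_concentration
        return KineticsFit(
            k_cat=None,
            k_m=None,
            efficiency=eff,
            k_cat_se=None,
            k_m_se=None,
            efficiency_se=slope_se / enzyme_concentration,
            saturating=False,
            span_flag=True,
        )

    perr = np.sqrt(np.diag(pcov))
    k_cat_se, k_m_se = float(perr[0]), float(perr[1])
    cov_kcat_km = float(pcov[0, 1])
    eff = k_cat / k_m
    # Delta method for the SE of the ratio k_cat/K_M.
    eff_var = (
        (k_cat_se / k_m) ** 2
        + (k_cat * k_m_se / k_m**2) ** 2
        - 2.0 * k_cat / k_m**3 * cov_kcat_km
    )
    eff_se = float(np.sqrt(max(eff_var, 0.0)))
    span_flag = not (s.min() < k_m < s.max())
    return KineticsFit(
        k_cat=k_cat,
        k_m=k_m,
        efficiency=eff,
        k_cat_se=k_cat_se,
        k_m_se=k_m_se,
        efficiency_se=eff_se,
        saturating=True,
        span_flag=span_flag,
    )


# ---------------------------------------------------------------------------
# Fold changes and mutant cycles


def fold_change(a: ActivityRecord, b: ActivityRecord, mean: str = "geometric") -> FoldChange:
    """Fold change of a over b: ratio of mean replicate efficiencies.

    The default geometric mean matches the multiplicative composition of
    activity effects; ``mean="arithmetic"`` is available for cross-checking
    against ratios of plain means. The SE of the log ratio propagates the two
    per-group standard errors of the mean log efficiency.
    """
    if mean == "geometric":
        ratio = a.geometric_mean / b.geometric_mean
    elif mean == "arithmetic":
        ratio = a.arithmetic_mean / b.arithmetic_mean
    else:
        raise DomainMotionError(f"unknown mean convention {mean!r}")
    log_se = math.sqrt(a.log_sem**2 + b.log_sem**2)
    return FoldChange(
        numerator_variant=a.variant,
        denominator_variant=b.variant,
        ratio=float(ratio),
        log_se=float(log_se),
    )


def mutant_cycle(
    wt: ActivityRecord,
    single1: ActivityRecord,
    single2: ActivityRecord,
    double: ActivityRecord,
    temperature_K: float = 298.15,
) -> CouplingResult:
    """Double-mutant-cycle coupling between two substitutions.

    The four variants must form a closed cycle: each single differs from the
    ``wt`` background by its own substitutions, and the double carries exactly
    the union. Ω and ΔΔG_int are invariant under swapping the two singles and
    under rescaling all activities by a common positive constant.
    """
    base = wt.variant.substitutions
    sub1 = single1.variant.substitutions - base
    sub2 = single2.variant.substitutions - base
    if not sub1 or not sub2:
        raise CycleError(
            f"singles must add substitutions to the background {wt.variant}: "
            f"got {single1.variant}, {single2.variant}"
        )
    if single1.variant.substitutions != base | sub1 or single2.variant.substitutions != base | sub2:
        raise CycleError("single mutants must contain the background substitutions")
    if sub1 & sub2:
        raise CycleError(f"singles share substitutions: {sub1 & sub2}")
    expected_double = base | sub1 | sub2
    if double.variant.substitutions != expected_double:
        raise CycleError(
            f"double mutant {double.variant} does not close the cycle; "
            f"expected {VariantLabel(frozenset(expected_double))}"
        )
    omega = (wt.geometric_mean * double.geometric_mean) / (
        single1.geometric_mean * single2.geometric_mean
    )
    ddg = -R_KCAL * temperature_K * math.log(omega)
    return CouplingResult(
        omega=float(omega),
        delta_delta_g_interaction=float(ddg),
        temperature_K=temperature_K,
    )


def background_effect_ratio(
    effect_in_background: FoldChange, effect_in_reference: FoldChange
) -> tuple[float, str]:
    """How much a substitution's effect changes between two backgrounds.

    Both fold changes must describe the same substitution (numerator minus
    denominator substitution sets agree). Returns (ratio ≥ 1, direction) where
    direction is ``"enhanced"`` if the effect is larger in the background of
    interest, ``"attenuated"`` if smaller, ``"unchanged"`` at equality.
    """
    delta_bg = (
        effect_in_background.numerator_variant.substitutions
        ^ effect_in_background.denominator_variant.substitutions
    )
    delta_ref = (
        effect_in_reference.numerator_variant.substitutions
        ^ effect_in_reference.denominator_variant.substitutions
    )
    if delta_bg != delta_ref:
        raise DomainMotionError(
            "fold changes describe different substitutions: "
            f"{sorted(delta_bg)} vs {sorted(delta_ref)}"
        )
    raw = effect_in_background.ratio / effect_in_reference.ratio
    ratio = float(raw) if raw >= 1.0 else float(1.0 / raw)
    # Direction compares effect *magnitudes* in log space, so an amplified
    # reduction (ratio < 1 moving further from 1) counts as enhanced.
    mag_bg = abs(math.log(effect_in_background.ratio))
    mag_ref = abs(math.log(effect_in_reference.ratio))
    if math.isclose(mag_bg, mag_ref, rel_tol=1e-12, abs_tol=1e-12):
        return ratio, "unchanged"
    return ratio, "enhanced" if mag_bg > mag_ref else "attenuated"


# ---------------------------------------------------------------------------
# Statistics


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float], log_transform: bool = True
) -> tuple[float, float, float]:
    """Welch's unequal-variance two-tailed t test.

    Returns (t statistic, Welch–Satterthwaite degrees of freedom, two-tailed
    p). ``log_transform`` (default on) tests natural-log values, matching the
    ratio scale of catalytic efficiencies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError("each group needs at least 2 values")
    if log_transform:
        if np.any(a <= 0) or np.any(b <= 0):
            raise StatisticsError("log transform requires positive values")
        a = np.log(a)
        b = np.log(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise StatisticsError("both groups have zero variance")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


def significance_stars(p: float) -> str:
    """Conventional star annotation: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Melt curves


def boltzmann_sigmoid(t, baseline: float, amplitude: float, tm: float, slope: float):
    """Four-parameter sigmoid: baseline + amplitude / (1 + exp((tm − t)/slope))."""
    t = np.asarray(t, dtype=float)
    return baseline + amplitude / (1.0 + np.exp((tm - t) / slope))


def _derivative_tm(curve: MeltCurve) -> tuple[float, float, float]:
    """(tm, peak derivative, derivative noise scale) from the smoothed dF/dT."""
    n = curve.signal.size
    window = min(11, n if n % 2 == 1 else n - 1)
    smoothed = savgol_filter(curve.signal, window_length=window, polyorder=3)
    dfdt = np.gradient(smoothed, curve.temperatures)
    magnitude = np.abs(dfdt)
    k = int(np.argmax(magnitude))
    peak = float(magnitude[k])
    noise = float(np.median(magnitude) + 1e-30)
    # parabolic interpolation around the grid maximum
    if 0 < k < n - 1:
        y0, y1, y2 = magnitude[k - 1 : k + 2]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        shift = float(np.clip(shift, -1.0, 1.0))
        step = curve.temperatures[k + 1] - curve.temperatures[k] if shift >= 0 else (
            curve.temperatures[k] - curve.temperatures[k - 1]
        )
        tm = float(curve.temperatures[k] + shift * abs(step))
    else:
        tm = float(curve.temperatures[k])
    return tm, peak, noise


def melt_temperature(
    curve: MeltCurve, method: str = "boltzmann-fit", transition_factor: float = 5.0
) -> float:
    """Extract the melting temperature (°C) from a DSF curve.

    ``method="boltzmann-fit"`` (default) returns the midpoint of a
    four-parameter sigmoid fit; ``"derivative-max"`` the temperature of the
    maximum of the smoothed |dF/dT| (with parabolic refinement). A curve whose
    derivative peak does not exceed ``transition_factor`` times the median
    derivative magnitude is rejected as transition-free.
    """
    signal_range = float(np.ptp(curve.signal))
    if signal_range <= 1e-9 * max(1.0, float(np.abs(curve.signal).max())):
        raise NoTransitionError("melt curve is flat")
    tm_deriv, peak, noise = _derivative_tm(curve)
    if peak < transition_factor * noise or peak <= 0:
        raise NoTransitionError("no unfolding transition detected in melt curve")
    if method == "derivative-max":
        return tm_deriv
    if method != "boltzmann-fit":
        raise DomainMotionError(f"unknown method {method!r}")
    t = curve.temperatures
    f = curve.signal
    amp0 = float(f.max() - f.min())
    sign = 1.0 if f[-1] >= f[0] else -1.0
    p0 = [float(f.min() if sign > 0 else f.max()), sign * amp0, tm_deriv, 1.0]
    try:
        popt, _ = optimize.curve_fit(boltzmann_sigmoid, t, f, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    tm = float(popt[2])
    if not (t.min() - 5.0 <= tm <= t.max() + 5.0):
        raise FitError(f"fitted T_m {tm:.1f} °C lies outside the measured range")
    return tm


# ---------------------------------------------------------------------------
# Co-IP quantification


def coip_normalize(
    interactor_ip: float, interactor_tcl: float, wt_ip: float, wt_tcl: float
) -> float:
    """Relative phosphoprotein binding from co-IP band intensities.

    Interactor signal in the immunoprecipitate is normalized to its
    total-cell-lysate level, then rescaled to the wild-type sample:
    (IP/TCL) / (IP_WT/TCL_WT). The wild-type sample maps to exactly 1.0.
    """
    values = (interactor_ip, interactor_tcl, wt_ip, wt_tcl)
    if any(v <= 0 for v in values):
        raise DomainMotionError("band intensities must be positive")
    return float((interactor_ip / interactor_tcl) / (wt_ip / wt_tcl))
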
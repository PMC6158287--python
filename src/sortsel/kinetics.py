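"""Slow tight-binding inhibition kinetics and the Ki selectivity algebra.

Tight-binding inhibitors of serine proteases are characterized by progress
curves in which the velocity relaxes slowly from an initial v0 to a
steady-state vs:

    P(t) = baseline + vs*t + (v0 - vs) * (1 - exp(-kobs*t)) / kobs

The steady-state velocities across an inhibitor titration follow the
Morrison quadratic (no free-inhibitor approximation, valid when [I] ~ [E]):

    vs/v0 = 1 - ((E + I + Ki_app) - sqrt((E + I + Ki_app)^2 - 4*E*I)) / (2*E)

with the competitive-substrate correction Ki = Ki_app / (1 + S/Km).

On top of the fitted Ki values sits the selectivity algebra used to compare
mutants of an inhibitor scaffold across targets: parent-normalized
calculated selectivity, products over competitor targets (total
selectivity), the expected selectivity of a double mutant as the product of
its single mutants, Ki fold-change switch ratios, and the double-mutant
cycle coupling energy ddG_int = -RT ln(S_AB / (S_A * S_B)), which is zero
exactly when the two mutations act multiplicatively (additively in free
energy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ProgressCurve",
    "TightBindingFit",
    "KiEstimate",
    "fit_progress_curve",
    "morrison_vs",
    "morrison_fit",
    "calculated_selectivity",
    "expected_double_selectivity",
    "switch_ratio",
    "coupling_energy",
    "selectivity_report",
    "load_reference_ki_table",
    "GAS_CONSTANT_KCAL",
]

#: gas constant in kcal/(mol*K)
GAS_CONSTANT_KCAL = 1.987e-3


@dataclass(frozen=True)
class ProgressCurve:
    """One product-formation time course at fixed [E], [I], [S]."""

    t: np.ndarray
    signal: np.ndarray
    enzyme: float  # [E], same concentration unit as inhibitor (pM here)
    inhibitor: float  # [I]
    substrate: float  # [S], same unit as km
    km: float
    curve_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if len(t) != len(self.signal):
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if min(self.enzyme, self.substrate, self.km) <= 0 or self.inhibitor < 0:
            raise ValueError("concentrations must be positive ([I] may be zero)")


@dataclass
class TightBindingFit:
    """Parameters of one slow-binding progress curve."""

    v0: float
    vs: float
    kobs: float
    baseline: float
    residual_rms: float
    converged: bool = True
    kobs_identifiable: bool = True


def _progress_model(t: np.ndarray, baseline: float, v0: float, vs: float,
                    kobs: float) -> np.ndarray:
    return baseline + vs * t + (v0 - vs) * (1.0 - np.exp(-kobs * t)) / kobs


def _progress_model_frac(t: np.ndarray, baseline: float, v0: float, frac: float,
                         kobs: float) -> np.ndarray:
    # vs = frac * v0 with frac in [0, 1]: enforces vs <= v0 (an inhibitor can
    # only slow the reaction), which keeps straight-line curves well-behaved
    return _progress_model(t, baseline, v0, frac * v0, kobs)


def fit_progress_curve(curve: ProgressCurve) -> TightBindingFit:
    """Nonlinear least-squares fit of the slow-binding progress curve.

    Initialized from early/late finite-difference slopes. When the curve is
    indistinguishable from a straight line (v0 ~ vs), kobs is flagged
    unidentifiable and the slope is reported as both v0 and vs.
    """
    t = np.asarray(curve.t, dtype=float)
    y = np.asarray(curve.signal, dtype=float)
    if len(t) < 10:
        raise ValueError("progress-curve fit needs at least 10 time points")

    n_edge = max(3, len(t) // 5)
    v0_init = float(np.polyfit(t[:n_edge], y[:n_edge], 1)[0])
    vs_init = float(np.polyfit(t[-n_edge:], y[-n_edge:], 1)[0])
    kobs_init = 3.0 / (t[-1] - t[0])
    span = max(abs(v0_init), abs(vs_init), 1e-12)

    # straight line: kobs has no leverage
    line_slope, line_icpt = np.polyfit(t, y, 1)
    line_rms = float(np.sqrt(np.mean((y - (line_slope * t + line_icpt)) ** 2)))
    if abs(v0_init - vs_init) < 1e-6 * span:
        return TightBindingFit(
            v0=float(line_slope), vs=float(line_slope), kobs=kobs_init,
            baseline=float(line_icpt), residual_rms=line_rms,
            kobs_identifiable=False,
        )

    # fit in normalized units so tolerances are scale-free
    t_scale = t[-1] - t[0]
    y_scale = max(float(np.ptp(y)), 1e-12)
    tn = (t - t[0]) / t_scale
    yn = (y - y[0]) / y_scale
    rate = t_scale / y_scale  # velocity unit conversion
    frac_init = min(max(vs_init / v0_init, 0.0), 1.0) if v0_init > 0 else 0.5
    try:
        popt, _ = curve_fit(
            _progress_model_frac, tn, yn,
            p0=[0.0, max(v0_init, 1e-9) * rate, frac_init, kobs_init * t_scale],
            bounds=([-np.inf, 0.0, 0.0, 1e-9], [np.inf, np.inf, 1.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return TightBindingFit(
            v0=v0_init, vs=vs_init, kobs=kobs_init, baseline=float(y[0]),
            residual_rms=float("nan"), converged=False,
        )
    rms = float(np.sqrt(np.mean((yn - _progress_model_frac(tn, *popt)) ** 2))) * y_scale
    v0 = float(popt[1]) / rate
    vs = float(popt[1] * popt[2]) / rate
    kobs = float(popt[3]) / t_scale
    baseline = float(popt[0]) * y_scale + y[0]  # signal at t = t[0]
    # if the exponential buys nothing over a straight line, say so
    identifiable = not math.isclose(v0, vs, rel_tol=1e-6, abs_tol=1e-12 * span)
    return TightBindingFit(v0=v0, vs=vs, kobs=kobs, baseline=baseline,
                           residual_rms=rms, kobs_identifiable=identifiable)


def morrison_vs(i: np.ndarray, v0: float, ki_app: float, enzyme: float) -> np.ndarray:
    """Steady-state velocity under the Morrison tight-binding quadratic."""
    i = np.asarray(i, dtype=float)
    e = enzyme
    disc = np.sqrt((e + i + ki_app) ** 2 - 4.0 * e * i)
    return v0 * (1.0 - ((e + i + ki_app) - disc) / (2.0 * e))


@dataclass
class KiEstimate:
    """Inhibition constant from a Morrison fit of vs across [I]."""

    ki: float  # substrate-corrected, same unit as [I]
    ki_app: float
    sd: float
    v0: float
    n_points: int
    warnings: list = field(default_factory=list)


def morrison_fit(
    inhibitor: np.ndarray,
    vs: np.ndarray,
    enzyme: float,
    substrate: float,
    km: float,
) -> KiEstimate:
    """Fit (v0, Ki_app) to steady-state velocities over an [I] grid.

    Ki is reported after the competitive-substrate correction
    Ki = Ki_app / (1 + S/Km); its sd comes from the fit covariance, scaled
    by the same factor.
    """
    i = np.asarray(inhibitor, dtype=float)
    vs = np.asarray(vs, dtype=float)
    if len(i) < 5:
        raise ValueError("Morrison fit needs at least 5 inhibitor concentrations")
    warnings: list[str] = []

    v0_init = float(np.max(vs))
    ki_app_init = max(float(np.median(i[i > 0])) if np.any(i > 0) else enzyme, 1e-9)
    popt, pcov = curve_fit(
        lambda ii, v0, ki_app: morrison_vs(ii, v0, ki_app, enzyme),
        i, vs, p0=[v0_init, ki_app_init],
        bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        x_scale=[max(v0_init, 1e-12), ki_app_init],
    )
    v0_hat, ki_app_hat = (float(p) for p in popt)
    sd_app = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("inf")
    correction = 1.0 + substrate / km
    if i[i > 0].size and (ki_app_hat < 0.02 * i[i > 0].min() or
                          ki_app_hat > 50 * i.max()):
        warnings.append("inhibitor grid far from fitted Ki_app; estimate poorly constrained")
    if sd_app > 0.5 * ki_app_hat:
        warnings.append("wide uncertainty: sd exceeds half the estimate")
    return KiEstimate(
        ki=ki_app_hat / correction, ki_app=ki_app_hat, sd=sd_app / correction,
        v0=v0_hat, n_points=len(i), warnings=warnings,
    )


def estimate_ki_from_curves(curves: list[ProgressCurve]) -> KiEstimate:
    """Progress curves -> per-curve vs -> Morrison fit.

    All curves must share [E], [S] and Km; curves where kobs is
    unidentifiable (e.g. [I] = 0) contribute their straight-line slope.
    """
    e = {c.enzyme for c in curves}
    s = {c.substrate for c in curves}
    km = {c.km for c in curves}
    if len(e) != 1 or len(s) != 1 or len(km) != 1:
        raise ValueError("curves must share enzyme, substrate and Km")
    fits = [fit_progress_curve(c) for c in curves]
    i = np.array([c.inhibitor for c in curves])
    vs = np.array([f.vs for f in fits])
    return morrison_fit(i, vs, e.pop(), s.pop(), km.pop())


# ---------------------------------------------------------------------------
# Ki selectivity algebra


def calculated_selectivity(
    ki_parent_ref: float, ki_mut_ref: float,
    ki_parent_other: float, ki_mut_other: float,
) -> float:
    """Parent-normalized selectivity toward a reference target vs another.

    S = (Ki_parent,ref / Ki_mut,ref) / (Ki_parent,other / Ki_mut,other);
    S > 1 means the mutant improved its Ki toward the reference target more
    than toward the other. Scale-invariant per target, and 1 for the parent.
    """
    for ki in (ki_parent_ref, ki_mut_ref, ki_parent_other, ki_mut_other):
        if ki <= 0:
            raise ValueError("Ki values must be positive")
    return (ki_parent_ref / ki_mut_ref) / (ki_parent_other / ki_mut_other)


def expected_double_selectivity(s_total_a: float, s_total_b: float) -> float:
    """Multiplicative (no-coupling) expectation for a double mutant."""
    if s_total_a <= 0 or s_total_b <= 0:
        raise ValueError("selectivities must be positive")
    return s_total_a * s_total_b


def switch_ratio(
    ki_a_mut1: float, ki_a_mut2: float,
    ki_b_mut1: float, ki_b_mut2: float,
) -> float:
    """Ki fold change for target A divided by the fold change for target B."""
    for ki in (ki_a_mut1, ki_a_mut2, ki_b_mut1, ki_b_mut2):
        if ki <= 0:
            raise ValueError("Ki values must be positive")
    return (ki_a_mut1 / ki_a_mut2) / (ki_b_mut1 / ki_b_mut2)


def coupling_energy(
    s_ab: float, s_a: float, s_b: float,
    temperature_k: float = 298.15,
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> float:
    """Double-mutant-cycle coupling energy in kcal/mol.

    ddG_int = -R*T*ln(S_AB / (S_A * S_B)). Negative values mean the two
    mutations enhance selectivity cooperatively (the double mutant is more
    selective than the single-mutant product predicts).
    """
    if min(s_ab, s_a, s_b) <= 0:
        raise ValueError("selectivities must be positive")
    return -gas_constant * temperature_k * math.log(s_ab / (s_a * s_b))


def load_reference_ki_table() -> pd.DataFrame:
    """Bundled Ki panel (pM) for the Kunitz-scaffold variant set.

    Long format: mutant, target, ki_pm, sd_pm. Contains the parent scaffold
    and its loop variants against mesotrypsin, anionic trypsin, cationic
    trypsin and KLK6.
    """
    path = resources.files("sortsel.data") / "appi3m_ki.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def selectivity_report(
    ki_table: pd.DataFrame,
    ref_target: str,
    parent: str = "parent",
    temperature_k: float = 298.15,
) -> pd.DataFrame:
    """Per-mutant selectivity toward ``ref_target`` versus every other target.

    Input is a long-format Ki table (mutant, target, ki_pm). Output has one
    row per mutant with a column per competitor target, the total
    selectivity (product over competitors), and — for double mutants whose
    constituent singles are present — the expected total selectivity and the
    coupling energy ddG_int (kcal/mol).
    """
    ki = ki_table.pivot_table(index="mutant", columns="target", values="ki_pm")
    if parent not in ki.index:
        raise ValueError(f"parent {parent!r} missing from Ki table")
    others = [t for t in ki.columns if t != ref_target]
    rows = []
    totals: dict[str, float] = {}
    for mutant in ki.index:
        row: dict = {"mutant": mutant}
        sel = []
        for target in others:
            vals = (ki.loc[parent, ref_target], ki.loc[mutant, ref_target],
                    ki.loc[parent, target], ki.loc[mutant, target])
            if any(pd.isna(v) for v in vals):
                row[f"S_vs_{target}"] = float("nan")
                continue
            s = calculated_selectivity(*vals)
            row[f"S_vs_{target}"] = s
            sel.append(s)
        row["total_selectivity"] = float(np.prod(sel)) if len(sel) == len(others) else float("nan")
        totals[mutant] = row["total_selectivity"]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("mutant")

    expected, ddg = {}, {}
    for mutant in out.index:
        parts = mutant.split("/")
        if len(parts) == 2 and all(p in out.index for p in parts):
            exp = expected_double_selectivity(totals[parts[0]], totals[parts[1]])
            expected[mutant] = exp
            s_ab = totals[mutant]
            if not (pd.isna(s_ab) or pd.isna(exp)):
                ddg[mutant] = coupling_energy(
                    s_ab, totals[parts[0]], totals[parts[1]],
                    temperature_k=temperature_k,
                )
    out["expected_total_selectivity"] = pd.Series(expected)
    out["ddG_int_kcal_mol"] = pd.Series(ddg)
    return out
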
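"""TR-FRET dose-response analysis.

Plate readings arrive as 520/495 nm emission pairs; their ratio is the
assay response. Responses are fitted to the four-parameter logistic (4PL)

    y = bottom + (top - bottom) / (1 + 10**(hill * (log_mid - log10 x))),

with x in molar. Competitive-binding IC50s convert to inhibition constants
through the Cheng-Prusoff relation Ki = IC50 / (1 + [tracer]/Kd_tracer);
coregulator-recruitment EC50s and spans are normalised against a reference
full agonist/inverse agonist and fed to a threshold-based profile
classifier (full agonist / partial-selective modulator / neutral
antagonist / antagonist / inverse agonist).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .constants import TRACER_CONC, TRACER_KD
from .errors import FitError, PoseDeltaError

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    log_midpoint: float  # log10 M
    ci95: tuple[float, float]  # on log_midpoint
    residual_sd: float
    midpoint_in_range: bool

    @property
    def ic50_or_ec50(self) -> float:
        """Midpoint concentration, molar."""
        return 10.0 ** self.log_midpoint

    @property
    def span(self) -> float:
        return self.top - self.bottom


@dataclass(frozen=True)
class LigandProfile:
    binds: bool
    ki: float  # molar
    trap220_efficacy_pct: float
    ncor1_efficacy_pct: float
    classification: str


def four_pl(x: np.ndarray, bottom: float, top: float, hill: float,
            log_mid: float) -> np.ndarray:
    """4PL response at concentrations x (molar)."""
    exponent = np.clip(hill * (log_mid - np.log10(x)), -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0**exponent)


def tr_fret_ratio(em520: np.ndarray, em495: np.ndarray) -> np.ndarray:
    """Elementwise 520/495 emission ratio."""
    em520 = np.asarray(em520, dtype=float)
    em495 = np.asarray(em495, dtype=float)
    bad = np.flatnonzero(em495 <= 0)
    if bad.size:
        raise PoseDeltaError(f"nonpositive 495 nm reading at well index {int(bad[0])}")
    return em520 / em495


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate table (well, concentration, unit, em520, em495) and
    append molar concentrations and TR-FRET ratios."""
    df = pd.read_csv(path)
    required = {"well", "concentration", "unit", "em520", "em495"}
    missing = required - set(df.columns)
    if missing:
        raise PoseDeltaError(f"plate CSV missing columns: {sorted(missing)}")
    factors = df["unit"].map(_UNIT_TO_MOLAR)
    if factors.isna().any():
        bad = df.loc[factors.isna(), "unit"].unique().tolist()
        raise PoseDeltaError(f"unknown concentration units: {bad}")
    df = df.assign(
        concentration_m=df["concentration"] * factors,
        ratio=tr_fret_ratio(df["em520"].to_numpy(), df["em495"].to_numpy()),
    )
    return df


def fit_4pl(concentrations: np.ndarray, responses: np.ndarray) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialisation.

    Requires at least five distinct concentrations. The 95% CI on the log
    midpoint comes from the covariance at the optimum; a midpoint outside
    the tested range only sets a warning flag.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PoseDeltaError("concentrations and responses must be equal-length 1-D")
    if np.any(x <= 0):
        raise PoseDeltaError("concentrations must be positive (molar)")
    if np.unique(x).size < 5:
        raise PoseDeltaError("need >= 5 distinct concentrations")

    logx = np.log10(x)
    span = y.max() - y.min()
    best = None
    mid_starts = np.quantile(logx, [0.25, 0.5, 0.75])
    for hill0 in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0):
        for mid0 in mid_starts:
            p0 = (y.min(), y.max(), hill0, mid0)
            try:
                with warnings.catch_warnings():
                    # individual starts may sit at degenerate optima; only
                    # the best fit's covariance matters
                    warnings.simplefilter("ignore", OptimizeWarning)
                    popt, pcov = curve_fit(four_pl, x, y, p0=p0, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            resid = y - four_pl(x, *popt)
            ssr = float(resid @ resid)
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
    if best is None:
        raise FitError("4PL fit did not converge from any start", best_residual=None)
    ssr, popt, pcov = best
    bottom, top, hill, log_mid = (float(v) for v in popt)
    dof = max(1, x.size - 4)
    residual_sd = float(np.sqrt(ssr / dof))
    var_logmid = float(pcov[3, 3]) if np.all(np.isfinite(pcov)) else np.inf
    if not np.isfinite(var_logmid) or abs(top - bottom) < 1e-9 * max(1.0, abs(span)):
        raise FitError(
            "4PL midpoint is undetermined (flat or degenerate response)",
            best_residual=residual_sd,
        )
    se = float(np.sqrt(var_logmid))
    if bottom > top:  # canonical orientation: top = high-response plateau
        bottom, top, hill = top, bottom, -hill
    return DoseResponseFit(
        bottom=bottom,
        top=top,
        hill=hill,
        log_midpoint=log_mid,
        ci95=(log_mid - 1.96 * se, log_mid + 1.96 * se),
        residual_sd=residual_sd,
        midpoint_in_range=bool(logx.min() <= log_mid <= logx.max()),
    )


def cheng_prusoff_ki(ic50: float, tracer_conc: float = TRACER_CONC,
                     tracer_kd: float = TRACER_KD) -> float:
    """Inhibition constant from a competitive-binding IC50 (same units in/out)."""
    if ic50 <= 0 or tracer_conc < 0 or tracer_kd <= 0:
        raise PoseDeltaError(
            "cheng_prusoff_ki needs ic50 > 0, tracer_conc >= 0, tracer_kd > 0"
        )
    return ic50 / (1.0 + tracer_conc / tracer_kd)


def normalize_efficacy(fit: DoseResponseFit, reference_fit: DoseResponseFit) -> float:
    """Span of a fit as a percentage of the reference span."""
    ref_span = reference_fit.span
    if abs(ref_span) < 1e-12:
        raise PoseDeltaError("reference fit has zero span")
    return 100.0 * fit.span / ref_span


def classify_ligand(ki: float, trap220_efficacy_pct: float,
                    ncor1_efficacy_pct: float,
                    threshold_partial: float = 10.0,
                    threshold_full: float = 80.0) -> LigandProfile:
    """Classify a binder from coactivator/corepressor recruitment efficacies.

    Decision table (both efficacies as % of the respective reference):
    coactivator >= threshold_full -> full agonist; in [threshold_partial,
    threshold_full) -> partial/selective modulator; below threshold_partial
    the corepressor side decides: < threshold_partial -> neutral antagonist,
    >= threshold_full -> inverse agonist, otherwise antagonist.
    """
    for name, v in (("trap220_efficacy_pct", trap220_efficacy_pct),
                    ("ncor1_efficacy_pct", ncor1_efficacy_pct)):
        if v is None or not np.isfinite(v) or v < 0:
            raise PoseDeltaError(f"{name} must be a finite nonnegative percentage")
    if not (np.isfinite(ki) and ki > 0):
        raise PoseDeltaError("classification requires an established finite Ki")
    if trap220_efficacy_pct >= threshold_full:
        cls = "full agonist"
    elif trap220_efficacy_pct >= threshold_partial:
        cls = "partial/selective modulator"
    elif ncor1_efficacy_pct >= threshold_full:
        cls = "inverse agonist"
    elif ncor1_efficacy_pct >= threshold_partial:
        cls = "antagonist"
    else:
        cls = "neutral antagonist"
    return LigandProfile(
        binds=True,
        ki=ki,
        trap220_efficacy_pct=trap220_efficacy_pct,
        ncor1_efficacy_pct=ncor1_efficacy_pct,
        classification=cls,
    )
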
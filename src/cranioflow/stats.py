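"""Statistical analyses: normality, dual correlation, grid independence and
calculated-vs-measured ICP validation.

The ICC-stiffness relationship is tested with both the Pearson product-moment
and the Spearman rank correlation at alpha = 0.05, with Shapiro-Wilk
normality statistics reported alongside. Spearman p-values are exact
(permutation enumeration) for n <= 9 without ties and use the t approximation
otherwise; Pearson p-values use the t transform. Ties receive mid-ranks.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coupling import CouplingConfig, extract_icp, run_fsi
from .errors import SolverDivergenceError
from .geometry import REFINEMENT_LEVELS, HeadGeometry, generate_mesh


@dataclass
class CorrelationReport:
    """Dual-correlation and normality summary for two paired samples."""

    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    shapiro_w_x: float
    shapiro_p_x: float
    shapiro_w_y: float
    shapiro_p_y: float
    alpha: float = 0.05
    flags: list = field(default_factory=list)

    @property
    def pearson_verdict(self) -> str:
        if not np.isfinite(self.pearson_p):
            return "undefined"
        return "significant" if self.pearson_p < self.alpha else "not_significant"

    @property
    def spearman_verdict(self) -> str:
        if not np.isfinite(self.spearman_p):
            return "undefined"
        return "significant" if self.spearman_p < self.alpha else "not_significant"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pearson_verdict"] = self.pearson_verdict
        d["spearman_verdict"] = self.spearman_verdict
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_text(self) -> str:
        return (
            f"n = {self.n}\n"
            f"Pearson  r = {self.pearson_r:+.4f} (p = {self.pearson_p:.4g}) -> {self.pearson_verdict}\n"
            f"Spearman rho = {self.spearman_rho:+.4f} (p = {self.spearman_p:.4g}) -> {self.spearman_verdict}\n"
            f"Shapiro-Wilk x: W = {self.shapiro_w_x:.4f} (p = {self.shapiro_p_x:.4g})\n"
            f"Shapiro-Wilk y: W = {self.shapiro_w_y:.4f} (p = {self.shapiro_p_y:.4g})\n"
            f"alpha = {self.alpha}"
        )


def midranks(x: np.ndarray) -> np.ndarray:
    """Mid-rank transform (average ranks for ties), 1-based."""
    return sps.rankdata(np.asarray(x, dtype=float), method="average")


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (no ties)."""
    n = x.size
    rx = midranks(x)
    ry = midranks(y)
    # rho is monotone in sum(rx * ry_perm); enumerate permutations of ry
    perms = np.array(list(itertools.permutations(ry)))
    s = perms @ rx
    mean = n * (n + 1) ** 2 / 4.0
    denom = np.sum(rx**2) - n * ((n + 1) / 2.0) ** 2
    rhos = (s - mean) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlation_analysis(x, y, alpha: float = 0.05) -> CorrelationReport:
    """Pearson + Spearman correlations with Shapiro-Wilk normality checks.

    Constant inputs make both correlations undefined; the report is returned
    with NaN coefficients and an explanatory flag rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    flags = []
    nan = float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        flags.append("constant_input: correlation undefined")
        sw = (nan, nan, nan, nan)
        return CorrelationReport(
            n=x.size, pearson_r=nan, pearson_p=nan, spearman_rho=nan, spearman_p=nan,
            shapiro_w_x=sw[0], shapiro_p_x=sw[1], shapiro_w_y=sw[2], shapiro_p_y=sw[3],
            alpha=alpha, flags=flags,
        )
    pr, pp = sps.pearsonr(x, y)
    rho, sp_p = sps.spearmanr(x, y)
    has_ties = (np.unique(x).size < x.size) or (np.unique(y).size < y.size)
    if x.size <= 9 and not has_ties:
        sp_p = _spearman_exact_p(x, y, float(rho))
        flags.append("spearman_p: exact permutation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wx, px = sps.shapiro(x)
        wy, py = sps.shapiro(y)
    return CorrelationReport(
        n=int(x.size),
        pearson_r=float(pr),
        pearson_p=float(pp),
        spearman_rho=float(rho),
        spearman_p=float(sp_p),
        shapiro_w_x=float(wx),
        shapiro_p_x=float(px),
        shapiro_w_y=float(wy),
        shapiro_p_y=float(py),
        alpha=alpha,
        flags=flags,
    )


def icc_stiffness_analysis(table: pd.DataFrame, alpha: float = 0.05,
                           per_patient_mean: bool = False) -> CorrelationReport:
    """Correlate ICC against FSI-based stiffness over a cohort table
    (columns icc_ml_per_cmH2O, stiffness_N_per_m; one row per
    patient-interval, or per-patient means when requested)."""
    df = table
    if per_patient_mean:
        df = table.groupby("patient_id")[["icc_ml_per_cmH2O", "stiffness_N_per_m"]].mean()
    return correlation_analysis(
        df["icc_ml_per_cmH2O"].to_numpy(), df["stiffness_N_per_m"].to_numpy(), alpha
    )


# ------------------------------------------------------------- grid study


@dataclass
class GridStudyReport:
    """Cycle-mean ICP per refinement level and successive differences (%)."""

    levels: list
    icp_cmH2O: list
    successive_diff_percent: list
    excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def finest_pair_diff_percent(self) -> float:
        return self.successive_diff_percent[-1]


def grid_independence(
    geometry: HeadGeometry,
    waveforms,
    coupling: CouplingConfig | None = None,
    levels=REFINEMENT_LEVELS,
    fluid_props=None,
    material=None,
    reducer: str = "cycle_mean",
) -> GridStudyReport:
    """Run the coupled simulation at each refinement level and report the
    cycle-mean ventricular ICP and the successive relative differences in %.

    Levels whose run fails or does not converge are excluded with a warning.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 refinement levels")
    kept, icps, excluded = [], [], []
    for lvl in levels:
        mesh = generate_mesh(geometry, lvl)
        try:
            res = run_fsi(mesh, fluid_props, material, waveforms, coupling)
            if not res.all_converged:
                raise SolverDivergenceError(f"non-converged steps at level {lvl}")
            kept.append(lvl)
            icps.append(extract_icp(res, reducer))
        except SolverDivergenceError as exc:
            warnings.warn(f"grid level {lvl!r} excluded: {exc}", RuntimeWarning, stacklevel=2)
            excluded.append(lvl)
    diffs = [
        abs(a - b) / abs(b) * 100.0 for a, b in zip(icps[:-1], icps[1:])
    ]
    return GridStudyReport(
        levels=kept, icp_cmH2O=icps, successive_diff_percent=diffs, excluded=excluded
    )


# ------------------------------------------------------- validation compare


def validation_compare(calculated, measured, alpha: float = 0.05):
    """Per-patient |calculated - measured| / measured in %, plus the dual
    correlation between the two series.

    Returns (DataFrame with columns calculated, measured, diff_percent,
    flagged; CorrelationReport or None when n < 3)."""
    calc = np.asarray(calculated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if calc.shape != meas.shape:
        raise ValueError("paired lists must have equal length")
    flagged = meas == 0
    diff = np.where(~flagged, np.abs(calc - meas) / np.where(flagged, 1.0, np.abs(meas)) * 100.0, np.nan)
    df = pd.DataFrame(
        {"calculated": calc, "measured": meas, "diff_percent": diff, "flagged": flagged}
    )
    ok = ~flagged
    report = None
    if ok.sum() >= 3:
        report = correlation_analysis(calc[ok], meas[ok], alpha)
    return df, report
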
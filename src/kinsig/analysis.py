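"""Analysis of real-time assay datasets: KRI, peaks, fits, onset, statistics.

The procedures here are the ones used to turn raw kinetic and functional plate
data into pharmacological quantities:

* :func:`compute_kri` -- the kinetic rate index KRI = B_t1 / B_t2 from a
  dual-point competition association read; KRI > 1 flags competitors that
  dissociate more slowly than the radioligand, KRI < 1 faster.
* :func:`peak_response` -- peak analysis (max minus baseline) of each well.
* :class:`ConcentrationResponseModel` -- variable-slope (four-parameter
  logistic) fit of log(concentration) vs response, ascending for agonists,
  descending for IC50-type inhibition curves; multi-start least squares with
  standard errors.
* :func:`normalize_to_control` -- rescaling so the agonist-only control's
  fitted maximum reads 100%.
* :func:`compute_onset` -- onset of receptor activation: OLS slope of the
  response over the first 8 minutes after agonist addition.
* :func:`dunnett_anova` -- one-way ANOVA with Dunnett's many-to-one post-test
  (seeded multivariate-t Monte Carlo).
* :func:`classify_surmountability` -- surmountable / partially insurmountable /
  insurmountable labels from normalized Emax plus significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assays import TimeCourseDataset
from .kinetics import ValidationError

__all__ = [
    "KRIResult",
    "OnsetResult",
    "DunnettResult",
    "ConcentrationResponseModel",
    "ConcentrationResponseResults",
    "compute_kri",
    "kri_from_dataset",
    "peak_response",
    "fit_concentration_response",
    "fit_inhibition",
    "normalize_to_control",
    "compute_ec80",
    "compute_onset",
    "dunnett_anova",
    "classify_surmountability",
]


# -- KRI ----------------------------------------------------------------------


@dataclass(frozen=True)
class KRIResult:
    """Dual-point kinetic rate index with its inputs retained."""

    b_t1: float
    b_t2: float
    t1: float = 30.0
    t2: float = 120.0

    @property
    def kri(self) -> float:
        return self.b_t1 / self.b_t2

    @property
    def interpretation(self) -> str:
        if self.kri > 1.0:
            return "slower dissociation than the radioligand (KRI > 1)"
        if self.kri < 1.0:
            return "faster dissociation than the radioligand (KRI < 1)"
        return "dissociation comparable to the radioligand (KRI = 1)"


def compute_kri(b_t1: float, b_t2: float, t1: float = 30.0, t2: float = 120.0) -> KRIResult:
    """KRI = B_t1 / B_t2 from specific binding at the two read times."""
    if b_t2 <= 0:
        raise ValidationError(f"b_t2 must be positive, got {b_t2}")
    if b_t1 < 0:
        raise ValidationError(f"b_t1 must be non-negative, got {b_t1}")
    return KRIResult(b_t1=float(b_t1), b_t2=float(b_t2), t1=t1, t2=t2)


def kri_from_dataset(dataset: TimeCourseDataset) -> KRIResult:
    """Compute the KRI from a dual-point dataset (replicates averaged)."""
    df = dataset.data
    times = np.sort(df["time_min"].unique())
    if times.size != 2:
        raise ValidationError(f"dual-point dataset must have exactly 2 read times, got {times.size}")
    t1, t2 = float(times[0]), float(times[1])
    b1 = df.loc[df["time_min"] == t1, "value"].mean()
    b2 = df.loc[df["time_min"] == t2, "value"].mean()
    return compute_kri(b1, b2, t1=t1, t2=t2)


# -- peak analysis ------------------------------------------------------------


def peak_response(
    dataset: TimeCourseDataset, baseline_window: Optional[float] = None
) -> pd.DataFrame:
    """Peak analysis: per condition and replicate, max(value - baseline).

    Baseline is the mean of pre-stimulation samples (time < 0, optionally
    restricted to the last ``baseline_window`` minutes before addition); when
    the trace starts at addition, the first sample serves as baseline.
    """
    df = dataset.data
    if df.empty:
        raise ValidationError("dataset is empty")
    rows = []
    for (cond, rep), grp in df.groupby(["condition_id", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        if grp["value"].isna().all():
            raise ValidationError(f"condition {cond!r} replicate {rep} has no data")
        pre = grp[grp["time_min"] < 0]
        if baseline_window is not None:
            pre = pre[pre["time_min"] >= -baseline_window]
        baseline = pre["value"].mean() if len(pre) else float(grp["value"].iloc[0])
        post = grp[grp["time_min"] >= 0]
        rows.append(
            {
                "condition_id": cond,
                "agonist_conc_nM": grp["agonist_conc_nM"].iloc[0],
                "antagonist_conc_nM": grp["antagonist_conc_nM"].iloc[0],
                "replicate": rep,
                "baseline": baseline,
                "peak": float((post["value"] - baseline).max()),
            }
        )
    return pd.DataFrame(rows)


# -- variable-slope concentration-response fitting ----------------------------


def _logistic(x: np.ndarray, bottom: float, top: float, logec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - x) * hill))


@dataclass
class ConcentrationResponseResults:
    """Parameter estimates of a variable-slope logistic fit.

    ``ec50`` is in nM; ``pec50`` on the -log10(molar) scale.  ``emax`` is the
    fitted top, ``baseline`` the fitted bottom.  ``bse`` holds asymptotic
    standard errors in the order (baseline, emax, log10 ec50, hill).
    """

    baseline: float
    emax: float
    ec50: float
    hill: float
    bse: dict[str, float]
    converged: bool
    direction: str
    normalized: bool = False
    extrapolated: bool = False
    residual_ss: float = float("nan")
    n_obs: int = 0
    model: Optional["ConcentrationResponseModel"] = None

    @property
    def pec50(self) -> float:
        return 9.0 - math.log10(self.ec50) if self.ec50 > 0 else float("nan")

    @property
    def ic50(self) -> float:
        """Alias used for descending (inhibition) fits."""
        return self.ec50

    def predict(self, conc_nM: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(conc_nM, dtype=float))
        if self.direction == "descending":
            return _logistic(-x, self.baseline, self.emax, -math.log10(self.ec50), self.hill)
        return _logistic(x, self.baseline, self.emax, math.log10(self.ec50), self.hill)

    def summary(self) -> str:
        label = "EC50" if self.direction == "ascending" else "IC50"
        lines = [
            "Variable-slope concentration-response fit",
            "=" * 45,
            f"direction:   {self.direction}",
            f"n obs:       {self.n_obs}",
            f"converged:   {self.converged}",
            f"normalized:  {self.normalized}",
            f"{label}:        {self.ec50:.4g} nM  (p{label} {self.pec50:.3f})"
            + ("  [extrapolated]" if self.extrapolated else ""),
            f"Emax (top):  {self.emax:.4g} +/- {self.bse.get('emax', float('nan')):.2g}",
            f"bottom:      {self.baseline:.4g} +/- {self.bse.get('baseline', float('nan')):.2g}",
            f"Hill slope:  {self.hill:.4g} +/- {self.bse.get('hill', float('nan')):.2g}",
            f"residual SS: {self.residual_ss:.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Concentration-response scatter with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.semilogx(self.model.conc, self.model.response, "o", alpha=0.6)
            grid = np.logspace(
                np.log10(self.model.conc.min()) - 0.5, np.log10(self.model.conc.max()) + 0.5, 200
            )
            ax.semilogx(grid, self.predict(grid), "-")
        ax.set_xlabel("concentration (nM)")
        ax.set_ylabel("response")
        return ax


class ConcentrationResponseModel:
    """log(concentration) vs response, variable-slope logistic.

    Ascending (agonist) form::

        r = bottom + (top - bottom) / (1 + 10^((logEC50 - logL) * hill))

    Descending (inhibition at fixed agonist challenge) uses the mirrored form
    so the response falls with concentration while ``hill`` stays positive.
    ``fit`` runs least squares from five deterministic starts spanning the
    concentration range and reports asymptotic standard errors; non-convergence
    is flagged on the result, never raised.
    """

    N_STARTS = 5

    def __init__(self, conc_nM: Sequence[float], response: Sequence[float], direction: str = "ascending"):
        conc = np.asarray(conc_nM, dtype=float)
        resp = np.asarray(response, dtype=float)
        if direction not in ("ascending", "descending"):
            raise ValidationError(f"direction must be ascending or descending, got {direction!r}")
        if conc.shape != resp.shape:
            raise ValidationError("conc and response must have the same shape")
        keep = np.isfinite(conc) & np.isfinite(resp) & (conc > 0)
        self.conc = conc[keep]
        self.response = resp[keep]
        self.direction = direction
        if np.unique(self.conc).size < 5:
            raise ValidationError("need >= 5 distinct positive concentrations")

    @classmethod
    def from_peaks(
        cls, peaks: pd.DataFrame, direction: str = "ascending", conc_col: Optional[str] = None
    ) -> "ConcentrationResponseModel":
        if conc_col is None:
            conc_col = "agonist_conc_nM" if direction == "ascending" else "antagonist_conc_nM"
        df = peaks[peaks[conc_col] > 0]
        return cls(df[conc_col].to_numpy(), df["peak"].to_numpy(), direction=direction)

    def fit(self) -> ConcentrationResponseResults:
        x = np.log10(self.conc)
        y = self.response
        if self.direction == "descending":
            x = -x  # mirrored axis: logistic is ascending in -logL
        span = y.max() - y.min()
        scale = max(abs(y).max(), 1.0)
        degenerate = span < 1e-9 * scale

        best = None
        if not degenerate:
            lo, hi = x.min(), x.max()
            starts = np.linspace(lo, hi, self.N_STARTS)
            bounds = ([-np.inf, -np.inf, lo - 3.0, 0.05], [np.inf, np.inf, hi + 3.0, 10.0])
            for s in starts:
                p0 = [y.min(), y.max(), s, 1.0]
                try:
                    popt, pcov = optimize.curve_fit(
                        _logistic, x, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-13, ftol=1e-13
                    )
                except (RuntimeError, ValueError):
                    continue
                ss = float(np.sum((y - _logistic(x, *popt)) ** 2))
                if best is None or ss < best[2]:
                    best = (popt, pcov, ss)

        if best is None:
            nan = float("nan")
            return ConcentrationResponseResults(
                baseline=nan, emax=nan, ec50=nan, hill=nan,
                bse={}, converged=False, direction=self.direction, n_obs=y.size, model=self,
            )

        popt, pcov, ss = best
        bottom, top, logec50, hill = popt
        with np.errstate(invalid="ignore"):
            perr = np.sqrt(np.diag(pcov))
        ec50 = 10.0 ** (-logec50) if self.direction == "descending" else 10.0 ** logec50
        extrapolated = not (x.min() - 1.0 <= logec50 <= x.max() + 1.0)
        return ConcentrationResponseResults(
            baseline=float(bottom),
            emax=float(top),
            ec50=float(ec50),
            hill=float(hill),
            bse={
                "baseline": float(perr[0]),
                "emax": float(perr[1]),
                "log_ec50": float(perr[2]),
                "hill": float(perr[3]),
            },
            converged=True,
            direction=self.direction,
            extrapolated=extrapolated,
            residual_ss=ss,
            n_obs=int(y.size),
            model=self,
        )


def fit_concentration_response(
    peaks: pd.DataFrame | tuple, direction: str = "ascending"
) -> ConcentrationResponseResults:
    """Variable-slope fit of a peaks table (or ``(conc, response)`` arrays)."""
    if isinstance(peaks, pd.DataFrame):
        model = ConcentrationResponseModel.from_peaks(peaks, direction=direction)
    else:
        conc, resp = peaks
        model = ConcentrationResponseModel(conc, resp, direction=direction)
    return model.fit()


def fit_inhibition(peaks: pd.DataFrame | tuple) -> ConcentrationResponseResults:
    """Descending variable-slope fit for antagonist-vs-EC80-challenge data."""
    return fit_concentration_response(peaks, direction="descending")


def normalize_to_control(
    peaks: pd.DataFrame,
    control_mask: Optional[pd.Series] = None,
    value_col: str = "peak",
) -> tuple[pd.DataFrame, float]:
    """Rescale peak values so the agonist-only control maximum reads 100%.

    The control is the ``antagonist_conc_nM == 0`` subset unless a boolean
    ``control_mask`` is supplied.  When the control spans a concentration
    series, its fitted top defines 100% (less noise-sensitive than the single
    largest observation); for a single-concentration control the replicate mean
    is used.  Returns the rescaled table and the scale factor applied.
    """
    if control_mask is None:
        control_mask = peaks["antagonist_conc_nM"] == 0
    control = peaks[control_mask]
    if control.empty:
        raise ValidationError("no control rows found for normalization")
    if control["agonist_conc_nM"].nunique() >= 5:
        control_top = fit_concentration_response(control, direction="ascending").emax
    else:
        control_top = control[value_col].mean()
    if not control_top > 0:
        raise ValidationError(f"control maximum must be positive, got {control_top}")
    factor = 100.0 / control_top
    out = peaks.copy()
    out[value_col] = out[value_col] * factor
    return out, factor


def compute_ec80(fit: ConcentrationResponseResults) -> float:
    """EC80 = EC50 * (80/20)^(1/hill) from a converged ascending fit."""
    if not fit.converged:
        raise ValidationError("EC80 requires a converged fit")
    if not fit.hill > 0:
        raise ValidationError(f"hill must be positive, got {fit.hill}")
    return fit.ec50 * 4.0 ** (1.0 / fit.hill)


# -- onset of receptor activation ---------------------------------------------


@dataclass(frozen=True)
class OnsetResult:
    """Onset of receptor activation: early-window linear slope of the response."""

    slope: float
    intercept: float
    window_min: float
    r_squared: float
    n_points: int
    per_replicate: pd.DataFrame = field(repr=False, default=None)


def compute_onset(
    dataset: TimeCourseDataset,
    condition_id: Optional[str] = None,
    window_min: float = 8.0,
) -> OnsetResult:
    """OLS slope of value vs time over the first ``window_min`` minutes.

    Uses samples strictly after agonist addition (0 < t <= window), fitted per
    replicate and then averaged, in readout units per minute.
    """
    df = dataset.data
    if condition_id is None:
        ids = df["condition_id"].unique()
        if len(ids) != 1:
            raise ValidationError("condition_id required when the dataset has several conditions")
        condition_id = ids[0]
    sub = df[df["condition_id"] == condition_id]
    if sub.empty:
        raise ValidationError(f"unknown condition {condition_id!r}")
    rows = []
    for rep, grp in sub.groupby("replicate"):
        win = grp[(grp["time_min"] > 0) & (grp["time_min"] <= window_min)].sort_values("time_min")
        if len(win) < 3:
            raise ValidationError(
                f"need >= 3 samples in (0, {window_min}] min, got {len(win)} for replicate {rep}"
            )
        res = stats.linregress(win["time_min"], win["value"])
        rows.append(
            {
                "replicate": rep,
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.rvalue**2,
                "n_points": len(win),
            }
        )
    per_rep = pd.DataFrame(rows)
    return OnsetResult(
        slope=float(per_rep["slope"].mean()),
        intercept=float(per_rep["intercept"].mean()),
        window_min=window_min,
        r_squared=float(per_rep["r_squared"].mean()),
        n_points=int(per_rep["n_points"].iloc[0]),
        per_replicate=per_rep,
    )


# -- ANOVA + Dunnett ----------------------------------------------------------


@dataclass(frozen=True)
class DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons against a control."""

    table: pd.DataFrame  # columns: label, mean_diff, t, p_adj
    f_stat: float
    f_pvalue: float
    alpha: float
    df_resid: int
    n_comparisons: int

    def p_adj(self, label: str) -> float:
        row = self.table[self.table["label"] == label]
        if row.empty:
            raise ValidationError(f"no comparison for group {label!r}")
        return float(row["p_adj"].iloc[0])

    def significant(self, label: str) -> bool:
        return self.p_adj(label) < self.alpha


_MAXT_CACHE: dict[tuple, np.ndarray] = {}


def _dunnett_null_maxt(
    ns: tuple[int, ...], n0: int, df: int, n_draws: int, seed: int
) -> np.ndarray:
    """Seeded Monte Carlo sample of max_i |T_i| under the Dunnett null.

    T has the multivariate-t distribution with correlation
    rho_ij = sqrt(n_i n_j / ((n_i + n0)(n_j + n0))), realised via the
    one-factor construction W_i = lam_i Z0 + sqrt(1 - lam_i^2) Z_i.
    """
    key = (ns, n0, df, n_draws, seed)
    if key not in _MAXT_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
        lam = np.sqrt(np.array(ns) / (np.array(ns) + n0))
        z0 = rng.standard_normal(n_draws)
        z = rng.standard_normal((n_draws, len(ns)))
        w = lam * z0[:, None] + np.sqrt(1.0 - lam**2) * z
        chi = np.sqrt(rng.chisquare(df, size=n_draws) / df)
        _MAXT_CACHE[key] = np.sort(np.max(np.abs(w) / chi[:, None], axis=1))
    return _MAXT_CACHE[key]


def dunnett_anova(
    groups: Mapping[str, Sequence[float]] | pd.DataFrame,
    control_label: str,
    alpha: float = 0.05,
    seed: int = 0,
    n_draws: int = 100_000,
) -> DunnettResult:
    """One-way ANOVA followed by Dunnett's post-test against ``control_label``.

    ``groups`` maps label -> replicate values (or a DataFrame with ``group``
    and ``value`` columns).  Two-sided adjusted p-values come from a seeded
    Monte Carlo sample (default 1e5 draws) of the max-|T| multivariate-t null,
    so results are deterministic given ``seed``.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {g: grp["value"].to_numpy() for g, grp in groups.groupby("group")}
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if control_label not in groups:
        raise ValidationError(f"control group {control_label!r} missing")
    if len(groups) < 2:
        raise ValidationError("need at least one treatment group plus the control")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {label!r} needs >= 2 replicates")

    labels = [k for k in groups if k != control_label]
    y0 = groups[control_label]
    n0 = len(y0)
    ns = tuple(len(groups[k]) for k in labels)
    n_total = n0 + sum(ns)
    k_groups = len(groups)
    df_resid = n_total - k_groups

    sse = sum(np.sum((v - v.mean()) ** 2) for v in groups.values())
    if sse <= 0:
        raise ValidationError("zero within-group variance in every group; t statistics undefined")
    s2 = sse / df_resid

    f_stat, f_p = stats.f_oneway(*groups.values())

    t_stats = np.array(
        [
            (groups[k].mean() - y0.mean()) / math.sqrt(s2 * (1.0 / len(groups[k]) + 1.0 / n0))
            for k in labels
        ]
    )
    null_maxt = _dunnett_null_maxt(ns, n0, df_resid, n_draws, seed)
    # P(max|T| >= |t|) via the sorted null sample
    exceed = null_maxt.size - np.searchsorted(null_maxt, np.abs(t_stats), side="left")
    p_adj = np.clip(exceed / null_maxt.size, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "label": labels,
            "mean_diff": [groups[k].mean() - y0.mean() for k in labels],
            "t": t_stats,
            "p_adj": p_adj,
        }
    )
    return DunnettResult(
        table=table,
        f_stat=float(f_stat),
        f_pvalue=float(f_p),
        alpha=alpha,
        df_resid=df_resid,
        n_comparisons=len(labels),
    )


# -- surmountability ----------------------------------------------------------


def classify_surmountability(
    control_fit: ConcentrationResponseResults,
    antagonist_fits: Mapping[str, ConcentrationResponseResults | float],
    dunnett: DunnettResult,
    emax_cut: float = 50.0,
) -> dict[str, str]:
    """Label each antagonist condition from its normalized Emax.

    surmountable: Emax reduction vs control not significant.
    partially insurmountable: significant reduction, normalized Emax >= cut.
    insurmountable: significant reduction, normalized Emax < cut.

    ``antagonist_fits`` maps condition label to a normalized fit (or directly
    to a normalized Emax in %); labels must match the Dunnett comparisons.
    """
    if control_fit is None:
        raise ValidationError("control fit required")
    out: dict[str, str] = {}
    for label, fit in antagonist_fits.items():
        emax = fit if isinstance(fit, (int, float)) else fit.emax
        significant = dunnett.significant(label) and emax < 100.0
        if not significant:
            out[label] = "surmountable"
        elif emax >= emax_cut:
            out[label] = "partially insurmountable"
        else:
            out[label] = "insurmountable"
    return out
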
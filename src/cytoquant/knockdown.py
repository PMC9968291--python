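"""Single-cell knockdown analysis: trace correction, dose stratification,
per-timepoint 4PL dose-response, and a kinetic knockdown model.

The kinetic model is a three-species ODE: cytosolic siRNA decays first order,
mRNA is produced at a constant rate and degraded both constitutively and by a
Hill-type siRNA-dependent pathway, and the reporter protein follows the mRNA
with fixed fast turnover.  Relative expression is the protein level divided
by the untreated steady state, so a dose of zero gives exactly 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, curve_fit, least_squares

__all__ = [
    "KineticModel",
    "FourPLFit",
    "QuantileGroup",
    "correct_expression",
    "group_by_magnitude",
    "fit_4pl",
    "ic50_timecourse",
    "fit_kinetic_model",
]

#: protein half-life of the destabilized reporter, hours
PROTEIN_HALF_LIFE_H = 0.8
DEFAULT_DELTA_P = math.log(2) / PROTEIN_HALF_LIFE_H


@dataclass
class KineticModel:
    """Dose-dependent knockdown kinetics.

    s' = -lambda_s * s
    m' = alpha - m * (delta_m + v_max * s^n / (s^n + K^n))
    p' = beta * m - delta_p * p

    with untreated steady state m0 = alpha/delta_m, p0 = beta*m0/delta_p.
    ``alpha`` and ``beta`` cancel in relative expression and default to 1.
    """

    delta_m: float = 0.35      # per h, constitutive mRNA turnover
    v_max: float = 3.0         # per h, maximal siRNA-mediated degradation
    K: float = 1.0             # nM, half-saturation of the silencing pathway
    n: float = 1.0             # Hill coefficient
    lambda_s: float = 0.05     # per h, cytosolic siRNA loss
    alpha: float = 1.0
    beta: float = 1.0
    delta_p: float = DEFAULT_DELTA_P

    def __post_init__(self) -> None:
        for name in ("delta_m", "v_max", "K", "n", "lambda_s", "alpha", "beta", "delta_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def relative_expression(self, dose_nm: float, times_h) -> np.ndarray:
        """Relative reporter expression p(t)/p0 at the requested times."""
        times_h = np.atleast_1d(np.asarray(times_h, dtype=float))
        if dose_nm < 0:
            raise ValueError("dose must be non-negative")
        if dose_nm == 0:
            return np.ones_like(times_h)
        t_max = float(times_h.max())
        if t_max == 0:
            return np.ones_like(times_h)
        # fine-grid linear-ODE integration via integrating factors
        grid = np.linspace(0.0, t_max, max(400, int(t_max * 50) + 1))
        s = dose_nm * np.exp(-self.lambda_s * grid)
        sn = s ** self.n
        g = self.delta_m + self.v_max * sn / (sn + self.K ** self.n)
        G = np.minimum(cumulative_trapezoid(g, grid, initial=0.0), 500.0)  # overflow guard
        m0 = self.alpha / self.delta_m
        m = np.exp(-G) * (m0 + cumulative_trapezoid(self.alpha * np.exp(G), grid, initial=0.0))
        H = self.delta_p * grid
        p0 = self.beta * m0 / self.delta_p
        p = np.exp(-H) * (p0 + cumulative_trapezoid(self.beta * m * np.exp(H), grid, initial=0.0))
        return np.interp(times_h, grid, p / p0)

    def absolute_ic50(self, t_h: float, bracket=(1e-4, 1e4)) -> float:
        """Dose at which relative expression at ``t_h`` equals 0.5 (nM);
        NaN when the model never reaches 50% knockdown in the bracket."""
        def f(log_d):
            return float(self.relative_expression(10 ** log_d, [t_h])[0]) - 0.5

        lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
        if f(lo) <= 0 or f(hi) >= 0:
            return float("nan")
        return float(10 ** brentq(f, lo, hi, xtol=1e-6))


@dataclass
class FourPLFit:
    top: float
    bottom: float
    hillslope: float
    ic50_relative: float
    ic50_absolute: float
    timepoint_h: float | None = None
    n: int = 0
    ci_relative: tuple | None = None
    ci_absolute: tuple | None = None
    degenerate: bool = False


@dataclass
class QuantileGroup:
    index: int
    track_ids: list
    median_conc: float
    conc_iqr: tuple
    mean_r2: float
    times: np.ndarray
    mean_curve: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    member_curves: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# expression correction


def correct_expression(
    traces: pd.DataFrame,
    events: pd.DataFrame,
    value_column: str = "median_eGFP_nucleusmask",
    well_column: str | None = "well",
    apoptosis: dict | None = None,
    mitosis: dict | None = None,
    mitosis_correction: np.ndarray | None = None,
    low_egfp_threshold: float | None = None,
    frame_interval_min: float = 5.0,
    late_entry_frame: int = 3,
    apoptosis_mask_frames: int = 20,
    min_controls: int = 5,
) -> pd.DataFrame:
    """Bleach-correct, align, and normalize eGFP traces of event cells.

    Each event cell is divided by the mean normalized trajectory of same-well
    control cells (tracks with no detected event), aligned so the first event
    is t = 0, and normalized to its value at t = 0 (exactly 1 there by
    construction).  Frames after a second event, within
    ``apoptosis_mask_frames`` of apoptosis, and cells entering after
    ``late_entry_frame`` or below ``low_egfp_threshold`` are dropped.

    Returns a long DataFrame (track_id, rel_frame, time_min, rel_expression).
    """
    traces = traces.copy()
    if well_column is None or well_column not in traces.columns:
        traces["_well"] = 0
        well_column = "_well"
    apoptosis = apoptosis or {}
    mitosis = mitosis or {}

    events = events.sort_values(["track_id", "frame"])
    first_event = events.groupby("track_id")["frame"].first()
    second_event = events.groupby("track_id")["frame"].apply(
        lambda s: s.iloc[1] if len(s) > 1 else np.nan).dropna()
    event_cells = set(first_event.index)

    out_rows = []
    excluded: dict[str, list] = {"late_entry": [], "low_egfp": [], "no_t0": []}
    for well, wgrp in traces.groupby(well_column):
        controls = [tid for tid in wgrp["track_id"].unique() if tid not in event_cells]
        if len(controls) < min_controls:
            warnings.warn(
                f"well {well!r}: only {len(controls)} control cells "
                f"(< {min_controls}); bleach correction skipped",
                stacklevel=2,
            )
            control_curve = None
        else:
            ctrl = wgrp[wgrp["track_id"].isin(controls)]
            normed = []
            for _, cg in ctrl.groupby("track_id"):
                cg = cg.sort_values("frame")
                v0 = cg[value_column].iloc[0]
                if not np.isfinite(v0) or v0 == 0:
                    continue
                normed.append(pd.Series(cg[value_column].to_numpy() / v0, index=cg["frame"]))
            control_curve = pd.concat(normed, axis=1).mean(axis=1) if normed else None

        for tid in sorted(set(wgrp["track_id"]) & event_cells):
            cg = wgrp[wgrp["track_id"] == tid].sort_values("frame")
            if cg["frame"].iloc[0] > late_entry_frame:
                excluded["late_entry"].append(tid)
                continue
            raw = cg[value_column].to_numpy(dtype=float)
            if low_egfp_threshold is not None and np.nanmean(raw[: late_entry_frame + 1]) < low_egfp_threshold:
                excluded["low_egfp"].append(tid)
                continue
            frames = cg["frame"].to_numpy()
            vals = raw.copy()
            if control_curve is not None:
                denom = control_curve.reindex(frames).to_numpy()
                with np.errstate(divide="ignore", invalid="ignore"):
                    vals = np.where(np.abs(denom) > 1e-9, vals / denom, np.nan)
            if mitosis_correction is not None and tid in mitosis:
                vals = _apply_mitosis_correction(vals, frames, mitosis[tid], mitosis_correction)

            t_ev = int(first_event.loc[tid])
            keep = np.ones(frames.size, dtype=bool)
            if tid in second_event.index and np.isfinite(second_event.loc[tid]):
                keep &= frames <= int(second_event.loc[tid])
            if tid in apoptosis:
                keep &= frames < int(apoptosis[tid]) - apoptosis_mask_frames
            at0 = np.flatnonzero(frames == t_ev)
            if at0.size == 0 or not np.isfinite(vals[at0[0]]) or vals[at0[0]] == 0:
                excluded["no_t0"].append(tid)
                continue
            vals = vals / vals[at0[0]]
            for fr, v, k in zip(frames, vals, keep):
                if k and np.isfinite(v):
                    out_rows.append((tid, int(fr - t_ev), (fr - t_ev) * frame_interval_min, float(v)))

    out = pd.DataFrame(out_rows, columns=["track_id", "rel_frame", "time_min", "rel_expression"])
    out.attrs["excluded"] = excluded
    return out


def _apply_mitosis_correction(vals, frames, mitosis_frame, correction):
    half = len(correction) // 2
    vals = vals.copy()
    for j, fr in enumerate(frames):
        off = int(fr) - int(mitosis_frame)
        if -half <= off <= half:
            c = correction[off + half]
            if c != 0:
                vals[j] = vals[j] / c
    return vals


# ---------------------------------------------------------------------------
# dose stratification


def group_by_magnitude(
    releases: pd.DataFrame,
    corrected: pd.DataFrame,
    r2_threshold: float = 0.3,
    n_groups: int = 5,
    ci_level: float = 0.80,
) -> list[QuantileGroup]:
    """Split cells into ``n_groups`` equal-size groups by release magnitude.

    ``releases`` needs columns ``track_id, peak_conc_nM, r_squared``;
    ``corrected`` is the long output of :func:`correct_expression`.  Cells
    below the R² threshold are discarded before grouping.  Per-group output
    includes the median/IQR magnitude and a mean expression curve with a
    t-interval CI across member cells.
    """
    from scipy import stats

    rel = releases[releases["r_squared"] >= r2_threshold].sort_values("peak_conc_nM")
    if len(rel) < n_groups:
        raise ValueError(f"only {len(rel)} cells pass the R² filter; need >= {n_groups}")
    chunks = [rel.iloc[ix] for ix in np.array_split(np.arange(len(rel)), n_groups)]

    wide = corrected.pivot_table(index="track_id", columns="rel_frame", values="rel_expression")
    groups = []
    for gi, chunk in enumerate(chunks):
        ids = list(chunk["track_id"])
        member = wide.reindex(ids)
        times = member.columns.to_numpy(dtype=float)
        curves = member.to_numpy(dtype=float)
        mean = np.nanmean(curves, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sem = stats.sem(curves, axis=0, nan_policy="omit")
            cnt = np.sum(np.isfinite(curves), axis=0)
        tcrit = stats.t.ppf(0.5 + ci_level / 2, np.maximum(cnt - 1, 1))
        conc = chunk["peak_conc_nM"].to_numpy()
        groups.append(QuantileGroup(
            index=gi,
            track_ids=ids,
            median_conc=float(np.median(conc)),
            conc_iqr=(float(np.percentile(conc, 25)), float(np.percentile(conc, 75))),
            mean_r2=float(chunk["r_squared"].mean()),
            times=times,
            mean_curve=mean,
            ci_lo=mean - tcrit * sem,
            ci_hi=mean + tcrit * sem,
            member_curves=curves,
        ))
    return groups


# ---------------------------------------------------------------------------
# 4PL dose-response


def _fourpl(logx, bottom, log_ic50, hill):
    return bottom + (1.0 - bottom) / (1.0 + 10 ** ((log_ic50 - logx) * hill))


def fit_4pl(
    dose,
    response,
    bootstrap_reps: int = 0,
    ci_level: float = 0.95,
    seed: int | None = None,
    timepoint_h: float | None = None,
) -> FourPLFit:
    """Constrained 4PL fit on log10(dose): top fixed at 1, bottom in [0, 1].

    The relative IC50 is the fitted midpoint parameter; the absolute IC50 is
    the dose at which the fitted curve crosses 0.5 (NaN when bottom >= 0.5).
    Optional bootstrap (resampling cells) yields percentile CIs.
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    ok = np.isfinite(dose) & np.isfinite(response) & (dose > 0)
    dose, response = dose[ok], response[ok]
    if len(np.unique(dose)) < 4:
        raise ValueError("need at least 4 distinct positive dose levels")

    logx = np.log10(dose)
    fitres = _fit_4pl_arrays(logx, response)
    if fitres is None:
        return FourPLFit(1.0, float("nan"), float("nan"), float("nan"), float("nan"),
                         timepoint_h=timepoint_h, n=len(dose), degenerate=True)
    bottom, log_ic50, hill = fitres
    fit = FourPLFit(
        top=1.0, bottom=bottom, hillslope=hill,
        ic50_relative=10 ** log_ic50,
        ic50_absolute=_absolute_ic50_4pl(bottom, log_ic50, hill),
        timepoint_h=timepoint_h, n=len(dose),
    )
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        rel, absol = [], []
        for _ in range(bootstrap_reps):
            ix = rng.integers(0, len(dose), len(dose))
            res = _fit_4pl_arrays(logx[ix], response[ix])
            if res is None:
                continue
            b, l50, h = res
            rel.append(10 ** l50)
            absol.append(_absolute_ic50_4pl(b, l50, h))
        q = [50 * (1 - ci_level), 50 * (1 + ci_level)]
        if rel:
            fit.ci_relative = tuple(np.percentile(rel, q))
        absol = [a for a in absol if np.isfinite(a)]
        if absol:
            fit.ci_absolute = tuple(np.percentile(absol, q))
    return fit


def _fit_4pl_arrays(logx, y):
    p0 = [max(min(np.min(y), 0.9), 0.0), float(np.median(logx)), -1.0]
    try:
        popt, _ = curve_fit(
            _fourpl, logx, y, p0=p0,
            bounds=([0.0, logx.min() - 3, -10.0], [1.0, logx.max() + 3, -0.01]),
            maxfev=5000,
        )
    except RuntimeError:
        return None
    return float(popt[0]), float(popt[1]), float(popt[2])


def _absolute_ic50_4pl(bottom, log_ic50, hill):
    if bottom >= 0.5:
        return float("nan")
    u = 0.5 / (0.5 - bottom)
    return float(10 ** (log_ic50 - math.log10(u) / hill))


def ic50_timecourse(
    cells: pd.DataFrame,
    timepoints_h,
    dose_column: str = "peak_conc_nM",
    frame_interval_min: float = 5.0,
    min_cells: int = 20,
    bootstrap_reps: int = 200,
    ci_level: float = 0.80,
    seed: int | None = None,
) -> list[FourPLFit]:
    """Per-timepoint 4PL IC50s from single-cell dose/expression data.

    ``cells`` is long format with columns ``track_id, time_min,
    rel_expression`` plus a per-cell dose column (repeated per row or
    supplied via a separate merge beforehand).
    """
    fits = []
    for tp in np.atleast_1d(timepoints_h):
        target_min = tp * 60.0
        sub = cells.loc[np.isclose(cells["time_min"], target_min)]
        if sub.empty:
            # nearest available frame within half a frame interval
            idx = (cells["time_min"] - target_min).abs() <= frame_interval_min / 2
            sub = cells.loc[idx]
        sub = sub.dropna(subset=[dose_column, "rel_expression"])
        if len(sub) < min_cells:
            warnings.warn(f"timepoint {tp} h: only {len(sub)} cells; skipped", stacklevel=2)
            continue
        fits.append(fit_4pl(
            sub[dose_column], sub["rel_expression"],
            bootstrap_reps=bootstrap_reps, ci_level=ci_level, seed=seed,
            timepoint_h=float(tp),
        ))
    return fits


# ---------------------------------------------------------------------------
# kinetic model fitting


def fit_kinetic_model(
    groups,
    delta_p: float = DEFAULT_DELTA_P,
    ic50_time_h: float = 10.0,
    bootstrap_reps: int = 200,
    ci_level: float = 0.95,
    seed: int | None = None,
    x0: KineticModel | None = None,
) -> dict:
    """Fit the knockdown ODE to dose-group mean curves.

    ``groups`` is a sequence of :class:`QuantileGroup` (or dicts with keys
    ``median_conc``, ``times`` (min or h, see below), ``mean_curve``, and
    optionally ``member_curves`` for bootstrapping).  Group times are taken
    in hours if max(times) < 50, else interpreted as minutes.

    Returns a dict with the fitted :class:`KineticModel`, the model-based
    absolute IC50 at ``ic50_time_h`` and a bootstrap CI (cells resampled
    within groups).
    """
    parsed = []
    for g in groups:
        if isinstance(g, QuantileGroup):
            dose, times, curve, members = g.median_conc, g.times, g.mean_curve, g.member_curves
        else:
            dose, times, curve = g["median_conc"], np.asarray(g["times"], float), np.asarray(g["mean_curve"], float)
            members = g.get("member_curves")
        times = np.asarray(times, dtype=float)
        if times.max() >= 50:  # minutes
            times = times / 60.0
        keep = (times >= 0) & np.isfinite(curve)
        parsed.append((float(dose), times[keep], np.asarray(curve, float)[keep],
                       None if members is None else np.asarray(members, float)[:, keep]))

    if len(parsed) < 3:
        raise ValueError("need at least 3 dose groups")

    model = _fit_groups(parsed, delta_p, x0=x0)
    ic50 = model.absolute_ic50(ic50_time_h)

    boot_ic50: list[float] = []
    failures = 0
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        for _ in range(bootstrap_reps):
            resampled = []
            for dose, times, curve, members in parsed:
                if members is None or members.shape[0] < 2:
                    resampled.append((dose, times, curve, None))
                    continue
                ix = rng.integers(0, members.shape[0], members.shape[0])
                resampled.append((dose, times, np.nanmean(members[ix], axis=0), None))
            try:
                m = _fit_groups(resampled, delta_p, x0=model, max_nfev=60)
                v = m.absolute_ic50(ic50_time_h)
                if np.isfinite(v):
                    boot_ic50.append(v)
                else:
                    failures += 1
            except Exception:
                failures += 1
    result = {
        "model": model,
        "ic50_absolute": ic50,
        "ic50_time_h": ic50_time_h,
        "bootstrap_failures": failures,
        "bootstrap_ic50": np.asarray(boot_ic50),
    }
    if boot_ic50:
        q = [50 * (1 - ci_level), 50 * (1 + ci_level)]
        result["ic50_ci"] = tuple(np.percentile(boot_ic50, q))
        result["ic50_median"] = float(np.median(boot_ic50))
    return result


def _fit_groups(parsed, delta_p, x0: KineticModel | None = None, max_nfev: int | None = None) -> KineticModel:
    x0 = x0 or KineticModel(delta_p=delta_p)
    theta0 = np.log([x0.delta_m, x0.v_max, x0.K, x0.n, max(x0.lambda_s, 1e-3)])

    def residuals(theta):
        dm, vmax, K, n, lam = np.exp(theta)
        m = KineticModel(delta_m=dm, v_max=vmax, K=K, n=n, lambda_s=lam, delta_p=delta_p)
        res = []
        for dose, times, curve, _ in parsed:
            res.append(m.relative_expression(dose, times) - curve)
        return np.concatenate(res)

    sol = least_squares(
        residuals, theta0, method="lm" if max_nfev is None else "lm",
        max_nfev=max_nfev or 400,
    )
    dm, vmax, K, n, lam = np.exp(sol.x)
    fitted = KineticModel(delta_m=dm, v_max=vmax, K=K, n=n, lambda_s=lam, delta_p=delta_p)
    flat = float(np.ptp(np.concatenate([c for _, _, c, _ in parsed])))
    if flat < 1e-3:
        warnings.warn("knockdown curves are flat; kinetic fit is non-identifiable", stacklevel=2)
    return fitted
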
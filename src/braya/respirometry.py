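"""Closed respirometry: rates, corrections, batch standardization, and P_crit.

Raw per-well oxygen traces (% air saturation vs time) become corrected,
mass-specific, batch-standardized respiration rates in four steps: an OLS
slope per well, subtraction of the film diffusion rate (measured in a sealed
no-animal run) and of the per-run microbial background rate (blank wells),
division by allometric dry weight, and a reference-clone batch correction.
The critical oxygen limit P_crit is estimated from a rate-vs-O2 profile with
a two-segment ("broken stick") least-squares fit, with a reached / not-reached
call from an F-test against the single-line fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometricModel",
    "DEFAULT_ALLOMETRY",
    "OxygenTrace",
    "RateEstimate",
    "CorrectedRate",
    "BrokenStickModel",
    "BrokenStickResults",
    "estimate_rate",
    "diffusion_rate",
    "background_rate",
    "correct_rate",
    "dry_weight",
    "run_bias",
    "standardize_rates",
    "rate_o2_profile",
    "pcrit_broken_stick",
    "reached_pcrit_coding",
    "respiration_pipeline",
    "load_traces",
]

ROLES = ("experimental", "blank", "reference", "diffusion_control")


@dataclass(frozen=True)
class AllometricModel:
    """Length-weight model: dry weight = a * length**b (length in mm)."""

    a: float = 9.015362
    b: float = 2.86448

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("allometric coefficient a must be positive")


#: Length-weight model fitted for the study lake's Daphnia population.
DEFAULT_ALLOMETRY = AllometricModel()


def dry_weight(length_mm: float, model: AllometricModel = DEFAULT_ALLOMETRY) -> float:
    """Allometric dry weight from body length; strictly increasing for length > 0."""
    length = np.asarray(length_mm, dtype=float)
    if np.any(length < 0):
        raise ValueError("body length must be non-negative")
    out = model.a * length**model.b
    return float(out) if np.isscalar(length_mm) or out.ndim == 0 else out


@dataclass
class OxygenTrace:
    """One well's oxygen time series with its experimental-design metadata."""

    well_id: str
    run_id: str
    batch_id: str
    role: str
    time_h: np.ndarray
    o2: np.ndarray  # % air saturation
    body_length_mm: float | None = None
    clone: str | None = None
    subpopulation: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        order = np.argsort(self.time_h)
        self.time_h = np.asarray(self.time_h, dtype=float)[order]
        self.o2 = np.asarray(self.o2, dtype=float)[order]
        if len(self.time_h) != len(self.o2):
            raise ValueError("time and O2 arrays differ in length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError(f"well {self.well_id}: time must be strictly increasing")
        if np.any(self.o2 < 0):
            raise ValueError(f"well {self.well_id}: O2 must be non-negative")


@dataclass
class RateEstimate:
    """OLS consumption rate (positive magnitude of the O2-vs-time slope)."""

    rate: float  # % air sat per hour, consumption-positive
    slope: float
    intercept: float
    r2: float
    n_points: int
    window: tuple[float, float]


def estimate_rate(trace: OxygenTrace, window: tuple[float, float] | None = None) -> RateEstimate:
    """Ordinary least-squares O2 decline rate over ``window`` (default: full trace)."""
    t, y = trace.time_h, trace.o2
    if window is not None:
        lo, hi = window
        if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise ValueError("fit window must lie within the trace time span")
        mask = (t >= lo) & (t <= hi)
        t, y = t[mask], y[mask]
    if len(t) < 3:
        raise ValueError("rate estimation needs at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance in fit window")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    return RateEstimate(
        rate=float(-slope),
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        n_points=len(t),
        window=(float(t[0]), float(t[-1])),
    )


def diffusion_rate(controls: Sequence[OxygenTrace]) -> float:
    """Mean O2 decline rate over the sealed no-animal wells (film diffusion)."""
    controls = list(controls)
    if not controls:
        raise ValueError("diffusion_rate requires at least one diffusion-control trace")
    for tr in controls:
        if tr.role != "diffusion_control":
            raise ValueError(f"well {tr.well_id} has role {tr.role!r}, not diffusion_control")
    return float(np.mean([estimate_rate(tr).rate for tr in controls]))


def background_rate(blanks: Sequence[OxygenTrace]) -> float:
    """Mean decline rate of one run's blank wells (microbial background)."""
    blanks = list(blanks)
    if not blanks:
        raise ValueError("background_rate requires at least one blank trace")
    runs = {tr.run_id for tr in blanks}
    if len(runs) > 1:
        raise ValueError(f"blanks span multiple runs {sorted(runs)}; average within one run")
    for tr in blanks:
        if tr.role != "blank":
            raise ValueError(f"well {tr.well_id} has role {tr.role!r}, not blank")
    return float(np.mean([estimate_rate(tr).rate for tr in blanks]))


@dataclass(frozen=True)
class CorrectedRate:
    value: float
    flagged_negative: bool


def correct_rate(raw: float, diffusion: float, background: float) -> CorrectedRate:
    """Subtract diffusion and background from a raw rate; negative results are kept but flagged."""
    value = float(raw - diffusion - background)
    return CorrectedRate(value=value, flagged_negative=value < 0)


def run_bias(ref_rates_by_run: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-run batch bias of the reference clone.

    bias = |mean(ref, run) - mean(ref, overall)| / mean(ref, overall), with the
    overall mean pooled over every reference measurement.  Also tabulates the
    ratio factor mean(ref, overall) / mean(ref, run) used by ratio-mode
    standardization.
    """
    if not ref_rates_by_run:
        raise ValueError("no reference-clone rates supplied")
    for run, vals in ref_rates_by_run.items():
        if len(list(vals)) == 0:
            raise ValueError(f"run {run!r} has no reference-clone replicates")
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in ref_rates_by_run.values()])
    grand = float(pooled.mean())
    if grand <= 0:
        raise ValueError("overall reference mean must be positive")
    rows = []
    for run, vals in ref_rates_by_run.items():
        m = float(np.mean(vals))
        rows.append(
            {
                "run_id": run,
                "ref_run_mean": m,
                "ref_overall_mean": grand,
                "bias": abs(m - grand) / grand,
                "ratio_factor": grand / m,
            }
        )
    return pd.DataFrame(rows).set_index("run_id")


def standardize_rates(
    records: pd.DataFrame, biases: pd.DataFrame, mode: str = "ratio"
) -> pd.DataFrame:
    """Batch-standardize mass-specific rates against the reference clone.

    ``mode='ratio'`` (default) multiplies each rate by
    mean(ref, overall) / mean(ref, run), which equalizes the reference clone's
    run means by construction.  ``mode='literal'`` multiplies by the
    dimensionless bias itself.
    """
    if mode not in ("ratio", "literal"):
        raise ValueError("mode must be 'ratio' or 'literal'")
    out = records.copy()
    unknown = set(out["run_id"]) - set(biases.index)
    if unknown:
        raise KeyError(f"runs missing from the bias table: {sorted(unknown)}")
    factor = biases["ratio_factor"] if mode == "ratio" else biases["bias"]
    out["resp_standard"] = out["mass_specific_rate"].to_numpy() * factor.loc[
        out["run_id"]
    ].to_numpy()
    out["standardization_mode"] = mode
    return out


def rate_o2_profile(
    trace: OxygenTrace, window_points: int = 10, step: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Rolling-window rate-vs-O2 profile for P_crit estimation.

    OLS slope over each sliding window of ``window_points`` samples, paired
    with the window's mean O2; returned ordered by declining O2.
    """
    t, y = trace.time_h, trace.o2
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    if len(t) < window_points:
        raise ValueError("trace shorter than one window")
    o2s, rates = [], []
    for start in range(0, len(t) - window_points + 1, step):
        sl = slice(start, start + window_points)
        slope, _ = np.polyfit(t[sl], y[sl], 1)
        o2s.append(float(y[sl].mean()))
        rates.append(float(-slope))
    o2s = np.asarray(o2s)
    rates = np.asarray(rates)
    order = np.argsort(-o2s)
    return o2s[order], rates[order]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(((y - (slope * x + intercept)) ** 2).sum())
    return float(slope), float(intercept), rss


@dataclass
class BrokenStickResults:
    """Two-segment least-squares fit of a rate-vs-O2 profile."""

    pcrit: float | None
    breakpoint_index: int | None
    left: tuple[float, float, float] | None  # slope, intercept, RSS (high-O2 side)
    right: tuple[float, float, float] | None
    rss: float | None
    single_rss: float | None
    f_stat: float | None
    p_value: float | None
    reached: bool
    reason: str
    n_points: int
    o2: np.ndarray = field(repr=False, default=None)
    rate: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Broken-stick P_crit fit",
            f"  n points          : {self.n_points}",
            f"  reached P_crit    : {self.reached} ({self.reason})",
        ]
        if self.pcrit is not None:
            lines += [
                f"  P_crit            : {self.pcrit:.3f} % air saturation",
                f"  segment slopes    : {self.left[0]:.5g} (oxyregulating), {self.right[0]:.5g} (declining)",
                f"  two-segment RSS   : {self.rss:.5g} (single line {self.single_rss:.5g})",
                f"  F-test            : F = {self.f_stat:.4g}, p = {self.p_value:.4g}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Profile with the two fitted segments and the P_crit location."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.o2, self.rate, "o", ms=4, color="0.4", label="profile")
        if self.breakpoint_index is not None:
            b = self.breakpoint_index
            for (slope, icpt, _), seg in ((self.left, self.o2[:b]), (self.right, self.o2[b:])):
                xs = np.linspace(seg.min(), seg.max(), 20)
                ax.plot(xs, slope * xs + icpt, "-", lw=2)
            if self.pcrit is not None:
                ax.axvline(self.pcrit, ls="--", color="crimson",
                           label=f"P_crit = {self.pcrit:.1f}")
        ax.set_xlabel("O2 (% air saturation)")
        ax.set_ylabel("respiration rate")
        ax.invert_xaxis()
        ax.legend()
        return ax


class BrokenStickModel:
    """Broken-stick (two-segment) model of a rate-vs-O2 profile.

    The breakpoint is found by exhaustive search over every admissible split
    (each segment keeping at least ``min_segment`` points), minimizing the
    total residual sum of squares of the two independent OLS lines.  P_crit is
    the O2 at the intersection of the fitted lines, falling back to the O2 of
    the breakpoint observation when the intersection lies outside the profile
    span or the slopes are parallel.
    """

    def __init__(self, o2: Sequence[float], rate: Sequence[float]):
        o2 = np.asarray(o2, dtype=float)
        rate = np.asarray(rate, dtype=float)
        if o2.shape != rate.shape or o2.ndim != 1:
            raise ValueError("o2 and rate must be 1-D arrays of equal length")
        order = np.argsort(-o2)  # declining O2
        self.o2 = o2[order]
        self.rate = rate[order]

    def fit(self, min_segment: int = 3, alpha: float = 0.05) -> BrokenStickResults:
        o2, rate = self.o2, self.rate
        n = len(o2)
        if n < 2 * min_segment:
            return BrokenStickResults(
                pcrit=None, breakpoint_index=None, left=None, right=None,
                rss=None, single_rss=None, f_stat=None, p_value=None,
                reached=False, reason="insufficient_data", n_points=n,
                o2=o2, rate=rate,
            )
        _, _, single_rss = _ols(o2, rate)
        best = None
        for b in range(min_segment, n - min_segment + 1):
            left = _ols(o2[:b], rate[:b])
            right = _ols(o2[b:], rate[b:])
            total = left[2] + right[2]
            if best is None or total < best[0] - 1e-15:
                best = (total, b, left, right)
        total_rss, b, left, right = best

        # P_crit: intersection of the two lines, else the breakpoint's O2
        ml, cl = left[0], left[1]
        mr, cr = right[0], right[1]
        if abs(ml - mr) > 1e-12:
            x = (cr - cl) / (ml - mr)
            pcrit = float(x) if o2.min() - 1e-9 <= x <= o2.max() + 1e-9 else float(o2[b])
        else:
            pcrit = float(o2[b])

        # reached: two segments beat the single line (extra-SS F test) with
        # genuinely distinct slopes
        df2 = n - 4
        scale = max(abs(ml), abs(mr), 1e-12)
        distinct = abs(ml - mr) > 1e-8 * scale
        if df2 <= 0:
            f_stat, p_value = None, None
            reached, reason = False, "insufficient_data"
        elif total_rss <= 1e-12 * max(single_rss, 1.0):
            if single_rss <= 1e-12:
                f_stat, p_value = 0.0, 1.0
                reached, reason = False, "no_breakpoint"
            else:
                f_stat, p_value = np.inf, 0.0
                reached, reason = distinct, ("reached" if distinct else "no_breakpoint")
        else:
            f_stat = ((single_rss - total_rss) / 2.0) / (total_rss / df2)
            p_value = float(stats.f.sf(f_stat, 2, df2))
            reached = bool(p_value < alpha and distinct)
            reason = "reached" if reached else "no_breakpoint"
        return BrokenStickResults(
            pcrit=pcrit, breakpoint_index=b, left=left, right=right,
            rss=total_rss, single_rss=single_rss, f_stat=f_stat, p_value=p_value,
            reached=reached, reason=reason, n_points=n, o2=o2, rate=rate,
        )


def pcrit_broken_stick(
    o2: Sequence[float],
    rate: Sequence[float],
    min_segment: int = 3,
    alpha: float = 0.05,
) -> BrokenStickResults:
    """Convenience wrapper: fit :class:`BrokenStickModel` on a profile."""
    return BrokenStickModel(o2, rate).fit(min_segment=min_segment, alpha=alpha)


def reached_pcrit_coding(results: Iterable[BrokenStickResults]) -> pd.DataFrame:
    """Binary success/failure coding of reaching P_crit, one row per animal."""
    rows = [{"reached": int(r.reached), "reason": r.reason, "pcrit": r.pcrit if r.reached else np.nan}
            for r in results]
    df = pd.DataFrame(rows, columns=["reached", "reason", "pcrit"])
    df.attrs["proportion_reached"] = float(df["reached"].mean()) if len(df) else np.nan
    return df


def respiration_pipeline(
    traces: Sequence[OxygenTrace],
    reference_clone: str,
    mode: str = "ratio",
    allometry: AllometricModel = DEFAULT_ALLOMETRY,
    rate_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Raw traces to standardized mass-specific rates, with per-stage provenance.

    Diffusion is measured batch-wide from the diffusion-control wells in
    ``traces``; background per run from that run's blanks; corrected rates are
    divided by allometric dry weight and standardized on the reference clone.
    """
    controls = [t for t in traces if t.role == "diffusion_control"]
    diff = diffusion_rate(controls) if controls else 0.0
    animals = [t for t in traces if t.role in ("experimental", "reference")]
    blanks_by_run: dict[str, list[OxygenTrace]] = {}
    for t in traces:
        if t.role == "blank":
            blanks_by_run.setdefault(t.run_id, []).append(t)

    rows = []
    for tr in animals:
        est = estimate_rate(tr, window=rate_window)
        # blanks are sealed wells too: their measured decline already contains
        # film diffusion, so the microbial background is the blank rate net of it
        bg = (
            background_rate(blanks_by_run[tr.run_id]) - diff
            if tr.run_id in blanks_by_run
            else 0.0
        )
        corrected = correct_rate(est.rate, diff, bg)
        if tr.body_length_mm is None:
            raise ValueError(f"well {tr.well_id}: body length required for mass-specific rate")
        dw = dry_weight(tr.body_length_mm, allometry)
        rows.append(
            {
                "well_id": tr.well_id,
                "run_id": tr.run_id,
                "batch_id": tr.batch_id,
                "clone": tr.clone,
                "subpopulation": tr.subpopulation,
                "role": tr.role,
                "body_length_mm": tr.body_length_mm,
                "raw_rate": est.rate,
                "diffusion_adjusted_rate": est.rate - diff,
                "background_adjusted_rate": corrected.value,
                "negative_rate_flag": corrected.flagged_negative,
                "dry_weight": dw,
                "mass_specific_rate": corrected.value / dw,
                "corrections": "raw>diffusion>background>mass_specific",
            }
        )
    records = pd.DataFrame(rows)
    ref = records[records["clone"] == reference_clone]
    if ref.empty:
        raise ValueError(f"reference clone {reference_clone!r} absent from the traces")
    missing = set(records["run_id"]) - set(ref["run_id"])
    if missing:
        raise ValueError(f"reference clone missing from runs: {sorted(missing)}")
    biases = run_bias(
        {run: grp["mass_specific_rate"].to_list() for run, grp in ref.groupby("run_id")}
    )
    out = standardize_rates(records, biases, mode=mode)
    out["corrections"] = out["corrections"] + ">standardize[" + mode + "]"
    out.attrs["diffusion_rate"] = diff
    out.attrs["bias_table"] = biases
    return out


def load_traces(traces_csv: str, wells_csv: str | None = None) -> list[OxygenTrace]:
    """Read long-format trace CSV (+ optional well metadata CSV) into traces.

    ``traces_csv`` columns: well_id, run_id, batch_id, role, time_h,
    o2_percent_airsat.  ``wells_csv`` columns: well_id, clone, subpopulation,
    body_length_mm.
    """
    df = pd.read_csv(traces_csv)
    meta = pd.read_csv(wells_csv).set_index("well_id") if wells_csv else None
    traces = []
    for well, grp in df.groupby("well_id", sort=False):
        kw = {}
        if meta is not None and well in meta.index:
            row = meta.loc[well]
            kw = {
                "body_length_mm": None if pd.isna(row.get("body_length_mm")) else float(row["body_length_mm"]),
                "clone": row.get("clone"),
                "subpopulation": row.get("subpopulation"),
            }
        traces.append(
            OxygenTrace(
                well_id=str(well),
                run_id=str(grp["run_id"].iloc[0]),
                batch_id=str(grp["batch_id"].iloc[0]),
                role=str(grp["role"].iloc[0]),
                time_h=grp["time_h"].to_numpy(),
                o2=grp["o2_percent_airsat"].to_numpy(),
                **kw,
            )
        )
    return traces
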
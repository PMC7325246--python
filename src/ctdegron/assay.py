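"""Reporter-assay quantification: OD normalization, percent-of-control,
degradation percentages, knockout recovery, decay-rate fits and the
fold-change / net-effect arithmetic used to reason about abundance vs
activity trade-offs."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, InvalidArgumentError

log = logging.getLogger(__name__)

TIMECOURSE_COLUMNS = ["time_h", "fluorescence", "od600",
                      "condition", "genotype", "replicate"]

GENOTYPES = ("WT", "dClpA", "dClpX", "dClpP", "dLon", "dClpP-dLon")
CONTROL_CONDITION = "untagged-control"

#: OD600 floor below which normalized points are masked.
DEFAULT_OD_FLOOR = 0.01


@dataclass
class TimeCourse:
    """Tidy reporter data: one row per (time, condition, genotype, replicate)."""

    df: pd.DataFrame
    genotype_vocabulary: tuple[str, ...] = GENOTYPES

    def __post_init__(self):
        missing = [c for c in TIMECOURSE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"time course missing column(s): {missing}")
        bad = sorted(set(self.df["genotype"]) - set(self.genotype_vocabulary))
        if bad:
            raise DataError(f"unknown genotype label(s): {bad}")
        for (cond, geno, rep), grp in self.df.groupby(
                ["condition", "genotype", "replicate"], sort=False):
            t = grp["time_h"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise DataError(
                    f"time not strictly increasing in ({cond}, {geno}, rep {rep})"
                )

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.df["condition"]))

    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.df["genotype"]))

    def subset(self, condition: str, genotype: str) -> "TimeCourse":
        sub = self.df[(self.df["condition"] == condition)
                      & (self.df["genotype"] == genotype)]
        if sub.empty:
            raise DataError(f"no rows for condition={condition!r}, genotype={genotype!r}")
        return TimeCourse(sub.reset_index(drop=True), self.genotype_vocabulary)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, **kwargs) -> "TimeCourse":
        df = pd.read_csv(path, sep="\t")
        return cls(df, **kwargs)


@dataclass
class NormalizedSeries:
    """Replicate-averaged fluorescence/OD600 with per-point spread."""

    time: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    n_masked: int = 0
    per_replicate: pd.DataFrame | None = field(default=None, repr=False)

    def value_at(self, t: float) -> float:
        """Linear interpolation at t; errors outside the observed range."""
        tmin, tmax = self.time[0], self.time[-1]
        if not (tmin <= t <= tmax):
            raise DataError(f"t={t} outside series range [{tmin}, {tmax}]")
        return float(np.interp(t, self.time, self.mean))


def normalize(tc: TimeCourse, od_floor: float = DEFAULT_OD_FLOOR) -> NormalizedSeries:
    """Per-point fluorescence / OD600, replicate-wise, then averaged.

    Points with OD600 below ``od_floor`` are masked (NaN) and logged;
    replicate means ignore masked values.
    """
    df = tc.df
    if df[["condition", "genotype"]].drop_duplicates().shape[0] > 1:
        raise InvalidArgumentError(
            "normalize expects a single (condition, genotype) series; use subset()"
        )
    work = df.copy()
    low = work["od600"] < od_floor
    n_masked = int(low.sum())
    if n_masked:
        log.warning("masking %d point(s) with OD600 below %.3g", n_masked, od_floor)
    work["normalized"] = np.where(low, np.nan,
                                  work["fluorescence"] / work["od600"])
    wide = work.pivot_table(index="time_h", columns="replicate",
                            values="normalized")
    time = wide.index.to_numpy(dtype=float)
    mean = wide.mean(axis=1, skipna=True).to_numpy()
    sd = wide.std(axis=1, ddof=1, skipna=True).fillna(0.0).to_numpy()
    keep = ~np.isnan(mean)
    return NormalizedSeries(time=time[keep], mean=mean[keep], sd=sd[keep],
                            n_replicates=wide.shape[1], n_masked=n_masked,
                            per_replicate=wide)


def percent_of_control(tagged: NormalizedSeries, control: NormalizedSeries,
                       t: float) -> float:
    """100 * tagged(t) / control(t), both linearly interpolated at t."""
    c = control.value_at(t)
    if c <= 0:
        raise DataError(f"control value at t={t} is nonpositive ({c})")
    return 100.0 * tagged.value_at(t) / c


def degradation_percent(tagged: NormalizedSeries, control: NormalizedSeries,
                        t: float) -> float:
    return 100.0 - percent_of_control(tagged, control, t)


@dataclass(frozen=True)
class DegradationResult:
    condition: str
    genotype: str
    endpoint_time: float
    percent_of_control: float
    decay_rate_estimate: float | None = None

    @property
    def degradation_percent(self) -> float:
        return 100.0 - self.percent_of_control


def quantify_degradation(tagged_tc: TimeCourse, control_tc: TimeCourse,
                         endpoint_time: float,
                         od_floor: float = DEFAULT_OD_FLOOR) -> DegradationResult:
    tagged = normalize(tagged_tc, od_floor)
    control = normalize(control_tc, od_floor)
    fit = fit_decay_rate(tagged)
    return DegradationResult(
        condition=tagged_tc.df["condition"].iloc[0],
        genotype=tagged_tc.df["genotype"].iloc[0],
        endpoint_time=endpoint_time,
        percent_of_control=percent_of_control(tagged, control, endpoint_time),
        decay_rate_estimate=fit.rate,
    )


def recovery_index(genotype_result: DegradationResult,
                   wt_result: DegradationResult) -> float:
    """Degradation lost in a knockout vs WT, in percentage points (>0 = recovery)."""
    if genotype_result.endpoint_time != wt_result.endpoint_time:
        raise InvalidArgumentError(
            f"endpoint mismatch: {genotype_result.endpoint_time} vs "
            f"{wt_result.endpoint_time}"
        )
    if genotype_result.condition != wt_result.condition:
        raise InvalidArgumentError(
            f"construct mismatch: {genotype_result.condition!r} vs "
            f"{wt_result.condition!r}"
        )
    return wt_result.degradation_percent - genotype_result.degradation_percent


@dataclass(frozen=True)
class DecayFit:
    rate: float | None
    r_squared: float | None
    flag: str | None = None  # None | "not-degrading" | "not-estimable"


def fit_decay_rate(series: NormalizedSeries, min_points: int = 3,
                   flat_tol: float = 1e-9) -> DecayFit:
    """First-order decay rate from the post-peak log-linear slope.

    The segment runs from the series maximum (inclusive) to the end and
    must contain at least ``min_points`` points after the peak. Returns
    the negated least-squares slope of log(mean) with its R².
    """
    y = series.mean
    if len(y) == 0:
        return DecayFit(None, None, "not-estimable")
    if float(y.max() - y.min()) <= flat_tol * max(abs(float(y.max())), 1.0):
        return DecayFit(0.0, None, "not-degrading")
    peak = int(np.argmax(y))
    if len(y) - 1 - peak < min_points:
        return DecayFit(None, None, "not-estimable")
    seg_t = series.time[peak:]
    seg_y = y[peak:]
    if np.any(seg_y <= 0):
        return DecayFit(None, None, "not-estimable")
    logy = np.log(seg_y)
    slope, intercept = np.polyfit(seg_t, logy, 1)
    pred = slope * seg_t + intercept
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(rate=-float(slope), r_squared=r2)


def _truncate2(x: float) -> float:
    """Floor at two decimals (display convention for printed folds)."""
    return math.floor(round(x * 100.0, 9)) / 100.0


@dataclass(frozen=True)
class FoldChange:
    before: float
    after: float
    fold: float
    direction: str  # "increase" | "decrease" | "none"
    display: float

    def __str__(self):
        if self.direction == "none":
            return f"{self.display:.2f}-fold (no change)"
        return f"{self.display:.2f}-fold {self.direction}"


def fold_change(before: float, after: float) -> FoldChange:
    """Ratio max/min of two positive values, with direction and the
    truncated-to-2-decimals display value used in printed summaries."""
    if before <= 0 or after <= 0:
        raise InvalidArgumentError("fold_change requires positive values")
    fold = max(before, after) / min(before, after)
    if after < before:
        direction = "decrease"
    elif after > before:
        direction = "increase"
    else:
        direction = "none"
    return FoldChange(before=before, after=after, fold=fold,
                      direction=direction, display=_truncate2(fold))


@dataclass(frozen=True)
class NetEffect:
    predicted_fold: float
    direction: str  # "increase" | "decrease" | "neutral"


def net_effect(abundance_fold_increase: float,
               activity_fold_decrease: float) -> NetEffect:
    """Predicted production fold when abundance rises but activity falls.

    Both inputs are ratios >= 1 in their stated directions; the predicted
    production change is their quotient.
    """
    if abundance_fold_increase < 1 or activity_fold_decrease < 1:
        raise InvalidArgumentError(
            "ratios must be >= 1; normalize direction before calling"
        )
    pred = abundance_fold_increase / activity_fold_decrease
    if pred > 1:
        direction = "increase"
    elif pred < 1:
        direction = "decrease"
    else:
        direction = "neutral"
    return NetEffect(predicted_fold=pred, direction=direction)
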
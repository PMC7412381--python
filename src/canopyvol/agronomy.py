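"""Plot-level agronomy: CVP computation, stage aggregation, yield grouping,
correlation analysis, and the exponential CC-CVP model.

The canopy volume parameter CVP = LAI x PH (leaf area index times plant
height in metres) is a proxy for canopy spatial volume per unit ground area:
LAI captures horizontal leaf-area expansion, PH the vertical dimension. Each
plot is observed at four growth stages (tillering, jointing, heading,
filling); canopy structure peaks at heading, so heading-stage values
(subscript HS) and four-stage means (subscript avg) are the candidate yield
predictors.

Canopy cover saturates as the canopy closes, so CC relates to CVP
exponentially rather than linearly:

    CVP = a * exp(b * CC)

fitted per variety by nonlinear least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateInputError, FitError, ValidationError
from .reference import VARIETY_TYPES, YIELD_CUTPOINTS

STAGES: tuple[str, ...] = ("tillering", "jointing", "heading", "filling")

#: Exact column set for sample tables read/written as delimited text.
SAMPLE_COLUMNS: tuple[str, ...] = (
    "plot_id",
    "site",
    "variety",
    "variety_type",
    "n_rate",
    "replicate",
    "stage",
    "lai",
    "ph",
    "cvp",
    "yield_kg_ha",
)


@dataclass(frozen=True)
class SampleRecord:
    """One plot x growth-stage observation."""

    plot_id: str
    site: str
    variety: str
    variety_type: str
    n_rate: float
    replicate: int
    stage: str
    lai: float
    ph: float
    cvp: float = field(default=math.nan)
    yield_kg_ha: float = math.nan

    def __post_init__(self):
        if self.lai < 0 or self.ph < 0:
            raise ValidationError(
                f"plot {self.plot_id}: LAI and PH must be non-negative"
            )
        if self.stage not in STAGES:
            raise ValidationError(f"unknown growth stage {self.stage!r}")
        expected_type = VARIETY_TYPES.get(self.variety)
        if expected_type is not None and expected_type != self.variety_type:
            raise ValidationError(
                f"variety {self.variety} is type {expected_type}, "
                f"not {self.variety_type}"
            )
        if math.isnan(self.cvp):
            object.__setattr__(self, "cvp", compute_cvp(self.lai, self.ph))
        elif not math.isclose(self.cvp, self.lai * self.ph, rel_tol=1e-9, abs_tol=1e-12):
            # exact on construction; a text round trip may carry rounding
            # at the last printed digit, which isclose absorbs
            raise ValidationError(
                f"plot {self.plot_id} stage {self.stage}: cvp {self.cvp} "
                f"!= lai x ph = {self.lai * self.ph}"
            )


@dataclass(frozen=True)
class PlotSummary:
    """Heading-stage and whole-period canopy parameters of one plot."""

    plot_id: str
    variety: str
    variety_type: str
    lai_hs: float
    ph_hs: float
    cvp_hs: float
    lai_avg: float
    ph_avg: float
    cvp_avg: float
    yield_kg_ha: float
    yield_level: str | None = None


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of CVP = a * exp(b * CC) for one subgroup."""

    a: float
    b: float
    r2: float
    subgroup: str
    n: int

    def predict(self, cc):
        return self.a * np.exp(self.b * np.asarray(cc, dtype=float))


def compute_cvp(lai: float, ph: float) -> float:
    """CVP = LAI x PH (PH in metres)."""
    if lai < 0 or ph < 0:
        raise ValidationError("LAI and PH must be non-negative")
    return lai * ph


def summarize_plot(records: list[SampleRecord]) -> PlotSummary:
    """Aggregate one plot's four stage records.

    Heading-stage values are copied; ``*_avg`` are arithmetic means over
    the four stages. ``cvp_avg`` is the mean of the per-stage CVPs, not
    lai_avg x ph_avg.
    """
    if not records:
        raise ValidationError("no records given")
    plot_id = records[0].plot_id
    seen = {r.stage for r in records}
    if len(records) != len(STAGES) or seen != set(STAGES):
        raise ValidationError(
            f"plot {plot_id}: expected one record per stage {STAGES}, "
            f"got stages {sorted(r.stage for r in records)}"
        )
    by_stage = {r.stage: r for r in records}
    hs = by_stage["heading"]
    return PlotSummary(
        plot_id=plot_id,
        variety=records[0].variety,
        variety_type=records[0].variety_type,
        lai_hs=hs.lai,
        ph_hs=hs.ph,
        cvp_hs=hs.cvp,
        lai_avg=float(np.mean([r.lai for r in records])),
        ph_avg=float(np.mean([r.ph for r in records])),
        cvp_avg=float(np.mean([r.cvp for r in records])),
        yield_kg_ha=records[0].yield_kg_ha,
        yield_level=(
            yield_level(records[0].yield_kg_ha, records[0].variety_type)
            if not math.isnan(records[0].yield_kg_ha)
            else None
        ),
    )


def summarize_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Plot summaries for a whole sample table (one row per plot)."""
    rows = []
    for plot_id, grp in samples.groupby("plot_id", sort=True):
        recs = [
            SampleRecord(
                plot_id=str(r.plot_id),
                site=str(r.site),
                variety=str(r.variety),
                variety_type=str(r.variety_type),
                n_rate=float(r.n_rate),
                replicate=int(r.replicate),
                stage=str(r.stage),
                lai=float(r.lai),
                ph=float(r.ph),
                cvp=float(r.cvp),
                yield_kg_ha=float(r.yield_kg_ha),
            )
            for r in grp.itertuples()
        ]
        rows.append(summarize_plot(recs).__dict__)
    return pd.DataFrame(rows)


def yield_level(yield_kg_ha: float, variety_type: str) -> str:
    """Group a plot yield into low / middle / high.

    Cut points are variety-type specific (A: 7500 and 8500 kg/ha; B: 6500
    and 7500 kg/ha). Intervals are half-open, lower bound inclusive:
    middle = [lower, upper), high = [upper, inf), so the line is
    partitioned and levels are monotone in yield.
    """
    if yield_kg_ha < 0:
        raise ValidationError("yield must be non-negative")
    try:
        lower, upper = YIELD_CUTPOINTS[variety_type]
    except KeyError:
        raise ValidationError(f"unknown variety type {variety_type!r}") from None
    if yield_kg_ha < lower:
        return "low"
    if yield_kg_ha < upper:
        return "middle"
    return "high"


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value (t transform,
    n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d sequences")
    if x.size < 3:
        raise ValidationError("correlation requires at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant sequence")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_r(x, y) -> tuple[float, float]:
    """Rank-correlation alternative, for sensitivity checks."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_table(
    summaries: pd.DataFrame, alpha: float = 0.01, method: str = "pearson"
) -> pd.DataFrame:
    """Canopy-parameter vs yield correlations per variety type.

    Returns one row per (variety_type, parameter) for the six parameters
    {lai, ph, cvp} x {hs, avg}, with the correlation against
    ``yield_kg_ha``, its p-value and a significance flag at ``alpha``.
    """
    corr = pearson_r if method == "pearson" else spearman_r
    params = ["lai_hs", "ph_hs", "cvp_hs", "lai_avg", "ph_avg", "cvp_avg"]
    rows = []
    for vtype, grp in summaries.groupby("variety_type", sort=True):
        if len(grp) < 3:
            raise ValidationError(
                f"variety type {vtype}: need >= 3 plots, got {len(grp)}"
            )
        for p in params:
            r, pval = corr(grp[p].to_numpy(), grp["yield_kg_ha"].to_numpy())
            rows.append(
                {
                    "variety_type": vtype,
                    "parameter": p,
                    "r": r,
                    "p_value": pval,
                    "significant": pval < alpha,
                    "n": len(grp),
                }
            )
    return pd.DataFrame(rows)


def fit_exponential(cc, cvp, subgroup: str = "") -> ExponentialFit:
    """Fit CVP = a * exp(b * CC) by nonlinear least squares.

    The fit is on the original scale, initialised from the log-linear
    regression of ln(CVP) on CC; R^2 is reported against the fitted curve
    (1 - SS_res / SS_tot).
    """
    cc = np.asarray(cc, dtype=float)
    cvp = np.asarray(cvp, dtype=float)
    if cc.shape != cvp.shape or cc.size < 3:
        raise ValidationError("need >= 3 paired (cc, cvp) points")
    if np.any(cvp <= 0):
        raise ValidationError("cvp values must be positive for the exponential fit")

    slope, intercept = np.polyfit(cc, np.log(cvp), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(b * x), cc, cvp, p0=p0, maxfev=10_000
            )
    except RuntimeError as exc:
        raise FitError(f"exponential fit failed to converge: {exc}", params=p0)
    a, b = float(popt[0]), float(popt[1])
    pred = a * np.exp(b * cc)
    ss_res = float(np.sum((cvp - pred) ** 2))
    ss_tot = float(np.sum((cvp - cvp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExponentialFit(a=a, b=b, r2=r2, subgroup=subgroup, n=int(cc.size))


def read_samples(path) -> pd.DataFrame:
    """Read a sample table from delimited text, validating the header."""
    df = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)
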
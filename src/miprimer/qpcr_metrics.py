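"""qPCR validation arithmetic: efficiency, cross-reactivity, false positives.

A standard curve regresses mean Cq on log10 template copies over a
dilution series; its slope S gives the amplification efficiency
(10^(-1/S) - 1) * 100%.  Cross-reactivity of a primer pair against a
heterologous template is 10^(dCq/S) * 100% with dCq = Cq_mm - Cq_pm, and
the no-template-control false-positive rate is simply the fraction of NTC
wells that amplified at any Cq.

Note that the often-quoted rule "dCq > 4 means < 5% cross-reactivity"
holds only for slopes shallower than about -3.01 Cq/log10; with the
canonical -3.3219 slope, dCq = 4 corresponds to 6.25%.  The formula is
evaluated literally here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class MetricsError(ValueError):
    pass


@dataclass
class StandardCurve:
    slope: float  # Cq per log10(copies)
    intercept: float
    r_squared: float
    efficiency: float  # percent
    points: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


@dataclass
class CrossReactivityRecord:
    cq_pm: float
    cq_mm: float
    slope: float
    capped: bool = False

    @property
    def delta_cq(self) -> float:
        return self.cq_mm - self.cq_pm

    @property
    def percent(self) -> float:
        return cross_reactivity(self.cq_mm, self.cq_pm, self.slope)


@dataclass
class NtcResult:
    p_ntc: int
    n: int

    def __post_init__(self):
        if not (0 <= self.p_ntc <= self.n) or self.n <= 0:
            raise MetricsError(f"invalid NTC counts {self.p_ntc}/{self.n}")

    @property
    def rate(self) -> float:
        return false_positive_rate(self.p_ntc, self.n)


def efficiency_from_slope(slope: float) -> float:
    """Percent qPCR efficiency from the standard-curve slope.

    (10^(-1/slope) - 1) * 100; a slope of -3.3219 (perfect doubling)
    gives 100%.
    """
    if slope >= 0:
        raise MetricsError(f"standard-curve slope must be negative, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(
    points, per_replicate: bool = False
) -> StandardCurve:
    """Least-squares standard curve of mean Cq on log10 template copies.

    ``points`` is an iterable of (log10_copies, cq) pairs, a mapping
    log10_copies -> iterable of replicate Cq, or a DataFrame with
    ``log10_copies`` and ``cq`` columns.  By default replicates are
    averaged per dilution level before the fit (mean-Cq regression, the
    way titration plots report mean +/- SD); ``per_replicate=True`` fits
    every well instead.
    """
    if isinstance(points, pd.DataFrame):
        df = points[["log10_copies", "cq"]].copy()
    elif isinstance(points, dict):
        rows = [(x, c) for x, cqs in points.items() for c in np.atleast_1d(cqs)]
        df = pd.DataFrame(rows, columns=["log10_copies", "cq"])
    else:
        df = pd.DataFrame(list(points), columns=["log10_copies", "cq"])
    levels = df["log10_copies"].nunique()
    if levels < 3:
        raise MetricsError(f"need >= 3 dilution levels, got {levels}")
    if np.isclose(df["log10_copies"].std(), 0.0):
        raise MetricsError("zero variance in log10 copies")
    if per_replicate:
        fit_df = df
    else:
        fit_df = df.groupby("log10_copies", as_index=False)["cq"].mean()
    res = stats.linregress(fit_df["log10_copies"], fit_df["cq"])
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=efficiency_from_slope(float(res.slope)),
        points=df,
    )


def cross_reactivity(cq_mm: float, cq_pm: float, slope: float) -> float:
    """Percent cross-reactivity 10^((Cq_mm - Cq_pm)/S) * 100.

    Cq_mm is the Cq of the template against the heterologous primer pair,
    Cq_pm against its homologous pair, S the standard-curve slope.
    """
    if slope >= 0:
        raise MetricsError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** ((cq_mm - cq_pm) / slope) * 100.0


def cross_reactivity_record(
    cq_mm: float, cq_pm: float, slope: float
) -> CrossReactivityRecord:
    """Cross-reactivity with the reporting cap at 100%.

    A heterologous template amplifying earlier than the homologous one
    (dCq < 0) signals a design failure; the record is capped at 100% and
    flagged rather than reported above unity.
    """
    rec = CrossReactivityRecord(cq_pm=cq_pm, cq_mm=cq_mm, slope=slope)
    if rec.delta_cq < 0:
        rec.capped = True
    return rec


def false_positive_rate(p_ntc: int, n: int) -> float:
    """Percent of no-template-control reactions that amplified (any Cq)."""
    if n <= 0:
        raise MetricsError("total reaction count must be positive")
    if not (0 <= p_ntc <= n):
        raise MetricsError(f"positive NTC count {p_ntc} outside [0, {n}]")
    return 100.0 * p_ntc / n


# ---------------------------------------------------------------------------
# well-table workflows (delimited text in, metrics tables out)

WELL_COLUMNS = ["assay_id", "template_id", "cq", "is_ntc", "log10_copies"]


def read_wells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise MetricsError(f"well table missing columns: {sorted(missing)}")
    return df


def efficiency_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-assay standard curves from homologous, non-NTC wells."""
    rows = []
    sub = wells[(~wells["is_ntc"]) & wells["log10_copies"].notna()]
    for assay, grp in sub.groupby("assay_id"):
        grp = grp[grp["template_id"] == assay]
        if grp["log10_copies"].nunique() < 3:
            continue
        curve = fit_standard_curve(grp[["log10_copies", "cq"]])
        rows.append(
            {
                "assay_id": assay,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
                "efficiency_pct": curve.efficiency,
            }
        )
    return pd.DataFrame(rows)


def cross_reactivity_table(wells: pd.DataFrame, slope: float) -> pd.DataFrame:
    """Assay x template cross-reactivity from mean Cq of matched wells.

    Cq_pm and Cq_mm are compared at matched template amounts: means are
    taken per (assay, template, log10_copies) and dCq is averaged over the
    dilution levels present for both the homologous and the heterologous
    template.
    """
    sub = wells[~wells["is_ntc"]]
    mean_cq = sub.groupby(["assay_id", "template_id", "log10_copies"])["cq"].mean()
    rows = []
    pairs = sub.groupby(["assay_id", "template_id"]).size().index
    for assay, template in pairs:
        if template == assay or (assay, assay) not in {(a, t) for a, t, _ in mean_cq.index}:
            continue
        mm = mean_cq.loc[assay, template]
        pm = mean_cq.loc[assay, assay]
        common = mm.index.intersection(pm.index)
        if common.empty:
            continue
        cq_mm = float(mm.loc[common].mean())
        cq_pm = float(pm.loc[common].mean())
        rec = cross_reactivity_record(cq_mm, cq_pm, slope)
        rows.append(
            {
                "assay_id": assay,
                "template_id": template,
                "cq_pm": cq_pm,
                "cq_mm": cq_mm,
                "delta_cq": rec.delta_cq,
                "cross_reactivity_pct": min(rec.percent, 100.0),
                "capped": rec.capped,
            }
        )
    return pd.DataFrame(rows)


def ntc_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-assay false-positive rate over NTC wells (positive = any Cq)."""
    sub = wells[wells["is_ntc"]]
    rows = []
    for assay, grp in sub.groupby("assay_id"):
        n = len(grp)
        p = int(grp["cq"].notna().sum())
        rows.append(
            {
                "assay_id": assay,
                "p_ntc": p,
                "n": n,
                "false_positive_pct": false_positive_rate(p, n),
            }
        )
    return pd.DataFrame(rows)
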
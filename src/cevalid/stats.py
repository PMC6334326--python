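"""ICH-style validation statistics.

Calibration fit, lack-of-fit ANOVA, LOD/LOQ, precision, assay content,
recovery, and the system-suitability summary.  All statistics are computed
at full precision; rounding to the 2-decimal reporting convention happens
only at presentation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .peaks import Peak


# ---------------------------------------------------------------------------
# data containers


@dataclass
class CalibrationDataset:
    """Calibration levels and their replicate corrected areas.

    ``areas[i]`` holds the replicate responses of level ``levels[i]``.  The
    lack-of-fit ANOVA requires an equal replicate count per level; the plain
    fit does not.
    """

    levels: np.ndarray  # (k,) nominal concentrations, µg/mL
    areas: list[np.ndarray]  # per-level replicate corrected areas

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.areas = [np.asarray(a, dtype=float) for a in self.areas]
        if self.levels.size != len(self.areas):
            raise ValueError("one replicate array required per level")
        if np.unique(self.levels).size < self.levels.size:
            raise ValueError("calibration levels must be distinct")

    @property
    def n_levels(self) -> int:
        return int(self.levels.size)

    @property
    def balanced_replicates(self) -> int | None:
        counts = {a.size for a in self.areas}
        return counts.pop() if len(counts) == 1 else None

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """All (concentration, area) observations, flattened."""
        x = np.concatenate([np.full(a.size, c) for c, a in zip(self.levels, self.areas)])
        y = np.concatenate(self.areas)
        return x, y

    @classmethod
    def from_points(cls, x: Sequence[float], y: Sequence[float]) -> "CalibrationDataset":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        levels = np.unique(x)
        return cls(levels=levels, areas=[y[x == c] for c in levels])


@dataclass
class LinearFit:
    slope: float  # area units per µg/mL (the S of the LOD/LOQ formulas)
    intercept: float  # area units
    r_squared: float
    residual_sd: float  # area units, sqrt(SS_res / (n − 2))
    n: int
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def equation(self) -> str:
        sign = "-" if self.intercept < 0 else "+"
        return f"y = {self.slope:.1f}x {sign} {abs(self.intercept):.0f}"


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None = None
    f: float | None = None
    f_crit: float | None = None
    significant: bool | None = None


@dataclass
class AnovaPartition:
    """Five-row calibration ANOVA: between-concentration, linear regression,
    deviation of linearity (lack of fit), residue (pure error), total."""

    rows: list[AnovaRow]
    alpha: float

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "df": r.df,
                    "ss": r.ss,
                    "ms": r.ms,
                    "f": r.f,
                    "f_crit": r.f_crit,
                    "significant": r.significant,
                }
                for r in self.rows
            ]
        )

    def __post_init__(self) -> None:
        b, res, tot = self.row("between-concentration"), self.row("residue"), self.row("total")
        reg, dev = self.row("linear regression"), self.row("deviation of linearity")
        if b.df + res.df != tot.df or reg.df + dev.df != b.df:
            raise ValueError("ANOVA degrees of freedom do not add up")
        scale = max(abs(tot.ss), 1.0)
        if abs(b.ss + res.ss - tot.ss) > 1e-6 * scale:
            raise ValueError("SS additivity violated: between + residue != total")
        if abs(reg.ss + dev.ss - b.ss) > 1e-6 * scale:
            raise ValueError("SS additivity violated: regression + deviation != between")


@dataclass
class LodLoq:
    lod: float  # µg/mL
    loq: float  # µg/mL
    sigma: float  # area units
    slope: float  # area units per µg/mL
    sigma_source: str  # residual-sd | intercept-sd | blank-sd


@dataclass
class PrecisionResult:
    n: int
    mean: float
    sd: float
    rsd_percent: float


@dataclass
class ContentResult:
    cs: float  # sample concentration, µg/mL
    cs_percent: float
    a_s: float
    a_rs: float
    c_rs: float
    c_t: float


@dataclass
class RecoveryResult:
    r_percent: float
    cf: float
    cu: float
    ca: float


# ---------------------------------------------------------------------------
# operations


def fit_calibration(data: CalibrationDataset) -> LinearFit:
    """Ordinary least squares over all (concentration, area) points."""
    if data.n_levels < 3:
        raise ValueError("calibration needs at least 3 distinct levels")
    x, y = data.points()
    res = sps.linregress(x, y)
    pred = res.intercept + res.slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    n = x.size
    residual_sd = float(np.sqrt(ss_res / (n - 2))) if n > 2 else float("nan")
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=residual_sd,
        n=int(n),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-``alpha`` quantile of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.f.ppf(1.0 - alpha, df1, df2))


def assemble_anova(
    ss_between: float,
    ss_regression: float,
    ss_residue: float,
    n_levels: int,
    replicates: int,
    alpha: float = 0.05,
) -> AnovaPartition:
    """Assemble the five-row partition from its sum-of-squares components.

    ``ss_deviation = ss_between − ss_regression`` and
    ``ss_total = ss_between + ss_residue``; mean squares are SS/df and each
    effect is tested against the residue (pure error) mean square.
    """
    k, r = int(n_levels), int(replicates)
    if k < 3 or r < 2:
        raise ValueError("ANOVA needs k >= 3 levels and r >= 2 replicates")
    n = k * r
    ss_dev = ss_between - ss_regression
    ss_total = ss_between + ss_residue
    df = {"between": k - 1, "reg": 1, "dev": k - 2, "res": n - k, "tot": n - 1}
    ms_res = ss_residue / df["res"]

    def _effect(source: str, dfe: int, ss: float) -> AnovaRow:
        ms = ss / dfe
        f = ms / ms_res if ms_res > 0 else float("inf")
        fc = f_critical(alpha, dfe, df["res"])
        return AnovaRow(source, dfe, ss, ms, f, fc, bool(f > fc))

    rows = [
        _effect("between-concentration", df["between"], ss_between),
        _effect("linear regression", df["reg"], ss_regression),
        _effect("deviation of linearity", df["dev"], ss_dev),
        AnovaRow("residue", df["res"], ss_residue, ms_res),
        AnovaRow("total", df["tot"], ss_total),
    ]
    return AnovaPartition(rows=rows, alpha=alpha)


def linearity_anova(data: CalibrationDataset, alpha: float = 0.05) -> AnovaPartition:
    """Lack-of-fit ANOVA of a replicated calibration.

    The between-concentration SS splits into the regression SS (slope fitted
    on all N points) and the deviation-of-linearity SS; the within-level
    (pure error) SS is the residue every effect is tested against.
    """
    r = data.balanced_replicates
    if r is None:
        raise ValueError(
            "lack-of-fit ANOVA requires an equal replicate count per level; "
            "use fit_calibration for unbalanced data"
        )
    if r < 2:
        raise ValueError("ANOVA needs at least 2 replicates per level")
    if data.n_levels < 3:
        raise ValueError("ANOVA needs at least 3 levels")
    x, y = data.points()
    grand = y.mean()
    level_means = np.array([a.mean() for a in data.areas])
    ss_between = r * float(np.sum((level_means - grand) ** 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (y - grand)) / sxx)
    ss_regression = slope**2 * sxx
    ss_residue = float(sum(np.sum((a - a.mean()) ** 2) for a in data.areas))
    return assemble_anova(ss_between, ss_regression, ss_residue, data.n_levels, r, alpha)


def lod_loq(sigma: float, slope: float, sigma_source: str = "residual-sd") -> LodLoq:
    """Detection and quantitation limits: ``3σ/S`` and ``10σ/S``."""
    if slope <= 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma_source not in ("residual-sd", "intercept-sd", "blank-sd"):
        raise ValueError(f"unknown sigma_source {sigma_source!r}")
    return LodLoq(
        lod=3.0 * sigma / slope,
        loq=10.0 * sigma / slope,
        sigma=sigma,
        slope=slope,
        sigma_source=sigma_source,
    )


def rsd(values: Iterable[float]) -> PrecisionResult:
    """Mean, sample SD (n−1) and relative standard deviation in percent."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    sd = float(v.std(ddof=1))
    return PrecisionResult(n=int(v.size), mean=mean, sd=sd, rsd_percent=100.0 * sd / mean)


def assay_content(a_s: float, a_rs: float, c_rs: float, c_t: float) -> ContentResult:
    """Sample concentration and percentage content against a reference standard.

    ``C_s = A_s·C_RS/A_RS`` and ``C_s% = 100·C_s/C_t`` where A are corrected
    peak areas, C_RS the reference-standard concentration and C_t the
    theoretical sample concentration.
    """
    if a_rs <= 0:
        raise ValueError(f"reference-standard area must be > 0, got {a_rs}")
    if c_t <= 0:
        raise ValueError(f"theoretical concentration must be > 0, got {c_t}")
    cs = a_s * c_rs / a_rs
    return ContentResult(
        cs=cs, cs_percent=100.0 * cs / c_t, a_s=a_s, a_rs=a_rs, c_rs=c_rs, c_t=c_t
    )


def recovery(cf: float, cu: float, ca: float) -> RecoveryResult:
    """Standard-addition recovery ``R% = 100·(Cf − Cu)/Ca``."""
    if ca <= 0:
        raise ValueError(f"added standard concentration must be > 0, got {ca}")
    return RecoveryResult(r_percent=100.0 * (cf - cu) / ca, cf=cf, cu=cu, ca=ca)


_SST_METRICS = ("corrected_area", "apex_time", "plate_number", "asymmetry")


def sst_summary(peaks: Sequence[Peak], rsd_limit: float = 2.0) -> pd.DataFrame:
    """Per-metric mean/SD/RSD table of a system-suitability replicate series.

    One row per metric (corrected area, migration time, plate number,
    asymmetry); a metric passes if its RSD does not exceed ``rsd_limit``.
    """
    if len(peaks) < 2:
        raise ValueError("SST summary needs at least 2 peaks")
    rows = []
    for metric in _SST_METRICS:
        prec = rsd(getattr(p, metric) for p in peaks)
        rows.append(
            {
                "metric": metric,
                "n": prec.n,
                "mean": prec.mean,
                "sd": prec.sd,
                "rsd_percent": prec.rsd_percent,
                "passed": bool(prec.rsd_percent <= rsd_limit),
            }
        )
    return pd.DataFrame(rows)


def intermediate_precision(day_results: Iterable[float]) -> PrecisionResult:
    """Between-day precision: RSD of the per-day mean contents."""
    v = list(day_results)
    if len(v) < 2:
        raise ValueError("intermediate precision needs at least 2 days")
    return rsd(v)
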
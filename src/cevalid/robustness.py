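"""Plackett–Burman-style robustness screening with the Youden–Steiner rule.

A 15-run, 7-factor, three-level design (four runs at +1 and four at −1 per
factor, seven at the nominal 0 level, run 8 entirely nominal) perturbs the
method's operating parameters.  For each factor and side the deviation
``D = |mean(content at the altered level) − mean(content at nominal)|`` is
compared against the Youden–Steiner criterion ``√2·S`` with
``S = √((2/7)·ΣD²)`` over the seven same-side deviations; a factor whose D
stays below the criterion does not significantly disturb the assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FACTOR_CODES = ("A", "B", "C", "D", "E", "F", "G")
SIDES = (1, -1)


@dataclass
class PBFactor:
    """One screened operating parameter with its low/nominal/high settings."""

    code: str
    name: str
    unit: str
    low: float
    nominal: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.nominal < self.high:
            raise ValueError(
                f"factor {self.code}: levels must satisfy low < nominal < high"
            )

    def value_at(self, level: int) -> float:
        return {-1: self.low, 0: self.nominal, 1: self.high}[int(level)]


@dataclass
class PBDesign:
    """15 runs × 7 factors of levels in {−1, 0, +1}.

    Each column must contain exactly four +1, four −1 and seven 0 entries,
    and run 8 is the all-nominal run.
    """

    levels: np.ndarray  # (15, 7) int
    factor_codes: tuple[str, ...] = FACTOR_CODES

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.shape != (15, 7):
            raise ValueError(f"design must be 15 runs x 7 factors, got {self.levels.shape}")
        if not np.all(np.isin(self.levels, (-1, 0, 1))):
            raise ValueError("design levels must be in {-1, 0, +1}")
        for j, code in enumerate(self.factor_codes):
            col = self.levels[:, j]
            counts = (np.sum(col == 1), np.sum(col == -1), np.sum(col == 0))
            if counts != (4, 4, 7):
                raise ValueError(
                    f"factor {code}: column balance must be 4 x +1, 4 x -1, 7 x 0, "
                    f"got {counts}"
                )
        if np.any(self.levels[7] != 0):
            raise ValueError("run 8 must be the all-nominal run")

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    def to_frame(self, runs_as_columns: bool = True) -> pd.DataFrame:
        """Design layout with factors as rows and runs 1–15 as columns
        (``runs_as_columns=False`` transposes)."""
        df = pd.DataFrame(
            self.levels.T,
            index=list(self.factor_codes),
            columns=[str(i) for i in range(1, self.n_runs + 1)],
        )
        return df if runs_as_columns else df.T


# Canonical 15-run screening matrix (factors as rows, runs 1..15 as columns).
_CANONICAL = np.array(
    [
        [1, 1, 1, 0, 1, 0, 0, 0, -1, -1, -1, 0, -1, 0, 0],   # A
        [0, 1, 1, 1, 0, 1, 0, 0, 0, -1, -1, -1, 0, -1, 0],   # B
        [0, 0, 1, 1, 1, 0, 1, 0, 0, 0, -1, -1, -1, 0, -1],   # C
        [1, 0, 0, 1, 1, 1, 0, 0, -1, 0, 0, -1, -1, -1, 0],   # D
        [0, 1, 0, 0, 1, 1, 1, 0, 0, -1, 0, 0, -1, -1, -1],   # E
        [1, 0, 1, 0, 0, 1, 1, 0, -1, 0, -1, 0, 0, -1, -1],   # F
        [1, 1, 0, 1, 0, 0, 1, 0, -1, -1, 0, -1, 0, 0, -1],   # G
    ],
    dtype=int,
)


def canonical_design() -> PBDesign:
    """The package's fixed 15-run, 7-factor screening matrix (2n + 1 runs)."""
    return PBDesign(levels=_CANONICAL.T.copy())


def canonical_factors() -> list[PBFactor]:
    """The seven CE operating parameters screened by the reference assay."""
    return [
        PBFactor("A", "Buffer concentration", "mM", 9.0, 10.0, 11.0),
        PBFactor("B", "Voltage", "kV", 14.0, 15.0, 16.0),
        PBFactor("C", "Wavelength", "nm", 213.0, 214.0, 215.0),
        PBFactor("D", "Injection time", "s", 4.0, 5.0, 6.0),
        PBFactor("E", "Rinsing of capillary", "min", 1.0, 2.0, 3.0),
        PBFactor("F", "Temperature of cartridge", "degC", 24.0, 25.0, 26.0),
        PBFactor("G", "Temperature of sample storage", "degC", 24.0, 25.0, 26.0),
    ]


def realize_design(design: PBDesign, factors: list[PBFactor]) -> pd.DataFrame:
    """Map the coded levels to physical settings, one row per run."""
    if len(factors) != design.levels.shape[1]:
        raise ValueError(
            f"need {design.levels.shape[1]} factors, got {len(factors)}"
        )
    codes = [f.code for f in factors]
    if codes != list(design.factor_codes):
        raise ValueError(f"factor codes {codes} do not match design {design.factor_codes}")
    rows = []
    for r in range(design.n_runs):
        row: dict = {"run_id": r + 1}
        for j, fac in enumerate(factors):
            row[f"{fac.code} ({fac.unit})"] = fac.value_at(design.levels[r, j])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EffectTable:
    """Per-factor, per-side absolute deviations and the means behind them."""

    table: pd.DataFrame  # columns: factor, side, mean_side, mean_nominal, d

    def deviations(self, side: int) -> np.ndarray:
        sub = self.table[self.table["side"] == side].set_index("factor")
        return sub.loc[list(FACTOR_CODES), "d"].to_numpy()


def effects(design: PBDesign, results: pd.DataFrame) -> EffectTable:
    """Absolute content deviations of every factor at each altered side.

    ``results`` must hold one ``content_percent`` per ``run_id`` of the
    design.  For factor ``i`` and side ``s``,
    ``D = |mean(content | level = s) − mean(content | level = 0)|``.
    """
    if not {"run_id", "content_percent"}.issubset(results.columns):
        raise ValueError("results must have columns run_id and content_percent")
    content = results.set_index("run_id")["content_percent"]
    wanted = set(range(1, design.n_runs + 1))
    if set(content.index) != wanted:
        missing = sorted(wanted - set(content.index))
        raise ValueError(f"missing run results for runs {missing}")
    c = content.loc[sorted(wanted)].to_numpy(dtype=float)
    rows = []
    for j, code in enumerate(design.factor_codes):
        col = design.levels[:, j]
        mean_nom = float(c[col == 0].mean())
        for side in SIDES:
            mean_side = float(c[col == side].mean())
            rows.append(
                {
                    "factor": code,
                    "side": side,
                    "mean_side": mean_side,
                    "mean_nominal": mean_nom,
                    "d": abs(mean_side - mean_nom),
                }
            )
    return EffectTable(table=pd.DataFrame(rows))


def youden_statistic(deviations) -> tuple[float, float]:
    """Youden–Steiner S and the √2·S acceptance criterion for one side.

    ``S = √((2/7)·Σ D²)`` over the seven same-side deviations.
    """
    d = np.asarray(list(deviations), dtype=float)
    if d.size != 7:
        raise ValueError(f"need exactly 7 deviations, got {d.size}")
    if np.any(d < 0):
        raise ValueError("deviations must be non-negative")
    s = float(np.sqrt((2.0 / 7.0) * np.sum(d**2)))
    return s, float(np.sqrt(2.0) * s)


@dataclass
class YoudenAssessment:
    """Per-side criteria and per-factor robustness verdicts."""

    table: pd.DataFrame  # factor, side, d, s_statistic, criterion, robust
    s_statistic: dict[int, float]
    criterion: dict[int, float]
    overall_robust: bool


def assess(effect_table: EffectTable) -> YoudenAssessment:
    """Apply the √2·S rule to both sides of an effect table.

    A factor-side is robust when its D is strictly below the side's
    criterion; the degenerate all-zero side (criterion 0) passes by
    definition.  The method is robust overall iff all 14 verdicts pass.
    """
    present = set(effect_table.table["side"].unique())
    if present != set(SIDES):
        raise ValueError(f"effect table must cover sides {SIDES}, got {sorted(present)}")
    s_stat: dict[int, float] = {}
    crit: dict[int, float] = {}
    rows = []
    for side in SIDES:
        d = effect_table.deviations(side)
        s, c = youden_statistic(d)
        s_stat[side], crit[side] = s, c
        for code, dv in zip(FACTOR_CODES, d):
            robust = bool(dv < c) or (dv == 0.0 and c == 0.0)
            rows.append(
                {
                    "factor": code,
                    "side": side,
                    "d": float(dv),
                    "s_statistic": s,
                    "criterion": c,
                    "robust": robust,
                }
            )
    table = pd.DataFrame(rows)
    return YoudenAssessment(
        table=table,
        s_statistic=s_stat,
        criterion=crit,
        overall_robust=bool(table["robust"].all()),
    )
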
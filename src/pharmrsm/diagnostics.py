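"""ANOVA with lack-of-fit partition and fit-summary statistics.

The residual sum of squares from a designed experiment with replicated
points splits into *pure error* (replicate scatter about each replicate
group's mean, model-free) and *lack of fit* (the remainder, measuring model
inadequacy). Their mean-square ratio is an F statistic for model adequacy.

The fit summary reports the R^2 family and two prediction-oriented numbers:

* PRESS, the leave-one-out prediction error sum, computed through the OLS
  leverage shortcut  e_(r) = e_r / (1 - h_r);
* "adequate precision", the DoE convention of signal (range of the fitted
  values over the design) to noise (sqrt(p * MS_res / n)); > 4 is the usual
  rule of thumb for a model that can navigate the design space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import ResponseTable
from .rsm import QuadraticModel, partial_ss

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "FitSummary",
    "PressUndefinedError",
    "anova",
    "fit_summary",
    "f_p_value",
    "format_p",
]

_TERM_LABELS = {"b0": "Intercept"}


class PressUndefinedError(ValueError):
    """A leverage of 1 makes the leave-one-out residual undefined."""


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None
    f: float | None
    p: float | None


@dataclass
class AnovaTable:
    response_name: str
    rows: list[AnovaRow]

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def sources(self) -> list[str]:
        return [r.source for r in self.rows]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "ss": r.ss,
                    "df": r.df,
                    "ms": r.ms,
                    "f": r.f,
                    "p": r.p,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [f"ANOVA for {self.response_name}"]
        header = f"{'Source':<14}{'SS':>14}{'df':>5}{'MS':>14}{'F':>10}{'p':>10}"
        lines.append(header)
        lines.append("-" * len(header))
        for r in self.rows:
            ms = f"{r.ms:.4g}" if r.ms is not None else ""
            f_ = f"{r.f:.4g}" if r.f is not None else ""
            p_ = format_p(r.p) if r.p is not None else ""
            lines.append(
                f"{r.source:<14}{r.ss:>14.4g}{r.df:>5d}{ms:>14}{f_:>10}{p_:>10}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class FitSummary:
    response_name: str
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    adequate_precision: float


def f_p_value(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution."""
    if f < 0:
        raise ValueError(f"F statistic must be >= 0, got {f}")
    return float(stats.f.sf(f, df1, df2))


def format_p(p: float) -> str:
    """Report convention: values below 1e-4 print as '< 0.0001'."""
    return "< 0.0001" if p < 1e-4 else f"{p:.4f}"


def _replicate_groups(coded: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing identical coded levels (replicate sets)."""
    keys = [tuple(np.round(row, 9)) for row in coded]
    groups: dict[tuple, list[int]] = {}
    for idx, key in enumerate(keys):
        groups.setdefault(key, []).append(idx)
    return [np.array(v) for v in groups.values() if len(v) > 1]


def anova(model: QuadraticModel, table: ResponseTable | None = None) -> AnovaTable:
    """Full ANOVA table: model, per-term, residual, LOF, pure error, total.

    ``table`` is accepted for interface symmetry; the fitted model already
    carries its data. Without replicated design points the lack-of-fit and
    pure-error rows are omitted with a warning.
    """
    y = model.y
    n, p = model.n, model.p
    ss_total = model.ss_total
    ss_res = model.ss_residual
    ss_model = ss_total - ss_res
    df_model = p - 1
    df_res = n - p
    ms_model = ss_model / df_model
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    rows: list[AnovaRow] = []
    f_model = ms_model / ms_res if df_res > 0 else None
    rows.append(
        AnovaRow(
            "Model",
            ss_model,
            df_model,
            ms_model,
            f_model,
            f_p_value(f_model, df_model, df_res) if f_model is not None else None,
        )
    )
    for term, ss in partial_ss(model).items():
        f_term = ss / ms_res if df_res > 0 else None
        rows.append(
            AnovaRow(
                term,
                ss,
                1,
                ss,
                f_term,
                f_p_value(f_term, 1, df_res) if f_term is not None else None,
            )
        )
    rows.append(AnovaRow("Residual", ss_res, df_res, ms_res if df_res else None, None, None))

    groups = _replicate_groups(model.design.coded_matrix)
    df_pe = sum(len(g) - 1 for g in groups)
    if df_pe == 0:
        warnings.warn(
            f"{model.response_name}: no replicated design points; "
            "lack-of-fit rows omitted",
            stacklevel=2,
        )
    else:
        ss_pe = float(sum(np.sum((y[g] - y[g].mean()) ** 2) for g in groups))
        ss_lof = max(ss_res - ss_pe, 0.0)
        df_lof = df_res - df_pe
        ms_pe = ss_pe / df_pe
        if df_lof > 0 and ms_pe > 0:
            ms_lof = ss_lof / df_lof
            f_lof = ms_lof / ms_pe
            p_lof = f_p_value(f_lof, df_lof, df_pe)
        else:
            ms_lof = ss_lof / df_lof if df_lof > 0 else None
            f_lof = p_lof = None
        rows.append(AnovaRow("Lack of fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
        rows.append(AnovaRow("Pure error", ss_pe, df_pe, ms_pe, None, None))
    rows.append(AnovaRow("Cor total", ss_total, n - 1, None, None, None))

    out = AnovaTable(response_name=model.response_name, rows=rows)
    _check_additivity(out)
    return out


def _check_additivity(tbl: AnovaTable) -> None:
    ss_model = tbl["Model"].ss
    ss_res = tbl["Residual"].ss
    ss_tot = tbl["Cor total"].ss
    assert abs(ss_model + ss_res - ss_tot) <= 1e-8 * max(ss_tot, 1.0)
    try:
        lof, pe = tbl["Lack of fit"], tbl["Pure error"]
    except KeyError:
        return
    assert abs(lof.ss + pe.ss - ss_res) <= 1e-8 * max(ss_res, 1.0) + 1e-12
    assert lof.df + pe.df == tbl["Residual"].df


def press_statistic(model: QuadraticModel) -> float:
    """Leave-one-out prediction error SS via the leverage shortcut."""
    if np.any(model.leverages >= 1 - 1e-10):
        raise PressUndefinedError(
            f"{model.response_name}: a run has leverage 1; "
            "leave-one-out prediction is undefined"
        )
    loo = model.residuals / (1.0 - model.leverages)
    return float(loo @ loo)


def fit_summary(model: QuadraticModel, table: ResponseTable | None = None) -> FitSummary:
    """R^2 family, PRESS and adequate precision for a fitted quadratic."""
    n, p = model.n, model.p
    ss_total = model.ss_total
    ss_res = model.ss_residual
    df_res = n - p
    r2 = 1.0 - ss_res / ss_total
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_total / (n - 1))
    press = press_statistic(model)
    pred_r2 = 1.0 - press / ss_total
    ms_res = ss_res / df_res
    noise = np.sqrt(p * ms_res / n)
    signal = float(model.fitted.max() - model.fitted.min())
    return FitSummary(
        response_name=model.response_name,
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        adequate_precision=signal / noise if noise > 0 else np.inf,
    )
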
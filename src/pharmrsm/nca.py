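"""Non-compartmental pharmacokinetic analysis of oral profiles.

Model-free summary of a concentration–time curve: Cmax/Tmax by direct
maximum, AUC and AUMC by the linear trapezoidal rule (with a (0, 0) anchor
for oral dosing when the first sample is post-dose), the terminal rate
constant lambda_z from log-linear regression on the last points, and the
extrapolated quantities

    AUC_inf  = AUC_last  + C_last / lambda_z
    AUMC_inf = AUMC_last + t_last * C_last / lambda_z + C_last / lambda_z**2
    MRT      = AUMC_inf / AUC_inf.

Relative (oral) bioavailability between groups is the percent ratio of
dose-normalized AUC_inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationProfile",
    "NCAResult",
    "TerminalPhaseWarning",
    "nca",
    "relative_bioavailability",
    "group_summary",
    "nca_table",
    "read_concentration_csv",
    "write_concentration_csv",
]

NCA_PARAMETERS = (
    "cmax",
    "tmax",
    "auc_last",
    "auc_inf",
    "aumc_last",
    "aumc_inf",
    "lambda_z",
    "mrt",
)


class TerminalPhaseWarning(UserWarning):
    """Terminal phase unusable for lambda_z; extrapolation suppressed."""


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject's concentration–time series after a single oral dose."""

    group: str
    subject_id: str
    times: np.ndarray  # min
    concentrations: np.ndarray  # µg/mL
    dose: float  # mg/kg

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        t, c = self.times, self.concentrations
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be equal-length vectors")
        if len(t) == 0 or t[0] < 0:
            raise ValueError("times must be non-empty with first time >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite and >= 0")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental parameter set; extrapolated fields are None when
    the terminal phase could not be characterized."""

    group: str
    subject_id: str
    dose: float
    cmax: float
    tmax: float
    auc_last: float
    aumc_last: float
    lambda_z: float | None
    n_lambda_points: int
    auc_inf: float | None
    aumc_inf: float | None
    mrt: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {p: getattr(self, p) for p in NCA_PARAMETERS}


def _lambda_z(t: np.ndarray, c: np.ndarray, m: int) -> float | None:
    """Terminal slope from log-linear OLS on the last m samples; None if the
    tail is non-positive or not net-declining."""
    if m < 2 or len(t) < m:
        return None
    tt, cc = t[-m:], c[-m:]
    if np.any(cc <= 0):
        return None
    slope = np.polyfit(tt, np.log(cc), 1)[0]
    if slope >= 0:
        return None
    return float(-slope)


def nca(profile: ConcentrationProfile, lambda_points: int = 3) -> NCAResult:
    """Run non-compartmental analysis on one profile.

    Cmax/Tmax take the earliest time on ties. The 0 -> first-sample segment
    enters the AUC through a (0, 0) anchor (oral dosing, no pre-dose
    sample). When the last ``lambda_points`` concentrations are not strictly
    positive and net-declining, a :class:`TerminalPhaseWarning` is issued
    and the extrapolated fields are returned as None.
    """
    t, c = profile.times, profile.concentrations
    if np.count_nonzero(c > 0) < 3:
        raise ValueError("need at least 3 positive concentrations for NCA")
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])

    if t[0] > 0:
        t_int = np.concatenate([[0.0], t])
        c_int = np.concatenate([[0.0], c])
    else:
        t_int, c_int = t, c
    auc_last = float(np.trapezoid(c_int, t_int))
    aumc_last = float(np.trapezoid(t_int * c_int, t_int))

    lz = _lambda_z(t, c, lambda_points)
    if lz is None:
        warnings.warn(
            f"{profile.group}/{profile.subject_id}: terminal phase not "
            f"net-declining over the last {lambda_points} samples; "
            "extrapolation to infinity suppressed",
            TerminalPhaseWarning,
            stacklevel=2,
        )
        auc_inf = aumc_inf = mrt = None
    else:
        c_last, t_last = float(c[-1]), float(t[-1])
        auc_inf = auc_last + c_last / lz
        aumc_inf = aumc_last + t_last * c_last / lz + c_last / lz**2
        mrt = aumc_inf / auc_inf
    return NCAResult(
        group=profile.group,
        subject_id=profile.subject_id,
        dose=profile.dose,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        aumc_last=aumc_last,
        lambda_z=lz,
        n_lambda_points=lambda_points,
        auc_inf=auc_inf,
        aumc_inf=aumc_inf,
        mrt=mrt,
    )


def relative_bioavailability(test: NCAResult, reference: NCAResult) -> float:
    """Dose-normalized AUC_inf ratio of test over reference, in percent."""
    if test.auc_inf is None or reference.auc_inf is None:
        raise ValueError("relative bioavailability needs AUC_inf for both profiles")
    return 100.0 * (test.auc_inf / test.dose) / (reference.auc_inf / reference.dose)


def group_summary(
    profiles: Sequence[ConcentrationProfile], lambda_points: int = 3
) -> pd.DataFrame:
    """Mean and SEM of subject-level NCA parameters per group.

    SEM = sd(ddof=1) / sqrt(n); None-valued parameters are excluded
    per-parameter. Requires >= 2 subjects in every group.
    """
    results = [nca(p, lambda_points=lambda_points) for p in profiles]
    by_group: dict[str, list[NCAResult]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)
    rows = []
    for group, rs in by_group.items():
        if len(rs) < 2:
            raise ValueError(f"group {group!r}: need >= 2 subjects, got {len(rs)}")
        for param in NCA_PARAMETERS:
            vals = np.array([r.as_dict()[param] for r in rs if r.as_dict()[param] is not None])
            if len(vals) < 2:
                continue
            rows.append(
                {
                    "group": group,
                    "parameter": param,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                }
            )
    return pd.DataFrame(rows)


def nca_table(
    profiles: Sequence[ConcentrationProfile], lambda_points: int = 3
) -> pd.DataFrame:
    """Per-subject NCA results as a tidy DataFrame (one row per subject)."""
    rows = []
    for p in profiles:
        r = nca(p, lambda_points=lambda_points)
        row = {"group": r.group, "subject_id": r.subject_id, "dose_mg_kg": r.dose}
        row.update(r.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def write_concentration_csv(
    profiles: Sequence[ConcentrationProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append(
                {
                    "group": p.group,
                    "subject_id": p.subject_id,
                    "time_min": t,
                    "conc_ug_ml": c,
                    "dose_mg_kg": p.dose,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_concentration_csv(path: str | Path) -> list[ConcentrationProfile]:
    """Read `group, subject_id, time_min, conc_ug_ml, dose_mg_kg` CSV."""
    df = pd.read_csv(path)
    required = {"group", "subject_id", "time_min", "conc_ug_ml", "dose_mg_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles = []
    for (group, subject), sub in df.groupby(["group", "subject_id"], sort=False):
        sub = sub.sort_values("time_min")
        doses = sub["dose_mg_kg"].unique()
        if len(doses) != 1:
            raise ValueError(f"{group}/{subject}: inconsistent dose values {doses}")
        profiles.append(
            ConcentrationProfile(
                group=str(group),
                subject_id=str(subject),
                times=sub["time_min"].to_numpy(float),
                concentrations=sub["conc_ug_ml"].to_numpy(float),
                dose=float(doses[0]),
            )
        )
    return profiles
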
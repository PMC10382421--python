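"""Rotatable central composite designs and coded/actual factor mapping.

A central composite design (CCD) for k factors combines the 2**k factorial
corners at coded levels ±1, 2k axial ("star") points at coded distance
``alpha`` along each axis, and replicated center points at the coded origin.
The design is *rotatable* when ``alpha = (2**k) ** 0.25`` (== sqrt(2) for
k = 2), which makes the prediction variance a function of the distance from
the center only.

Coded units are an affine rescaling of the actual factor levels: a factor
with center ``c`` and half-range ``h`` maps coded level ``x`` to the actual
level ``c + h * x``, so the factorial range spans [c - h, c + h].
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "ParseError",
    "FactorSpec",
    "DesignPoint",
    "CCDDesign",
    "ResponseTable",
    "build_ccd",
    "coded_to_actual",
    "actual_to_coded",
    "read_response_table",
    "write_response_table",
]

POINT_CLASSES = ("factorial", "axial", "center")


class DesignError(ValueError):
    """Invalid design specification (factors, alpha, point layout)."""


class ParseError(ValueError):
    """Malformed design/response CSV."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor and its coded-unit calibration.

    ``center`` is the actual level at coded 0 and ``half_range`` the actual
    change per coded unit, so coded ±1 maps to ``center ± half_range``.
    """

    name: str
    center: float
    half_range: float
    units: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.half_range):
            raise DesignError(f"factor {self.name!r}: non-finite center/half_range")
        if self.half_range <= 0:
            raise DesignError(
                f"factor {self.name!r}: half_range must be > 0, got {self.half_range}"
            )

    def to_actual(self, coded: float) -> float:
        return self.center + self.half_range * float(coded)

    def to_coded(self, actual: float) -> float:
        return (float(actual) - self.center) / self.half_range


@dataclass(frozen=True)
class DesignPoint:
    run_id: str
    coded: tuple[float, ...]
    actual: tuple[float, ...]
    point_class: str

    def __post_init__(self) -> None:
        if len(self.coded) != len(self.actual):
            raise DesignError(f"run {self.run_id}: coded/actual length mismatch")
        if self.point_class not in POINT_CLASSES:
            raise DesignError(
                f"run {self.run_id}: point_class must be one of {POINT_CLASSES}"
            )


def _classify(coded: Sequence[float], alpha: float, atol: float = 1e-8) -> str:
    x = np.asarray(coded, dtype=float)
    if np.allclose(x, 0.0, atol=atol):
        return "center"
    if np.allclose(np.abs(x), 1.0, atol=atol):
        return "factorial"
    nonzero = np.abs(x) > atol
    if nonzero.sum() == 1 and np.isclose(np.abs(x[nonzero][0]), alpha, atol=1e-6):
        return "axial"
    raise DesignError(f"coded point {tuple(x)} is not a CCD point for alpha={alpha}")


@dataclass(frozen=True)
class CCDDesign:
    """A central composite design: factors, axial distance and run list."""

    factors: tuple[FactorSpec, ...]
    alpha: float
    points: tuple[DesignPoint, ...]

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise DesignError(f"alpha must be > 0, got {self.alpha}")
        k = self.k
        for pt in self.points:
            if len(pt.coded) != k:
                raise DesignError(f"run {pt.run_id}: expected {k} coded levels")
            expected = tuple(f.to_actual(x) for f, x in zip(self.factors, pt.coded))
            if not np.allclose(pt.actual, expected, rtol=1e-4, atol=5e-3):
                raise DesignError(
                    f"run {pt.run_id}: actual levels {pt.actual} do not match "
                    f"center + half_range * coded = {expected}"
                )
        ids = [pt.run_id for pt in self.points]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicated run_id in design")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def run_ids(self) -> tuple[str, ...]:
        return tuple(pt.run_id for pt in self.points)

    @property
    def coded_matrix(self) -> np.ndarray:
        """(n_runs, k) array of coded levels, in run order."""
        return np.array([pt.coded for pt in self.points], dtype=float)

    @property
    def actual_matrix(self) -> np.ndarray:
        return np.array([pt.actual for pt in self.points], dtype=float)

    @property
    def n_center(self) -> int:
        return sum(pt.point_class == "center" for pt in self.points)

    def coded_to_actual(self, coded: Sequence[float]) -> np.ndarray:
        coded = np.asarray(coded, dtype=float)
        if coded.shape[-1] != self.k:
            raise DesignError(f"expected vector of length {self.k}")
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return centers + halves * coded

    def actual_to_coded(self, actual: Sequence[float]) -> np.ndarray:
        actual = np.asarray(actual, dtype=float)
        if actual.shape[-1] != self.k:
            raise DesignError(f"expected vector of length {self.k}")
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return (actual - centers) / halves


def coded_to_actual(design: CCDDesign, coded: Sequence[float]) -> np.ndarray:
    """Map a coded-unit vector to actual factor levels."""
    return design.coded_to_actual(coded)


def actual_to_coded(design: CCDDesign, actual: Sequence[float]) -> np.ndarray:
    """Map actual factor levels to coded units (inverse of coded_to_actual)."""
    return design.actual_to_coded(actual)


def build_ccd(
    factors: Sequence[FactorSpec],
    n_center: int = 5,
    alpha_mode: str = "rotatable",
    alpha: float | None = None,
    run_prefix: str = "F",
    shuffle_seed: int | None = None,
) -> CCDDesign:
    """Construct a two-level central composite design.

    Run order is deterministic: the 2**k factorial corners in lexicographic
    coded order, then the axial pair (-alpha, +alpha) for each factor in
    turn, then the center replicates. ``shuffle_seed`` optionally randomizes
    the run order (off by default; run labels follow the final order).

    alpha_mode:
        ``rotatable``     alpha = (2**k) ** 0.25
        ``face_centered`` alpha = 1
        ``explicit``      alpha given by the ``alpha`` argument
    """
    factors = tuple(factors)
    k = len(factors)
    if k < 2:
        raise DesignError(f"a CCD needs at least 2 factors, got {k}")
    if n_center < 1:
        raise DesignError(f"n_center must be >= 1, got {n_center}")
    if alpha_mode == "rotatable":
        alpha_val = (2.0**k) ** 0.25
    elif alpha_mode == "face_centered":
        alpha_val = 1.0
    elif alpha_mode == "explicit":
        if alpha is None or alpha <= 0:
            raise DesignError("alpha_mode='explicit' requires alpha > 0")
        alpha_val = float(alpha)
    else:
        raise DesignError(f"unknown alpha_mode {alpha_mode!r}")

    coded_rows: list[tuple[float, ...]] = []
    classes: list[str] = []
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        coded_rows.append(corner)
        classes.append("factorial")
    for i in range(k):
        for sign in (-1.0, 1.0):
            row = [0.0] * k
            row[i] = sign * alpha_val
            coded_rows.append(tuple(row))
            classes.append("axial")
    for _ in range(n_center):
        coded_rows.append(tuple([0.0] * k))
        classes.append("center")

    order = np.arange(len(coded_rows))
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(order)

    points = []
    for run_no, idx in enumerate(order, start=1):
        coded = coded_rows[idx]
        actual = tuple(f.to_actual(x) for f, x in zip(factors, coded))
        points.append(
            DesignPoint(
                run_id=f"{run_prefix}{run_no}",
                coded=coded,
                actual=actual,
                point_class=classes[idx],
            )
        )
    return CCDDesign(factors=factors, alpha=alpha_val, points=tuple(points))


@dataclass
class ResponseTable:
    """A design with one measured (mean, sd) per run for each response.

    ``magnitude_responses`` lists responses that are modelled as absolute
    values (e.g. a negative zeta potential stored as printed but analyzed as
    |ZP| so "larger" means "more stable"); reports re-attach the sign.
    """

    design: CCDDesign
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray] = field(default_factory=dict)
    magnitude_responses: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        n = self.design.n_runs
        self.means = {k: np.asarray(v, dtype=float) for k, v in self.means.items()}
        self.sds = {k: np.asarray(v, dtype=float) for k, v in self.sds.items()}
        self.magnitude_responses = frozenset(self.magnitude_responses)
        if not self.means:
            raise ParseError("response table has no responses")
        for name, vals in self.means.items():
            if vals.shape != (n,):
                raise ParseError(
                    f"response {name!r}: expected {n} values, got {vals.shape}"
                )
            if not np.all(np.isfinite(vals)):
                raise ParseError(f"response {name!r}: non-finite value")
        for name, vals in self.sds.items():
            if vals.shape != (n,):
                raise ParseError(f"sd column {name!r}: expected {n} values")
            if np.any(vals < 0) or not np.all(np.isfinite(vals)):
                raise ParseError(f"sd column {name!r}: sd must be finite and >= 0")

    @property
    def response_names(self) -> tuple[str, ...]:
        return tuple(self.means)

    def analysis_values(self, name: str) -> tuple[np.ndarray, int]:
        """Values entering the model fit and the display sign.

        For magnitude-analyzed responses returns (|y|, -1) when the raw data
        are predominantly negative, so reports can restore the printed sign.
        """
        y = self.means[name]
        if name in self.magnitude_responses:
            sign = -1 if np.median(y) < 0 else 1
            return np.abs(y), sign
        return y.copy(), 1

    def to_dataframe(self) -> pd.DataFrame:
        d = self.design
        data: dict[str, object] = {"run_id": list(d.run_ids)}
        coded = d.coded_matrix
        actual = d.actual_matrix
        for i in range(d.k):
            data[f"x{i + 1}_coded"] = coded[:, i]
            data[f"x{i + 1}_actual"] = actual[:, i]
        data["point_class"] = [pt.point_class for pt in d.points]
        for name in self.response_names:
            data[f"{name}_mean"] = self.means[name]
            data[f"{name}_sd"] = self.sds.get(
                name, np.zeros(d.n_runs)
            )
        return pd.DataFrame(data)


def write_response_table(table: ResponseTable, path: str | Path) -> None:
    """Write the documented CSV dialect (UTF-8, header, full-precision floats)."""
    # shortest round-trip repr so write -> read is bit-exact
    table.to_dataframe().to_csv(path, index=False, float_format=lambda v: repr(float(v)))


_RESP_RE = re.compile(r"^(?P<name>.+)_mean$")


def read_response_table(
    path: str | Path,
    factors: Sequence[FactorSpec] | None = None,
    magnitude_responses: Iterable[str] = (),
) -> ResponseTable:
    """Read a design/response CSV into a validated :class:`ResponseTable`.

    Factor columns may be coded (``x<i>_coded``), actual (``x<i>_actual``) or
    both. When ``factors`` is omitted, each factor's center/half-range is
    recovered from the coded/actual column pair (the map is affine, so two
    distinct levels determine it exactly).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    if "run_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'run_id'")
    if df["run_id"].duplicated().any():
        dups = df.loc[df["run_id"].duplicated(), "run_id"].tolist()
        raise ParseError(f"{path}: duplicated run_id(s) {dups}")

    coded_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"x\d+_coded", c)),
        key=lambda c: int(c.split("_")[0][1:]),
    )
    actual_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"x\d+_actual", c)),
        key=lambda c: int(c.split("_")[0][1:]),
    )
    if not coded_cols and not actual_cols:
        raise ParseError(f"{path}: no factor columns (x<i>_coded / x<i>_actual)")
    k = max(len(coded_cols), len(actual_cols))

    numeric_cols = coded_cols + actual_cols + [
        c for c in df.columns if c.endswith(("_mean", "_sd"))
    ]
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "run_id"].tolist()
            raise ParseError(f"{path}: non-numeric value in column {col!r}, run(s) {bad}")
        df[col] = vals.astype(float)

    if factors is not None:
        factors = tuple(factors)
        if len(factors) != k:
            raise ParseError(f"{path}: {k} factor columns but {len(factors)} FactorSpecs")
    else:
        if not (coded_cols and actual_cols):
            raise ParseError(
                f"{path}: need both coded and actual columns to infer factor "
                "calibration, or pass factors= explicitly"
            )
        inferred = []
        for i, (cc, ac) in enumerate(zip(coded_cols, actual_cols), start=1):
            x = df[cc].to_numpy()
            y = df[ac].to_numpy()
            A = np.column_stack([np.ones_like(x), x])
            (center, half), *_ = np.linalg.lstsq(A, y, rcond=None)
            if half <= 0:
                raise ParseError(f"{path}: factor x{i} has non-positive half-range")
            inferred.append(FactorSpec(name=f"x{i}", center=center, half_range=half))
        factors = tuple(inferred)

    if coded_cols:
        coded = df[coded_cols].to_numpy()
    else:
        centers = np.array([f.center for f in factors])
        halves = np.array([f.half_range for f in factors])
        coded = (df[actual_cols].to_numpy() - centers) / halves

    alpha = float(np.max(np.abs(coded)))
    points = []
    for row_idx, run_id in enumerate(df["run_id"].astype(str)):
        c = tuple(float(v) for v in coded[row_idx])
        a = tuple(f.to_actual(v) for f, v in zip(factors, c))
        if "point_class" in df.columns:
            cls = str(df["point_class"].iloc[row_idx])
        else:
            cls = _classify(c, alpha)
        points.append(DesignPoint(run_id=run_id, coded=c, actual=a, point_class=cls))
    design = CCDDesign(factors=tuple(factors), alpha=alpha, points=tuple(points))

    means: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    for col in df.columns:
        m = _RESP_RE.match(col)
        if not m or m.group("name").endswith(("_coded", "_actual")):
            continue
        name = m.group("name")
        means[name] = df[col].to_numpy()
        sd_col = f"{name}_sd"
        if sd_col in df.columns:
            sds[name] = df[sd_col].to_numpy()
    if not means:
        raise ParseError(f"{path}: no response columns (<name>_mean)")
    return ResponseTable(
        design=design,
        means=means,
        sds=sds,
        magnitude_responses=frozenset(magnitude_responses),
    )
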
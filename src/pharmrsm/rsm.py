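"""Full second-order response-surface models fitted in coded units.

For k factors the model is

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i**2

with the x_i in coded units. All modelling happens in coded units (as the
standard DoE software does); actual-unit equations are a display transform.
On an orthogonal CCD the linear and interaction columns are mutually
orthogonal, which makes their partial sums of squares simple closed forms
(b_i**2 * sum x_i**2 and b_ij**2 * sum (x_i x_j)**2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import CCDDesign, ResponseTable

__all__ = [
    "SingularDesignError",
    "QuadraticModel",
    "term_names",
    "model_matrix",
    "fit_quadratic",
    "predict",
    "partial_ss",
]

log = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    """The quadratic model matrix is rank deficient."""


def term_names(k: int) -> tuple[str, ...]:
    """Coefficient labels: b0, linear b<i>, interactions b<ij>, quadratics b<ii>."""
    names = ["b0"]
    names += [f"b{i + 1}" for i in range(k)]
    names += [f"b{i + 1}{j + 1}" for i in range(k) for j in range(i + 1, k)]
    names += [f"b{i + 1}{i + 1}" for i in range(k)]
    return tuple(names)


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Build the full-quadratic design matrix from (n, k) coded levels."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, i] for i in range(k)]
    cols += [coded[:, i] * coded[:, j] for i in range(k) for j in range(i + 1, k)]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


def n_params(k: int) -> int:
    return 1 + k + k * (k - 1) // 2 + k


@dataclass
class QuadraticModel:
    """A fitted coded-unit quadratic for one response.

    ``sign`` is -1 when the response was analyzed as a magnitude of
    negative data (display layers multiply predictions by it); the model
    itself always lives on the analysis scale.
    """

    response_name: str
    terms: tuple[str, ...]
    coef: np.ndarray
    design: CCDDesign
    y: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    leverages: np.ndarray
    xtx_inv: np.ndarray
    sign: int = 1

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def k(self) -> int:
        return self.design.k

    @property
    def coef_dict(self) -> dict[str, float]:
        return {t: float(c) for t, c in zip(self.terms, self.coef)}

    @property
    def b0(self) -> float:
        return float(self.coef[0])

    @property
    def linear(self) -> np.ndarray:
        return self.coef[1 : 1 + self.k].copy()

    @property
    def interaction(self) -> dict[tuple[int, int], float]:
        k = self.k
        out = {}
        idx = 1 + k
        for i in range(k):
            for j in range(i + 1, k):
                out[(i, j)] = float(self.coef[idx])
                idx += 1
        return out

    @property
    def quadratic(self) -> np.ndarray:
        return self.coef[-self.k :].copy()

    @property
    def ss_residual(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def ss_total(self) -> float:
        return float(np.sum((self.y - self.y.mean()) ** 2))

    @property
    def ss_model(self) -> float:
        return self.ss_total - self.ss_residual

    def equation(self, ndigits: int = 3) -> str:
        """Human-readable coded-unit equation, e.g. for reports."""
        k = self.k
        labels = ["1"]
        labels += [f"X{i + 1}" for i in range(k)]
        labels += [f"X{i + 1}X{j + 1}" for i in range(k) for j in range(i + 1, k)]
        labels += [f"X{i + 1}^2" for i in range(k)]
        parts = [f"{self.sign * self.coef[0]:+.{ndigits}f}"]
        for c, lab in zip(self.coef[1:], labels[1:]):
            parts.append(f"{self.sign * c:+.{ndigits}f}*{lab}")
        return f"{self.response_name} = " + " ".join(parts)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "response": self.response_name,
            "coefficients": self.coef_dict,
            "n": self.n,
            "p": self.p,
            "sign": self.sign,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def fit_quadratic(table: ResponseTable, response_name: str) -> QuadraticModel:
    """Fit the full coded-unit quadratic to one response by OLS.

    The solver is numpy's SVD least squares; an independent normal-equations
    oracle (tests) agrees to 1e-8 relative. Raises
    :class:`SingularDesignError` naming the collinear columns when the model
    matrix is rank deficient, and ValueError when n_runs < p.
    """
    if response_name not in table.means:
        raise KeyError(f"unknown response {response_name!r}")
    design = table.design
    y, sign = table.analysis_values(response_name)
    X = model_matrix(design.coded_matrix)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least p={p} runs to fit, got n={n}")

    names = term_names(design.k)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[-1] <= s[0] * 1e-10:
        null = vt[-1]
        cols = [names[i] for i in np.flatnonzero(np.abs(null) > 0.3)]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {cols}"
        )

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    residuals = y - fitted
    xtx_inv = np.linalg.inv(X.T @ X)
    leverages = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    return QuadraticModel(
        response_name=response_name,
        terms=names,
        coef=coef,
        design=design,
        y=y,
        fitted=fitted,
        residuals=residuals,
        leverages=leverages,
        xtx_inv=xtx_inv,
        sign=sign,
    )


def predict(model: QuadraticModel, coded_point: Sequence[float]) -> float:
    """Evaluate the fitted quadratic at a coded point (extrapolation allowed)."""
    x = np.asarray(coded_point, dtype=float)
    if x.shape != (model.k,):
        raise ValueError(f"expected coded point of length {model.k}")
    if np.any(np.abs(x) > model.design.alpha + 1e-9):
        log.warning(
            "%s: predicting outside the design region |x| <= %.4f at %s",
            model.response_name,
            model.design.alpha,
            tuple(x),
        )
    row = model_matrix(x[None, :])[0]
    return float(row @ model.coef)


def partial_ss(model: QuadraticModel) -> dict[str, float]:
    """Per-term partial (type III) sum of squares.

    Computed as b_j**2 / [(X'X)^-1]_jj, the extra SS of dropping the term
    from the full model. On an orthogonal CCD this reduces to
    b_i**2 * sum(x_i**2) for linear terms and b_ij**2 * sum((x_i x_j)**2)
    for interactions.
    """
    out = {}
    for j, name in enumerate(model.terms):
        if name == "b0":
            continue
        out[name] = float(model.coef[j] ** 2 / model.xtx_inv[j, j])
    return out
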
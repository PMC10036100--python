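"""The biological conversion factor (BCF) and its fitted models.

The BCF is the ratio BDM/PDM: it converts a physical dosimetric margin into
the biological one for a given fractionation scheme.  Two model forms are
used, both functions of the dimensionless ratio x = d/(α/β):

* point prescription:     BCF(x) = A·ln(x) + B
* marginal prescription:  BCF(x, ID) = (C·ID + D)·ln(x) + (E·ID + F)

where ID is the prescription isodose level in percent.  Both are linear in
their parameters given the ln(x) and ID regressors, so the least-squares fit
has a closed-form solution; parameter standard deviations come from the
classical linear-model covariance σ̂²(XᵀX)⁻¹ (a bootstrap alternative is
available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .margin_engine import MarginResult

__all__ = [
    "BCFSample",
    "BCFFit",
    "compute_bcf",
    "eval_bcf_point",
    "eval_bcf_marginal",
    "fit_bcf",
    "pooled_bcf_stats",
]

_POINT_PARAMS = ("A", "B")
_MARGINAL_PARAMS = ("C", "D", "E", "F")


@dataclass(frozen=True)
class BCFSample:
    """One measured BCF value and the covariates it was observed at."""

    d_over_ab: float
    bcf: float
    direction: str
    id_percent: float | None = None  # absent for the point style
    density: float | None = None

    def __post_init__(self) -> None:
        if self.d_over_ab <= 0:
            raise ValueError("d_over_ab must be > 0")
        if self.bcf <= 0:
            raise ValueError("bcf must be > 0")
        if self.id_percent is not None and not 60.0 <= self.id_percent <= 80.0:
            raise ValueError("id_percent must lie in [60, 80] when present")


@dataclass(frozen=True)
class BCFFit:
    """Fitted BCF model parameters with per-parameter standard deviations."""

    style: Literal["point", "marginal"]
    params: tuple[float, ...]
    param_sd: tuple[float, ...]
    n_samples: int

    @property
    def param_names(self) -> tuple[str, ...]:
        return _POINT_PARAMS if self.style == "point" else _MARGINAL_PARAMS

    def as_dict(self) -> dict:
        return {
            "style": self.style,
            "params": dict(zip(self.param_names, self.params)),
            "sd": dict(zip(self.param_names, self.param_sd)),
            "n": self.n_samples,
        }

    def __call__(self, d_over_ab, id_percent=None):
        if self.style == "point":
            return eval_bcf_point(d_over_ab, *self.params)
        if id_percent is None:
            raise ValueError("marginal fit evaluation requires id_percent")
        return eval_bcf_marginal(d_over_ab, id_percent, *self.params)


def compute_bcf(bdm: MarginResult, pdm: MarginResult) -> float:
    """BCF = BDM / PDM for a matched axis pair of margin results."""
    if bdm.axis != pdm.axis:
        raise ValueError(f"axis mismatch: BDM {bdm.axis} vs PDM {pdm.axis}")
    if pdm.margin_mm <= 0:
        raise ZeroDivisionError("PDM is zero: BCF undefined")
    return bdm.margin_mm / pdm.margin_mm


def _check_positive(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("d_over_ab must be > 0 (ln argument)")
    return x


def eval_bcf_point(d_over_ab, A: float, B: float):
    """Point-prescription model A·ln(d/(α/β)) + B."""
    x = _check_positive(d_over_ab)
    out = A * np.log(x) + B
    return float(out) if out.ndim == 0 else out


def eval_bcf_marginal(d_over_ab, id_percent, C: float, D: float, E: float, F: float):
    """Marginal-prescription model (C·ID + D)·ln(d/(α/β)) + (E·ID + F)."""
    x = _check_positive(d_over_ab)
    idp = np.asarray(id_percent, dtype=float)
    out = (C * idp + D) * np.log(x) + (E * idp + F)
    return float(out) if out.ndim == 0 else out


def _design(samples: Sequence[BCFSample], style: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([s.d_over_ab for s in samples], dtype=float)
    y = np.array([s.bcf for s in samples], dtype=float)
    lx = np.log(_check_positive(x))
    if style == "point":
        X = np.column_stack([lx, np.ones_like(lx)])
    else:
        ids = [s.id_percent for s in samples]
        if any(i is None for i in ids):
            raise ValueError("marginal fit requires id_percent on every sample")
        idp = np.asarray(ids, dtype=float)
        if np.unique(idp).size < 2:
            raise ValueError(
                "rank-deficient design: marginal fit needs >= 2 distinct isodose levels"
            )
        X = np.column_stack([idp * lx, lx, idp, np.ones_like(lx)])
    return X, y


def fit_bcf(
    samples: Iterable[BCFSample],
    style: Literal["point", "marginal"],
    sd_method: Literal["analytic", "bootstrap"] = "analytic",
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> BCFFit:
    """Least-squares fit of the BCF model for one prescription style.

    Both model forms are linear in their parameters, so the estimate is the
    exact normal-equations solution.  ``sd_method="analytic"`` uses the
    linear-model covariance σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n−p); ``"bootstrap"``
    resamples the samples with replacement.
    """
    samples = list(samples)
    if style not in ("point", "marginal"):
        raise ValueError("style must be 'point' or 'marginal'")
    X, y = _design(samples, style)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} samples for the {style} model, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "rank-deficient design: the regressors do not span the model parameters "
            "(e.g. a single d/(α/β) value)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if sd_method == "analytic":
        if n > p:
            sigma2 = float(resid @ resid) / (n - p)
            cov = sigma2 * np.linalg.inv(X.T @ X)
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        else:
            sd = np.full(p, np.nan)
    elif sd_method == "bootstrap":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        boot = np.empty((n_boot, p))
        for b in range(n_boot):
            take = gen.integers(0, n, size=n)
            boot[b], *_ = np.linalg.lstsq(X[take], y[take], rcond=None)
        sd = boot.std(axis=0, ddof=1)
    else:
        raise ValueError("sd_method must be 'analytic' or 'bootstrap'")
    return BCFFit(style, tuple(map(float, beta)), tuple(map(float, sd)), n)


def pooled_bcf_stats(samples: Iterable[BCFSample]) -> pd.DataFrame:
    """Mean and SEM of the BCF per (style group, isodose level, d/(α/β)).

    Pools the cardinal directions: SEM = sample SD (ddof=1) / sqrt(n).
    Groups of size 1 report the mean with SEM missing (NaN).
    """
    rows = [
        {
            "id_percent": s.id_percent if s.id_percent is not None else np.nan,
            "d_over_ab": s.d_over_ab,
            "bcf": s.bcf,
        }
        for s in samples
    ]
    if not rows:
        raise ValueError("no samples to pool")
    df = pd.DataFrame(rows)
    grouped = df.groupby(["id_percent", "d_over_ab"], dropna=False)["bcf"]
    out = grouped.agg(
        mean="mean",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        n="size",
    ).reset_index()
    return out
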
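"""Causal-effect estimands over counterfactual estimates.

Given per-patient factual outcomes and model-estimated counterfactuals, the
three estimands are:

* ICE — individual causal effect: the factual outcome contrasted with the
  estimated outcome under the opposite intervention arm,
  ``y(1) - yhat(0)`` for treated patients and ``yhat(1) - y(0)`` for
  untreated ones.
* AICE — the group-level aggregation of squared ICE terms,
  ``sqrt(sum ICE_i^2 / n)`` under the default root convention (a magnitude
  on the Gleason-Score scale); the plain mean of squares is available via
  ``convention="mean-square"``.
* RMSE — root mean squared factual-arm reconstruction error,
  ``sqrt(sum (yhat(t_i) - y(t_i))^2 / n)``, measuring inference precision.

Each patient contributes exactly one summand to each estimand.  The signed
mean ICE is additionally exposed: AICE aggregates squares and so orders
groups by effect magnitude, not direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONVENTIONS = ("root", "mean-square")


@dataclass
class CounterfactualEstimates:
    """Per-patient potential-outcome estimates from a fitted model.

    All arrays are aligned, length n.  ``ice`` follows the two-branch
    definition; it is computed on construction and checked if supplied.
    """

    y_hat_0: np.ndarray
    y_hat_1: np.ndarray
    t_factual: np.ndarray
    y_factual: np.ndarray
    ice: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.y_hat_0 = np.asarray(self.y_hat_0, dtype=float)
        self.y_hat_1 = np.asarray(self.y_hat_1, dtype=float)
        self.t_factual = np.asarray(self.t_factual, dtype=int)
        self.y_factual = np.asarray(self.y_factual, dtype=float)
        n = len(self.y_factual)
        if not (len(self.y_hat_0) == len(self.y_hat_1) == len(self.t_factual) == n):
            raise ValueError("estimate arrays must have equal length")
        if not np.isin(self.t_factual, (0, 1)).all():
            raise ValueError("t_factual must be binary")
        if not (np.isfinite(self.y_hat_0).all() and np.isfinite(self.y_hat_1).all()):
            raise ValueError("counterfactual estimates must be finite")
        expected = ice_vector(self.y_factual, self.y_hat_0, self.y_hat_1, self.t_factual)
        if self.ice is None:
            self.ice = expected
        elif not np.allclose(self.ice, expected, atol=1e-9):
            raise ValueError("supplied ICE values disagree with the two-branch definition")

    @property
    def n(self) -> int:
        return len(self.y_factual)

    @property
    def y_hat_factual(self) -> np.ndarray:
        return np.where(self.t_factual == 1, self.y_hat_1, self.y_hat_0)

    def subset(self, mask) -> "CounterfactualEstimates":
        m = np.asarray(mask)
        return CounterfactualEstimates(
            self.y_hat_0[m], self.y_hat_1[m], self.t_factual[m], self.y_factual[m]
        )


def ice(y_factual: float, y_hat_other_arm: float, t_factual: int) -> float:
    """Individual causal effect for one patient.

    For a treated patient (t=1) the counterfactual is the untreated arm:
    ``y(1) - yhat(0)``.  For an untreated patient: ``yhat(1) - y(0)``.
    """
    if t_factual == 1:
        return float(y_factual - y_hat_other_arm)
    if t_factual == 0:
        return float(y_hat_other_arm - y_factual)
    raise ValueError(f"t_factual must be 0 or 1, got {t_factual!r}")


def ice_vector(y_factual, y_hat_0, y_hat_1, t_factual) -> np.ndarray:
    y_factual = np.asarray(y_factual, dtype=float)
    t = np.asarray(t_factual)
    return np.where(t == 1, y_factual - np.asarray(y_hat_0, dtype=float),
                    np.asarray(y_hat_1, dtype=float) - y_factual)


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")


def aice(estimates: CounterfactualEstimates, convention: str = "root") -> float:
    """Average individual causal effect of a group (squared-term aggregate).

    ``sqrt([sum_{t=0}(yhat(1)-y(0))^2 + sum_{t=1}(y(1)-yhat(0))^2] / n)``
    under the root convention (default); without the root under
    ``"mean-square"``.
    """
    _check_convention(convention)
    if estimates.n == 0:
        raise ValueError("AICE is undefined for an empty group")
    mean_sq = float(np.mean(estimates.ice**2))
    return float(np.sqrt(mean_sq)) if convention == "root" else mean_sq


def rmse(estimates: CounterfactualEstimates) -> float:
    """Root mean squared factual-arm reconstruction error of a group."""
    if estimates.n == 0:
        raise ValueError("RMSE is undefined for an empty group")
    resid = estimates.y_hat_factual - estimates.y_factual
    return float(np.sqrt(np.mean(resid**2)))


def mean_ice(estimates: CounterfactualEstimates) -> float:
    """Signed mean ICE (directional companion to the magnitude-only AICE)."""
    if estimates.n == 0:
        raise ValueError("mean ICE is undefined for an empty group")
    return float(np.mean(estimates.ice))


@dataclass
class GroupMetrics:
    """AICE/RMSE for one (race, grade, aberration) cell with CV replicates."""

    race: str
    grade: str
    aberration: str
    aice: float
    rmse: float
    n: int
    convention: str = "root"
    replicate_values: list[tuple[float, float]] = field(default_factory=list)
    replicate_mean_ice: list[float] = field(default_factory=list)
    replicate_grs: list[float] = field(default_factory=list)

    def __post_init__(self):
        _check_convention(self.convention)
        if self.n < 1:
            raise ValueError("a group must contain at least one patient")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
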
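"""Synthetic cohort generation.

Cohorts are drawn from a ``p``-variate Gaussian with unit variances and a
compound-symmetric (exchangeable) correlation structure: every pair of
indicators shares the same correlation ``rho``.  With one latent group the
population is homogeneous (mean zero).  With two latent groups, group 2 is
shifted by a standardized mean difference ``d`` on *every* indicator, and
each sampled unit belongs to either group with probability 1/2 (a binomial
split, so group sizes are equal only on average).

Effect size and correlation are themselves drawn per dataset from uniform
distributions, reflecting a-priori uncertainty in a design analysis:
``d ~ U(a, b)`` and ``rho ~ U(c, d)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioSpec",
    "Dataset",
    "min_valid_rho",
    "sample_scenario_params",
    "build_covariance",
    "generate_dataset",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of a simulation grid.

    Parameters
    ----------
    p
        Number of indicators (clustering variables), at least 2.
    n
        Sample size (number of individuals), at least 2.
    true_k
        True number of latent groups, 1 or 2.  With ``true_k=1`` the
        effect-size range is ignored and the effect is fixed at 0.
    d_range
        Bounds ``(a, b)`` of the uniform distribution of the standardized
        mean difference between the two groups (Cohen's d, dimensionless).
    rho_range
        Bounds ``(c, d)`` of the uniform distribution of the common pairwise
        correlation between indicators.
    label
        Free-text scenario identifier used in summaries and seeding.
    """

    p: int
    n: int
    true_k: int
    d_range: tuple[float, float] = (0.0, 0.0)
    rho_range: tuple[float, float] = (0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError(f"p must be >= 2, got {self.p}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.true_k not in (1, 2):
            raise ValueError(f"true_k must be 1 or 2, got {self.true_k}")
        a, b = self.d_range
        if a > b:
            raise ValueError(f"d_range must satisfy a <= b, got {self.d_range}")
        c, d = self.rho_range
        if not (-1.0 < c <= d < 1.0):
            raise ValueError(
                f"rho_range must satisfy -1 < c <= d < 1, got {self.rho_range}"
            )

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "n": self.n,
            "true_k": self.true_k,
            "d_range": list(self.d_range),
            "rho_range": list(self.rho_range),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            p=d["p"],
            n=d["n"],
            true_k=d["true_k"],
            d_range=tuple(d.get("d_range", (0.0, 0.0))),
            rho_range=tuple(d.get("rho_range", (0.0, 0.0))),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class Dataset:
    """A generated cohort: indicator matrix plus ground truth."""

    x: np.ndarray                 # (n, p) indicator values
    true_labels: np.ndarray       # (n,) group ids in {1, 2}
    d_drawn: float                # realized standardized mean difference
    rho_drawn: float              # realized pairwise correlation
    spec: ScenarioSpec | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.x.shape[0] != self.true_labels.shape[0]:
            raise ValueError("x and true_labels must have the same length")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"v{j + 1}" for j in range(self.p)]
        frame = pd.DataFrame(self.x, columns=cols)
        frame["true_label"] = self.true_labels
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, d_drawn: float = np.nan, rho_drawn: float = np.nan) -> "Dataset":
        frame = pd.read_csv(path)
        labels = frame.pop("true_label").to_numpy()
        return cls(
            x=frame.to_numpy(dtype=float),
            true_labels=labels.astype(int),
            d_drawn=d_drawn,
            rho_drawn=rho_drawn,
        )


def min_valid_rho(p: int) -> float:
    """Lower bound of admissible exchangeable correlations for dimension p.

    A compound-symmetric correlation matrix is positive definite iff
    ``rho > -1/(p-1)`` (its smallest eigenvalue is ``1 - rho``, attained with
    multiplicity p-1, and ``1 + (p-1) rho`` with multiplicity 1).
    """
    return -1.0 / (p - 1)


def sample_scenario_params(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[float, float]:
    """Draw the per-dataset effect size and correlation for a scenario.

    Returns ``(d, rho)``.  ``d`` is 0 exactly when ``true_k == 1``; otherwise
    it is uniform on ``d_range``.  ``rho`` is uniform on ``rho_range``, then
    truncated (with a warning) to the admissible region of the
    compound-symmetry structure, which matters only for wide negative ranges
    at large p (e.g. rho = -0.10 with p = 12).
    """
    a, b = spec.d_range
    d = 0.0 if spec.true_k == 1 else float(rng.uniform(a, b))
    c, e = spec.rho_range
    rho = float(rng.uniform(c, e))
    lo = min_valid_rho(spec.p) + 1e-6
    if rho < lo:
        warnings.warn(
            f"sampled rho={rho:.4f} is inadmissible for p={spec.p} "
            f"(requires rho > {min_valid_rho(spec.p):.4f}); truncating to {lo:.6f}",
            RuntimeWarning,
            stacklevel=2,
        )
        rho = lo
    return d, rho


def build_covariance(p: int, rho: float) -> np.ndarray:
    """Compound-symmetric covariance: unit diagonal, ``rho`` off-diagonal."""
    if p < 2:
        raise ValueError(f"p must be >= 2, got {p}")
    if rho <= min_valid_rho(p):
        raise ValueError(
            f"rho={rho} yields a non-positive-definite matrix for p={p}; "
            f"need rho > -1/(p-1) = {min_valid_rho(p):.6f}"
        )
    cov = np.full((p, p), rho, dtype=float)
    np.fill_diagonal(cov, 1.0)
    return cov


def generate_dataset(spec: ScenarioSpec, rng: np.random.Generator) -> Dataset:
    """Generate one cohort under a scenario.

    Rows are independent draws from ``N_p(mu_g, Sigma(rho))`` where
    ``mu_g = d * 1`` for group 2 and ``0`` for group 1.  Group membership is
    an independent fair coin per unit, so on average ``n_1 = n_2 = n / 2``.
    """
    d, rho = sample_scenario_params(spec, rng)
    cov = build_covariance(spec.p, rho)
    if spec.true_k == 1:
        labels = np.ones(spec.n, dtype=int)
    else:
        labels = 1 + (rng.random(spec.n) < 0.5).astype(int)
    x = rng.multivariate_normal(
        np.zeros(spec.p), cov, size=spec.n, method="cholesky"
    )
    x[labels == 2] += d
    return Dataset(x=x, true_labels=labels, d_drawn=d, rho_drawn=rho, spec=spec)
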
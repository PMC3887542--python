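"""Mating preference functions and population-level attractiveness ranking.

Two standard single-chooser preference-function classes are implemented:

* **Open-ended**: the response to a mate with trait value ``t`` is
  proportional to ``exp(y * ln t) = t**y``.  Every chooser with the same
  sign of the steepness ``y`` ranks mates identically; choosers differ
  only in how steeply response rises with the trait.

* **Unimodal**: the response is Gaussian in the trait,
  ``exp(-(t - y)**2 / (2 * nu**2))``, peaking at the chooser's peak
  preference ``y`` with width ``nu``.  When peaks vary among choosers,
  different choosers rank the same mates differently.

A population of choosers is summarised by a response matrix (rows =
choosers, columns = candidate mates), each row normalised so it can be
read as a per-chooser distribution of mating probability over mates.
Averaging rows gives the population-level preference function; ranking
mates by that average gives the attractiveness ranks used to re-express
each chooser's function on a common, trait-free axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PreferenceModel",
    "MaleTrait",
    "PreferenceSpec",
    "PopulationSpec",
    "ResponseMatrix",
    "open_ended_response",
    "unimodal_response",
    "default_trait_grid",
    "sample_population",
    "log_response_matrix",
    "response_matrix",
    "population_preference",
    "rank_males",
    "preference_by_rank",
]


class PreferenceModel(str, Enum):
    """Preference-function class."""

    OPEN_ENDED = "open_ended"
    UNIMODAL = "unimodal"


@dataclass(frozen=True)
class MaleTrait:
    """A candidate mate's trait value.

    The open-ended model consumes the natural log of the trait
    (``z_log``); the unimodal model consumes the raw value ``t``.
    """

    t: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t <= 0:
            raise ValueError(f"trait value must be positive and finite, got {self.t}")

    @property
    def z_log(self) -> float:
        return float(np.log(self.t))


@dataclass(frozen=True)
class PreferenceSpec:
    """One chooser's preference function.

    Parameters
    ----------
    model
        Preference-function class.
    y
        Steepness (open-ended) or peak location in trait units (unimodal).
    nu
        Width in trait units; required positive for the unimodal model,
        ignored by the open-ended model.
    """

    model: PreferenceModel
    y: float
    nu: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.y):
            raise ValueError("preference parameter y must be finite")
        if PreferenceModel(self.model) is PreferenceModel.UNIMODAL:
            if self.nu is None or not np.isfinite(self.nu) or self.nu <= 0:
                raise ValueError(f"unimodal width nu must be positive, got {self.nu}")

    def response(self, trait: float | MaleTrait) -> float:
        """Unnormalised response to a single mate."""
        male = trait if isinstance(trait, MaleTrait) else MaleTrait(float(trait))
        if PreferenceModel(self.model) is PreferenceModel.OPEN_ENDED:
            return open_ended_response(self.y, male)
        return unimodal_response(self.y, self.nu, male)


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling scheme for a population of choosers.

    Defaults follow the standard simulation conditions: open-ended
    steepness y ~ Normal(2, 0.3); unimodal peak y ~ Normal(10.5, 2) with
    width nu fixed at 15 or nu ~ Normal(15, 7) when ``nu_sd > 0``.
    """

    model: PreferenceModel
    n_females: int
    y_mean: float
    y_sd: float
    nu_mean: float = 15.0
    nu_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if self.y_sd < 0 or self.nu_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    @classmethod
    def open_ended(cls, n_females: int = 10, y_mean: float = 2.0,
                   y_sd: float = 0.3, seed: int = 0) -> "PopulationSpec":
        return cls(PreferenceModel.OPEN_ENDED, n_females, y_mean, y_sd, seed=seed)

    @classmethod
    def unimodal(cls, n_females: int = 10, y_mean: float = 10.5, y_sd: float = 2.0,
                 nu_mean: float = 15.0, nu_sd: float = 0.0, seed: int = 0) -> "PopulationSpec":
        return cls(PreferenceModel.UNIMODAL, n_females, y_mean, y_sd,
                   nu_mean=nu_mean, nu_sd=nu_sd, seed=seed)


@dataclass
class ResponseMatrix:
    """Per-(chooser, mate) response probabilities over a trait grid.

    ``values[i, j]`` is chooser ``i``'s response to mate ``j``.  With
    ``scale='sum'`` each row sums to one (a per-chooser mating
    distribution over the offered mates); with ``scale='max'`` each
    row's maximum is one.  Rankings are unchanged by either scaling.
    """

    values: np.ndarray
    traits: np.ndarray
    scale: str = "sum"

    @property
    def n_females(self) -> int:
        return self.values.shape[0]

    @property
    def n_males(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: female_id, male_id, male_trait, response."""
        n_f, n_m = self.values.shape
        return pd.DataFrame({
            "female_id": np.repeat(np.arange(n_f), n_m),
            "male_id": np.tile(np.arange(n_m), n_f),
            "male_trait": np.tile(self.traits, n_f),
            "response": self.values.ravel(),
        })


def open_ended_response(y: float, male: MaleTrait | float) -> float:
    """Open-ended response ``exp(y * ln t) = t**y``.

    ``y`` is the chooser's preference steepness; the trait enters on the
    natural-log scale, so the response is a power law in the raw trait.
    """
    m = male if isinstance(male, MaleTrait) else MaleTrait(float(male))
    return float(np.exp(y * m.z_log))


def unimodal_response(y: float, nu: float, male: MaleTrait | float) -> float:
    """Unimodal (Gaussian) response ``exp(-(t - y)**2 / (2 nu**2))``.

    Peaks at 1 when the trait equals the peak preference ``y``; ``nu``
    sets the width in trait units.
    """
    if nu is None or nu <= 0 or not np.isfinite(nu):
        raise ValueError(f"width nu must be positive, got {nu}")
    m = male if isinstance(male, MaleTrait) else MaleTrait(float(male))
    return float(np.exp(-((m.t - y) ** 2) / (2.0 * nu ** 2)))


def default_trait_grid(n_males: int = 10, y_mean: float = 10.5,
                       y_sd: float = 2.0) -> np.ndarray:
    """Evenly spaced male traits spanning ``y_mean ± 3*y_sd``.

    Under the default unimodal peak distribution (mean 10.5, SD 2) this
    is 10 values from 4.5 to 16.5.
    """
    return np.linspace(y_mean - 3 * y_sd, y_mean + 3 * y_sd, n_males)


def sample_population(spec: PopulationSpec,
                      rng: np.random.Generator | None = None) -> list[PreferenceSpec]:
    """Draw a population of chooser preference functions.

    y ~ Normal(y_mean, y_sd).  For the unimodal model, nu ~
    Normal(nu_mean, nu_sd) when ``nu_sd > 0``, rejection-sampled until
    positive (the width must be positive; the mean/SD are preserved
    approximately), else fixed at ``nu_mean``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ys = spec.y_mean + spec.y_sd * rng.standard_normal(spec.n_females)
    model = PreferenceModel(spec.model)
    if model is PreferenceModel.OPEN_ENDED:
        return [PreferenceSpec(model, float(y)) for y in ys]
    if spec.nu_sd > 0:
        nus = np.empty(spec.n_females)
        for i in range(spec.n_females):
            nu = spec.nu_mean + spec.nu_sd * rng.standard_normal()
            while nu <= 0:
                nu = spec.nu_mean + spec.nu_sd * rng.standard_normal()
            nus[i] = nu
    else:
        if spec.nu_mean <= 0:
            raise ValueError("fixed nu_mean must be positive for the unimodal model")
        nus = np.full(spec.n_females, spec.nu_mean)
    return [PreferenceSpec(model, float(y), float(nu)) for y, nu in zip(ys, nus)]


def log_response_matrix(females: Sequence[PreferenceSpec],
                        grid: Sequence[MaleTrait] | np.ndarray) -> np.ndarray:
    """Unnormalised log responses: ``y * ln t`` or ``-(t-y)^2 / (2 nu^2)``.

    Working on the log scale keeps very narrow unimodal preferences
    exact where the raw response would underflow to zero (which would
    create spurious rank ties among distant males).
    """
    traits = np.asarray([m.t if isinstance(m, MaleTrait) else float(m) for m in grid],
                        dtype=float)
    if np.any(traits <= 0) or not np.all(np.isfinite(traits)):
        raise ValueError("male traits must be positive and finite")
    out = np.empty((len(females), traits.size))
    for i, f in enumerate(females):
        if PreferenceModel(f.model) is PreferenceModel.OPEN_ENDED:
            out[i] = f.y * np.log(traits)
        else:
            out[i] = -((traits - f.y) ** 2) / (2.0 * f.nu ** 2)
    return out


def response_matrix(females: Sequence[PreferenceSpec],
                    grid: Sequence[MaleTrait] | np.ndarray,
                    scale: str = "sum") -> ResponseMatrix:
    """Evaluate every chooser's response on a grid of mates.

    Each row is normalised to sum to one (``scale='sum'``) or to peak at
    one (``scale='max'``).
    """
    if len(females) < 1:
        raise ValueError("need at least one female")
    traits = np.asarray([m.t if isinstance(m, MaleTrait) else float(m) for m in grid],
                        dtype=float)
    if traits.size < 2:
        raise ValueError("need at least two males on the trait grid")
    if np.any(traits <= 0) or not np.all(np.isfinite(traits)):
        raise ValueError("male traits must be positive and finite")
    if scale not in ("sum", "max"):
        raise ValueError(f"scale must be 'sum' or 'max', got {scale!r}")

    raw = np.empty((len(females), traits.size))
    for i, f in enumerate(females):
        if PreferenceModel(f.model) is PreferenceModel.OPEN_ENDED:
            raw[i] = np.exp(f.y * np.log(traits))
        else:
            raw[i] = np.exp(-((traits - f.y) ** 2) / (2.0 * f.nu ** 2))
    denom = raw.sum(axis=1, keepdims=True) if scale == "sum" else raw.max(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("a chooser's responses are all zero; cannot normalise")
    return ResponseMatrix(raw / denom, traits, scale=scale)


def population_preference(m: ResponseMatrix) -> np.ndarray:
    """Population-level preference function: column means of the matrix."""
    if m.values.size == 0:
        raise ValueError("empty response matrix")
    return m.values.mean(axis=0)


def rank_males(m: ResponseMatrix) -> np.ndarray:
    """Attractiveness ranks 1..n_males from the population preference.

    Greater rank means more attractive (rank 1 = least attractive);
    ties receive average ranks.
    """
    return rankdata(population_preference(m), method="average")


def preference_by_rank(females: Sequence[PreferenceSpec],
                       grid: Sequence[MaleTrait] | np.ndarray,
                       scale: str = "sum") -> pd.DataFrame:
    """Each chooser's responses re-indexed by population attractiveness rank.

    Returns a DataFrame with one row per chooser and columns 1..n_males
    (ascending attractiveness rank).  When rankings are shared (open-ended,
    or unimodal with a common peak) every row is nondecreasing; variable
    peaks produce rows that disagree in ordering.
    """
    m = response_matrix(females, grid, scale=scale)
    ranks = rank_males(m)
    order = np.argsort(ranks)  # least to most attractive
    reordered = m.values[:, order]
    cols = np.arange(1, m.n_males + 1)
    return pd.DataFrame(reordered, columns=cols)
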
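"""Cell-level growth kinetics of the physis.

Longitudinal growth is modelled as the product of two columnar processes:

* proliferation — ``n_p`` new chondrocytes per column per day, each of
  height ``h_p``, produced in the proliferative zone of width ``l_p``;
* hypertrophy — each post-mitotic chondrocyte swells linearly from ``h_p``
  to a terminal height ``h_max`` over a maturation time ``t_E`` while it
  traverses the hypertrophic zone of width ``l_h``.

In steady state the growth rate is ``G = n_p * h_max``, and the local
strain-rate (growth) tensor is rank-one along the preferential growth
direction ``n``: the proliferative contribution is ``(n_p h_p / l_p) n (x) n``
and the hypertrophic contribution sums the elongation rate of every cell in
the column.  Sustained axial stress modulates growth through the terminal
hypertrophic height: ``h_max = (1 + D(dsigma_n)) h_max_f``, where
``D`` is a piecewise-linear function of the stress difference
``dsigma_n = sigma_n - sigma_n_f`` calibrated on rat proximal tibia data
(compression shrinks the terminal cell, tension enlarges it, per the
Hueter-Volkmann law).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellDistribution",
    "KineticState",
    "ChondrocyteColumn",
    "GrowthRateTensor",
    "stress_difference",
    "d_hmax",
    "max_hypertrophic_height",
    "chondrocyte_height",
    "growth_rate",
    "time_step",
    "proliferation_strain_rate",
    "hypertrophy_strain_rate",
    "growth_tensor",
    "distribution_tensor",
    "steady_state_column",
]

#: Default growth direction: +y, the longitudinal axis of the bone.
GROWTH_DIRECTION = np.array([0.0, 1.0])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellDistribution:
    """Columnar arrangement of chondrocytes in one zone.

    ``anisotropy_ratio`` is the number of cells along the growth direction
    per cell in the transverse direction; the mesh is built so that every
    columnar-zone element contains exactly one cell, i.e. the ratio is 1.
    ``concentration`` (cells per volume) is optional bookkeeping: no
    numerical value is required by the growth laws.
    """

    anisotropy_ratio: float = 1.0
    growth_direction: np.ndarray = field(default_factory=lambda: GROWTH_DIRECTION.copy())
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.anisotropy_ratio <= 0:
            raise ValueError("anisotropy_ratio must be positive")
        n = np.asarray(self.growth_direction, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0):
            raise ValueError("growth_direction must be a unit vector")


@dataclass(frozen=True)
class KineticState:
    """Scalar kinetic parameters of one load case.

    n_p        proliferation rate, cells/day
    h_p        proliferative cell height, um
    h_max      terminal hypertrophic height under the current load, um
    t_E        full maturation time of a hypertrophic cell, days
    l_p, l_h   proliferative / hypertrophic zone widths, um
    """

    n_p: float
    h_p: float
    h_max: float
    t_E: float
    l_p: float
    l_h: float

    def __post_init__(self) -> None:
        for name in ("n_p", "h_p", "h_max", "t_E", "l_p", "l_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.h_p >= self.h_max:
            raise ValueError("proliferative height h_p must be below h_max")


@dataclass
class ChondrocyteColumn:
    """State of one chondrocyte column.

    ``hypertrophic_cells`` is ordered from youngest (adjacent to the
    proliferative zone) to oldest (about to undergo apoptosis); each entry
    is ``(maturation_age days, height um)``.
    """

    proliferative_count: int
    hypertrophic_cells: list[tuple[float, float]]

    def heights(self) -> np.ndarray:
        return np.array([h for _, h in self.hypertrophic_cells])

    def ages(self) -> np.ndarray:
        return np.array([a for a, _ in self.hypertrophic_cells])


@dataclass(frozen=True)
class GrowthRateTensor:
    """Rank-one growth (strain-rate) tensor ``rate_nn * n (x) n``, 1/day."""

    direction: np.ndarray
    rate_nn: float

    @property
    def tensor(self) -> np.ndarray:
        n = np.asarray(self.direction, dtype=float)
        return self.rate_nn * np.outer(n, n)

    def __add__(self, other: "GrowthRateTensor") -> "GrowthRateTensor":
        if not np.allclose(self.direction, other.direction):
            raise ValueError("cannot add growth tensors with different growth directions")
        return GrowthRateTensor(self.direction, self.rate_nn + other.rate_nn)


# ---------------------------------------------------------------------------
# stress modulation of the terminal hypertrophic height
# ---------------------------------------------------------------------------

def stress_difference(sigma_n: float, sigma_n_f: float) -> float:
    """Axial stress difference from the physiological baseline, MPa."""
    return sigma_n - sigma_n_f


def d_hmax(delta_sigma_n: float) -> float:
    """Fractional change of the terminal hypertrophic height under load.

    Piecewise linear in the stress difference, calibrated on the measured
    terminal-height changes in the rat proximal tibia:

    =====================  =============================
    stress difference      D
    =====================  =============================
    dsigma >= 0            +0.35 |dsigma|
    -0.1 <= dsigma < 0     +0.27 |dsigma|
    dsigma < -0.1          -0.47 |dsigma| + 0.074
    =====================  =============================

    Mild compression slightly enlarges the terminal cell while strongly
    reducing proliferation-zone turnover; only beyond -0.1 MPa does the
    terminal height itself fall below baseline.  Note the middle branch has
    a positive slope in |dsigma|: the calibration data (terminal heights of
    36.22, 35.00, 35.94 and 34.30 um at +0.1, 0.0, -0.1 and -0.2 MPa)
    force these signs.
    """
    mag = abs(delta_sigma_n)
    if delta_sigma_n >= 0:
        return 0.35 * mag
    if delta_sigma_n >= -0.1:
        return 0.27 * mag
    return -0.47 * mag + 0.074


def max_hypertrophic_height(delta_sigma_n: float, h_max_f: float = 35.0) -> float:
    """Terminal hypertrophic chondrocyte height under sustained load, um.

    ``h_max = (1 + D(dsigma_n)) * h_max_f``.
    """
    if h_max_f <= 0:
        raise ValueError("h_max_f must be positive")
    return (1.0 + d_hmax(delta_sigma_n)) * h_max_f


# ---------------------------------------------------------------------------
# cell maturation and column-scale rates
# ---------------------------------------------------------------------------

def chondrocyte_height(h_p: float, h_max: float, maturation_age: float, t_E: float) -> float:
    """Height of a hypertrophying chondrocyte at a given maturation age, um.

    Linear ramp from ``h_p`` at age 0 to ``h_max`` at age ``t_E``.
    """
    if not 0 <= maturation_age <= t_E:
        raise ValueError(
            f"maturation_age={maturation_age} outside [0, t_E={t_E}]: the cell is "
            "either not yet hypertrophic or already fully mature"
        )
    return h_p + (h_max - h_p) * (maturation_age / t_E)


def growth_rate(n_p: float, h_max: float) -> float:
    """Steady-state longitudinal growth rate ``G = n_p * h_max``, um/day."""
    if n_p < 0:
        raise ValueError("proliferation rate n_p must be non-negative")
    if h_max <= 0:
        raise ValueError("h_max must be positive")
    return n_p * h_max


def time_step(h_max: float, G: float) -> float:
    """Iteration interval ``dt = h_max / G``, days.

    Chosen so exactly one cell proliferates and one mature hypertrophic
    cell undergoes apoptosis per interval (equilibrium turnover).
    """
    if G <= 0:
        raise ValueError(f"growth rate must be positive to define a time step, got {G}")
    return h_max / G


def proliferation_strain_rate(
    n_p: float, h_p: float, l_p: float, n: np.ndarray = GROWTH_DIRECTION
) -> GrowthRateTensor:
    """Growth tensor of the proliferative zone: ``(n_p h_p / l_p) n (x) n``."""
    if l_p <= 0:
        raise ValueError("proliferative zone width l_p must be positive")
    return GrowthRateTensor(np.asarray(n, dtype=float), n_p * h_p / l_p)


def hypertrophy_strain_rate(
    column: ChondrocyteColumn, h_p: float, l_h: float, n: np.ndarray = GROWTH_DIRECTION
) -> GrowthRateTensor:
    """Growth tensor of the hypertrophic zone.

    Sums the mean elongation rate ``(h_i - h_p) / age_i`` of every
    hypertrophic cell in the column and divides by the zone width:
    ``(1/l_h) sum_i (h_i - h_p)/age_i * n (x) n``.
    """
    if l_h <= 0:
        raise ValueError("hypertrophic zone width l_h must be positive")
    total = 0.0
    for age, h_i in column.hypertrophic_cells:
        if age <= 0:
            if h_i > h_p:
                raise ValueError(
                    "hypertrophic cell with zero maturation age but height above h_p"
                )
            continue  # cell at onset contributes no elongation yet
        total += (h_i - h_p) / age
    return GrowthRateTensor(np.asarray(n, dtype=float), total / l_h)


def growth_tensor(d_prolif: GrowthRateTensor, d_hyper: GrowthRateTensor) -> GrowthRateTensor:
    """Total growth tensor: proliferative + hypertrophic contributions."""
    return d_prolif + d_hyper


def distribution_tensor(dist: CellDistribution) -> np.ndarray:
    """Second-order cell-distribution tensor of a columnar zone.

    Only the isotropic case (one cell per element in both directions,
    ratio 1) is supported; there the transversely isotropic form collapses
    to ``C * I`` (or the bare identity when no concentration is set).  The
    general anisotropic form is deliberately not implemented: its published
    expression is ambiguous and no simulation requires it.
    """
    if not np.isclose(dist.anisotropy_ratio, 1.0):
        raise NotImplementedError(
            "anisotropic cell distributions (ratio != 1) are unsupported: the "
            "transversely isotropic tensor form is ambiguous in the source data "
            "and only ratio 1 is exercised by the model"
        )
    scale = 1.0 if dist.concentration is None else dist.concentration
    return scale * np.eye(2)


# ---------------------------------------------------------------------------
# steady-state column construction
# ---------------------------------------------------------------------------

def steady_state_column(
    n_prolif: int, n_hyper: int, h_p: float, h_max: float, dt: float
) -> ChondrocyteColumn:
    """Column in maturation equilibrium.

    The i-th hypertrophic cell (1-based from the proliferative border) has
    age ``i * dt``; with ``t_E = n_hyper * dt`` its height follows the
    linear maturation ramp, so the oldest cell sits exactly at ``h_max``.
    """
    t_E = n_hyper * dt
    cells = [
        (i * dt, chondrocyte_height(h_p, h_max, i * dt, t_E))
        for i in range(1, n_hyper + 1)
    ]
    return ChondrocyteColumn(proliferative_count=n_prolif, hypertrophic_cells=cells)
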
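"""Material, geometric and kinetic parameter fixtures for the rat proximal tibia.

All constants used by the model are shipped as small human-readable text
files under :mod:`growthplate.data` and exposed through typed accessors, so
the rest of the package needs no external data.  The parameter set covers
four sustained axial load cases (stress difference from the physiological
baseline, tension positive): +0.1, 0.0, -0.1 and -0.2 MPa.  For each case
the fixtures give the cartilage zone thicknesses, the per-column chondrocyte
counts, the experimentally derived growth rate, the terminal hypertrophic
cell height and the resulting iteration time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "Tissue",
    "TissueProperties",
    "LoadCaseTable",
    "PhysiologicalConstants",
    "get_tissue",
    "get_load_case",
    "load_case_table",
    "get_constants",
    "TABULATED_LOAD_CASES",
]


class Tissue(str, Enum):
    """Tissue regions of the analysis domain, bottom to top of the physis."""

    TRABECULAR_BONE = "trabecular_bone"
    HYPERTROPHIC = "hypertrophic"
    PROLIFERATIVE = "proliferative"
    RESERVE = "reserve"


@dataclass(frozen=True)
class TissueProperties:
    """Linear isotropic elastic properties of one tissue."""

    tissue_name: Tissue
    youngs_modulus: float  # MPa
    poisson_ratio: float   # dimensionless

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.youngs_modulus}")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {self.poisson_ratio}")


@dataclass(frozen=True)
class LoadCaseTable:
    """Full parameter row for one sustained-load case.

    ``zone_thicknesses`` is (reserve, proliferative, hypertrophic) in um,
    ``cells_per_column`` is (proliferative, hypertrophic) counts.
    ``delta_t`` is the iteration interval h_max / G_stokes in days: one
    proliferation and one apoptosis event occur per interval.
    """

    delta_sigma_n: float                        # MPa
    zone_thicknesses: tuple[float, float, float]  # um
    cells_per_column: tuple[int, int]
    G_stokes: float                             # um/day
    h_max: float                                # um
    delta_t: float                              # days

    @property
    def reserve_thickness(self) -> float:
        return self.zone_thicknesses[0]

    @property
    def proliferative_thickness(self) -> float:
        return self.zone_thicknesses[1]

    @property
    def hypertrophic_thickness(self) -> float:
        return self.zone_thicknesses[2]

    @property
    def proliferative_cells(self) -> int:
        return self.cells_per_column[0]

    @property
    def hypertrophic_cells(self) -> int:
        return self.cells_per_column[1]


@dataclass(frozen=True)
class PhysiologicalConstants:
    """Load-independent constants of the rat proximal tibia model."""

    h_max_f: float = 35.0        # um, terminal hypertrophic height at baseline
    columns: int = 20
    column_spacing: float = 40.0  # um
    domain_side: float = 800.0    # um
    duration: float = 23.0        # days
    sigma_n_f: float = 0.0        # MPa, physiological axial stress baseline

    def __post_init__(self) -> None:
        if self.columns * self.column_spacing > self.domain_side:
            raise ValueError("columns * column_spacing exceeds the domain width")


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("growthplate.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def _tissue_fixtures() -> dict[Tissue, TissueProperties]:
    df = _read_csv("tissues.csv")
    out = {}
    for row in df.itertuples(index=False):
        t = Tissue(row.tissue_name)
        out[t] = TissueProperties(t, float(row.youngs_modulus_MPa), float(row.poisson_ratio))
    return out


def _load_case_fixtures() -> dict[float, LoadCaseTable]:
    df = _read_csv("load_cases.csv")
    out = {}
    for row in df.itertuples(index=False):
        lc = LoadCaseTable(
            delta_sigma_n=float(row.delta_sigma_n_MPa),
            zone_thicknesses=(
                float(row.reserve_um),
                float(row.proliferative_um),
                float(row.hypertrophic_um),
            ),
            cells_per_column=(int(row.proliferative_cells), int(row.hypertrophic_cells)),
            G_stokes=float(row.G_stokes_um_per_day),
            h_max=float(row.h_max_um),
            delta_t=float(row.delta_t_days),
        )
        out[lc.delta_sigma_n] = lc
    return out


_TISSUES = _tissue_fixtures()
_LOAD_CASES = _load_case_fixtures()

#: The four experimentally characterised stress differences, MPa.
TABULATED_LOAD_CASES: tuple[float, ...] = tuple(sorted(_LOAD_CASES))


def get_tissue(tissue_name: Tissue | str) -> TissueProperties:
    """Return the elastic properties of one tissue region.

    Parameters
    ----------
    tissue_name
        One of ``trabecular_bone``, ``reserve``, ``proliferative``,
        ``hypertrophic`` (or the :class:`Tissue` member).
    """
    try:
        key = Tissue(tissue_name)
    except ValueError:
        valid = ", ".join(t.value for t in Tissue)
        raise KeyError(f"unknown tissue {tissue_name!r}; valid tissues: {valid}") from None
    return _TISSUES[key]


def _match_case(delta_sigma_n: float) -> float | None:
    for key in _LOAD_CASES:
        if math.isclose(key, delta_sigma_n, abs_tol=1e-9):
            return key
    return None


def get_load_case(delta_sigma_n: float, *, interpolate: bool = False) -> LoadCaseTable:
    """Return the tabulated parameter row for a sustained stress difference.

    Only the four experimentally characterised cases (+0.1, 0.0, -0.1,
    -0.2 MPa) have measured zone thicknesses and cell counts.  With
    ``interpolate=True`` an intermediate stress difference inside the
    tabulated range is served by piecewise-linear interpolation of the
    thickness/cell columns; h_max and the time step are always recomputed
    from the hypertrophy modulation law rather than interpolated.
    """
    key = _match_case(delta_sigma_n)
    if key is not None:
        return _LOAD_CASES[key]
    if not interpolate:
        valid = ", ".join(f"{k:+.1f}" for k in TABULATED_LOAD_CASES)
        raise KeyError(
            f"delta_sigma_n={delta_sigma_n} MPa is not a tabulated load case "
            f"(valid: {valid} MPa); pass interpolate=True to interpolate "
            "between tabulated cases"
        )
    lo, hi = TABULATED_LOAD_CASES[0], TABULATED_LOAD_CASES[-1]
    if not lo <= delta_sigma_n <= hi:
        raise ValueError(
            f"cannot extrapolate outside the tabulated range [{lo}, {hi}] MPa"
        )
    # local import: kinetics depends on this module for its fixtures
    from . import kinetics

    df = load_case_table().sort_values("delta_sigma_n_MPa")
    x = df["delta_sigma_n_MPa"].to_numpy()

    def interp(col: str) -> float:
        import numpy as np

        return float(np.interp(delta_sigma_n, x, df[col].to_numpy()))

    h_max = kinetics.max_hypertrophic_height(delta_sigma_n)
    G = interp("G_stokes_um_per_day")
    return LoadCaseTable(
        delta_sigma_n=float(delta_sigma_n),
        zone_thicknesses=(
            interp("reserve_um"),
            interp("proliferative_um"),
            interp("hypertrophic_um"),
        ),
        cells_per_column=(
            round(interp("proliferative_cells")),
            round(interp("hypertrophic_cells")),
        ),
        G_stokes=G,
        h_max=h_max,
        delta_t=h_max / G,
    )


def load_case_table() -> pd.DataFrame:
    """The full load-case fixture as a DataFrame (one row per stress case)."""
    return _read_csv("load_cases.csv")


def get_constants() -> PhysiologicalConstants:
    """Physiological constants loaded from the shipped fixture file."""
    with resources.files("growthplate.data").joinpath("constants.yaml").open("r") as fh:
        raw = yaml.safe_load(fh)
    return PhysiologicalConstants(
        h_max_f=float(raw["h_max_f_um"]),
        columns=int(raw["columns"]),
        column_spacing=float(raw["column_spacing_um"]),
        domain_side=float(raw["domain_side_um"]),
        duration=float(raw["duration_days"]),
        sigma_n_f=float(raw["sigma_n_f_MPa"]),
    )
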
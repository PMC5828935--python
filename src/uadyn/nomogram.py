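"""Steady-state treatment-planning nomograms.

For a patient characterized by baseline serum uric acid, GFR and baseline
fractional excretion ("parametype"), the steady-state relations give the
percent change in serum concentration and urinary excretion for any
combination of production-rate inhibition (xanthine oxidase inhibitor
axis) and fractional-excretion increment (uricosuric axis).  The baseline
production rate is back-calculated from the stated baseline concentration,
so the grids are anchored at the patient's observed serum level.

Closed forms used throughout (derived from the steady-state relations):

    serum ratio   = (1 - i) * (cl_i + gfr*fe0) / (cl_i + gfr*(fe0 + d))
    required  i   = 1 - (1 - target) * (cl_i + gfr*(fe0 + d)) / (cl_i + gfr*fe0)
    urine amount  = kp * (1 - i) * gfr*(fe0 + d) / (cl_i + gfr*(fe0 + d)) * 24

with ``i`` the inhibition fraction and ``d`` the excretion increment.
Along a fixed-target contour the urine amount reduces to
``[S]_base * (1 - target) * gfr * (fe0 + d) * 24``, which is independent
of the intestinal clearance -- the reason the urinary side of the nomogram
is insensitive to the CL_I uncertainty band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MG_DL_TO_MG_L, ML_MIN_TO_L_H

__all__ = [
    "NomogramSpec",
    "NomogramGrid",
    "SensitivityBand",
    "build_grid",
    "required_inhibition",
    "urine_excretion_at",
    "sensitivity_band",
]


@dataclass(frozen=True)
class NomogramSpec:
    """Patient parametype and grid layout for one nomogram."""

    sua_base_mg_dl: float = 12.0
    gfr_ml_min: float = 60.0
    fe0: float = 0.03
    cl_i: float = 0.27
    cl_i_range: tuple[float, float] = (0.19, 0.36)
    inhibitions: tuple[float, ...] = tuple(np.linspace(0.0, 0.9, 101))
    increments: tuple[float, ...] = tuple(np.linspace(0.0, 0.15, 101))
    targets: tuple[float, ...] = (0.5,)

    def __post_init__(self) -> None:
        if not self.sua_base_mg_dl > 0 or not self.gfr_ml_min > 0:
            raise ValueError("baseline serum UA and GFR must be > 0")
        if not 0 < self.fe0 <= 1:
            raise ValueError(f"fe0 must be in (0, 1], got {self.fe0}")
        if self.fe0 + max(self.increments) > 1:
            raise ValueError("fe0 + max increment must be <= 1")
        if any(not 0 <= i < 1 for i in self.inhibitions):
            raise ValueError("inhibition fractions must be in [0, 1)")
        lo, hi = self.cl_i_range
        if not 0 < lo <= hi:
            raise ValueError("cl_i_range endpoints must be positive and ordered")

    @property
    def gfr(self) -> float:  # L/h
        return self.gfr_ml_min * ML_MIN_TO_L_H

    @property
    def conc_base(self) -> float:  # mg/L
        return self.sua_base_mg_dl * MG_DL_TO_MG_L

    def kp(self, cl_i: float | None = None) -> float:
        """Production rate anchored at the baseline concentration, mg/h."""
        cl = self.cl_i if cl_i is None else cl_i
        return self.conc_base * (cl + self.gfr * self.fe0)


@dataclass
class NomogramGrid:
    """Percent-change matrices over (inhibition x excretion-increment)."""

    inhibitions: np.ndarray  # rows
    increments: np.ndarray  # columns
    serum_pct: np.ndarray  # % change of steady-state serum concentration
    urine_pct: np.ndarray  # % change of steady-state urinary excretion
    urine_mg_24h: np.ndarray  # absolute daily urinary excretion
    spec: NomogramSpec


def build_grid(spec: NomogramSpec) -> NomogramGrid:
    """Evaluate the steady-state percent changes on the full grid."""
    i = np.asarray(spec.inhibitions)[:, None]
    d = np.asarray(spec.increments)[None, :]
    g, cl = spec.gfr, spec.cl_i
    kp = spec.kp()
    cl_total0 = cl + g * spec.fe0
    cl_total = cl + g * (spec.fe0 + d)
    serum_ratio = (1.0 - i) * cl_total0 / cl_total
    x0 = kp * g * spec.fe0 / cl_total0
    x = kp * (1.0 - i) * g * (spec.fe0 + d) / cl_total
    return NomogramGrid(
        inhibitions=np.asarray(spec.inhibitions),
        increments=np.asarray(spec.increments),
        serum_pct=100.0 * (serum_ratio - 1.0),
        urine_pct=100.0 * (x / x0 - 1.0),
        urine_mg_24h=x * 24.0,
        spec=spec,
    )


def required_inhibition(
    target_reduction: float,
    fe_increment: float,
    spec: NomogramSpec,
    cl_i: float | None = None,
) -> float:
    """Production inhibition needed for a target serum reduction.

    Closed form from the steady-state ratio, floored at 0 when the
    excretion increment alone already reaches the target.
    """
    if not 0 < target_reduction < 1:
        raise ValueError(f"target_reduction must be in (0, 1), got {target_reduction}")
    if fe_increment < 0 or spec.fe0 + fe_increment > 1:
        raise ValueError(f"invalid fe_increment {fe_increment}")
    cl = spec.cl_i if cl_i is None else cl_i
    g = spec.gfr
    req = 1.0 - (1.0 - target_reduction) * (cl + g * (spec.fe0 + fe_increment)) / (
        cl + g * spec.fe0
    )
    return max(req, 0.0)


def urine_excretion_at(
    inhibition: float,
    increment: float,
    spec: NomogramSpec,
    cl_i: float | None = None,
) -> tuple[float, float]:
    """Daily urinary excretion (mg/24h, % change vs baseline) at a grid point."""
    if not 0 <= inhibition < 1:
        raise ValueError(f"inhibition must be in [0, 1), got {inhibition}")
    if increment < 0 or spec.fe0 + increment > 1:
        raise ValueError(f"invalid increment {increment}")
    cl = spec.cl_i if cl_i is None else cl_i
    g = spec.gfr
    kp = spec.kp(cl)
    fe = spec.fe0 + increment
    x = kp * (1.0 - inhibition) * g * fe / (cl + g * fe)
    x0 = kp * g * spec.fe0 / (cl + g * spec.fe0)
    return x * 24.0, 100.0 * (x / x0 - 1.0)


@dataclass
class SensitivityBand:
    """Envelope of nomogram outputs over the CL_I uncertainty range.

    For each target reduction, ``required`` maps the excretion-increment
    axis to (lower, central, upper) required inhibition, and
    ``urine_mg_24h`` to the corresponding envelope of daily urinary
    excretion along the target contour.
    """

    increments: np.ndarray
    targets: tuple[float, ...]
    required: dict[float, np.ndarray]  # target -> (3, n) rows lo/center/hi
    urine_mg_24h: dict[float, np.ndarray]  # target -> (3, n)
    cl_i_range: tuple[float, float]


def sensitivity_band(spec: NomogramSpec) -> SensitivityBand:
    """Recompute the nomogram at the CL_I range endpoints and envelope it.

    The central value always lies inside the band.  The production rate is
    re-derived from the baseline concentration at each CL_I value, which is
    what anchors the patient at their observed serum level and makes the
    urinary excretion along a target contour independent of CL_I.
    """
    incs = np.asarray(spec.increments)
    lo, hi = spec.cl_i_range
    cls = (lo, spec.cl_i, hi)
    required: dict[float, np.ndarray] = {}
    urine: dict[float, np.ndarray] = {}
    for target in spec.targets:
        req = np.array(
            [[required_inhibition(target, d, spec, cl_i=c) for d in incs] for c in cls]
        )
        ur = np.array(
            [
                [urine_excretion_at(req[k, j], d, spec, cl_i=c)[0] for j, d in enumerate(incs)]
                for k, c in enumerate(cls)
            ]
        )
        required[target] = np.vstack(
            [req.min(axis=0), req[1], req.max(axis=0)]
        )
        urine[target] = np.vstack([ur.min(axis=0), ur[1], ur.max(axis=0)])
    return SensitivityBand(
        increments=incs,
        targets=tuple(spec.targets),
        required=required,
        urine_mg_24h=urine,
        cl_i_range=spec.cl_i_range,
    )
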
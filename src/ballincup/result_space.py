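"""Gridded evaluation of strategy measures over the 2-D result space.

The four execution variables span a 4-D space of strategies; for analysis
and display the frequency is fixed (1.0 Hz, the metronome pace) and the
initial ball angular velocity set to zero, leaving a 2-D map over cup
amplitude ``A`` (peak-to-peak) and initial ball angle ``theta0``.  Every
cell is simulated once and scored with the full measure set; map-level
quantities (Predictability Index normaliser, MI range for Sensitivity) are
derived after the sweep.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .dynamics import ModelParams, Strategy
from .measures import (
    MeasureSet,
    global_lyapunov_batch,
    measure_strategy,
    mi_sensitivity,
    predictability_index,
)

__all__ = ["MeasureMap", "evaluate_result_space", "locate_optima"]

log = logging.getLogger(__name__)

#: measures selectable in :func:`evaluate_result_space`
MAP_MEASURES = (
    "mi",
    "gle",
    "msf",
    "jerk_ball_norm",
    "jerk_ball_raw",
    "jerk_force_raw",
    "jerk_force_norm",
    "jerk_cup_raw",
    "sal",
    "strobe_force_variance",
    "strobe_force_variance_rel",
    "predictability_index",
    "sensitivity",
)

#: criteria accepted by :func:`locate_optima`
CRITERIA = {
    "max_mi": ("mi", np.nanargmax),
    "min_msf": ("msf", np.nanargmin),
    "min_gle": ("gle", np.nanargmin),
    "min_norm_jerk": ("jerk_ball_norm", np.nanargmin),
}


@dataclass
class MeasureMap:
    """Strategy-measure surfaces over an (amplitude, theta0) grid.

    ``surfaces[name]`` has shape ``(len(amplitude_grid), len(theta0_grid))``;
    failed cells hold NaN and are listed in ``provenance["failed_cells"]``.
    """

    amplitude_grid: np.ndarray
    theta0_grid: np.ndarray
    fixed_frequency: float
    fixed_omega0: float
    surfaces: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.amplitude_grid), len(self.theta0_grid))
        for name, surf in self.surfaces.items():
            if np.shape(surf) != shape:
                raise ValueError(f"surface {name} shape {np.shape(surf)} != {shape}")

    def strategy_at(self, i: int, k: int) -> Strategy:
        return Strategy(
            amplitude_pp=float(self.amplitude_grid[i]),
            frequency=self.fixed_frequency,
            theta0=float(self.theta0_grid[k]),
            omega0=self.fixed_omega0,
        )

    def interpolate(self, name: str, amplitude_pp: float, theta0: float) -> float:
        """Bilinear lookup of one surface at an off-grid strategy."""
        itp = RegularGridInterpolator(
            (self.amplitude_grid, self.theta0_grid),
            self.surfaces[name],
            method="linear",
            bounds_error=True,
        )
        return float(itp((amplitude_pp, theta0)))

    @property
    def mi_range(self) -> float:
        mi = self.surfaces["mi"]
        return float(np.nanmax(mi) - np.nanmin(mi))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (amplitude_pp_m, theta0_rad, measure, value)."""
        rows = []
        for name, surf in self.surfaces.items():
            for i, a in enumerate(self.amplitude_grid):
                for k, th in enumerate(self.theta0_grid):
                    rows.append((float(a), float(th), name, float(surf[i, k])))
        return pd.DataFrame(
            rows, columns=["amplitude_pp_m", "theta0_rad", "measure", "value"]
        )

    def save(self, directory) -> None:
        """Write the long-format table plus a provenance sidecar."""
        import os

        os.makedirs(directory, exist_ok=True)
        self.to_frame().to_csv(os.path.join(directory, "measure_map.csv"), index=False)
        sidecar = {
            "fixed_frequency": self.fixed_frequency,
            "fixed_omega0": self.fixed_omega0,
            "amplitude_grid": list(map(float, self.amplitude_grid)),
            "theta0_grid": list(map(float, self.theta0_grid)),
            **{k: v for k, v in self.provenance.items() if _jsonable(v)},
        }
        with open(os.path.join(directory, "provenance.json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "MeasureMap":
        import os

        with open(os.path.join(directory, "provenance.json")) as fh:
            side = json.load(fh)
        df = pd.read_csv(os.path.join(directory, "measure_map.csv"))
        a_grid = np.asarray(side.pop("amplitude_grid"))
        t_grid = np.asarray(side.pop("theta0_grid"))
        surfaces = {}
        for name, grp in df.groupby("measure"):
            surf = np.full((len(a_grid), len(t_grid)), np.nan)
            ia = np.searchsorted(a_grid, grp["amplitude_pp_m"].to_numpy())
            it = np.searchsorted(t_grid, grp["theta0_rad"].to_numpy())
            surf[ia, it] = grp["value"].to_numpy()
            surfaces[name] = surf
        return cls(
            amplitude_grid=a_grid,
            theta0_grid=t_grid,
            fixed_frequency=side.pop("fixed_frequency"),
            fixed_omega0=side.pop("fixed_omega0"),
            surfaces=surfaces,
            provenance=side,
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def default_grid(n_amplitude: int = 37, n_theta: int = 33):
    """The default map grid: 8-44 cm by -pi/2..pi/2 rad."""
    return (
        np.linspace(0.08, 0.44, n_amplitude),
        np.linspace(-math.pi / 2, math.pi / 2, n_theta),
    )


def evaluate_result_space(
    amplitude_grid=None,
    theta0_grid=None,
    params: ModelParams = ModelParams(),
    measures=("mi", "gle", "msf", "jerk_ball_norm", "predictability_index"),
    fixed_frequency: float = 1.0,
    fixed_omega0: float = 0.0,
    duration: float = 45.0,
    rate: float = 120.0,
    gle_duration: float = 240.0,
    sensitivity_duration: float = 45.0,
) -> MeasureMap:
    """Simulate every grid cell and assemble the measure surfaces.

    Per-cell failures are logged and leave NaN cells rather than aborting.
    The Predictability Index surface is ``1 - v/max(v)`` with ``v`` the
    strobed-force variance relative to the continuous-force variance of the
    same strategy (the scale-free scatter summary; see docs).  Sensitivity,
    if requested, re-simulates six perturbed strategies per cell and is by
    far the most expensive surface.

    The Lyapunov surface uses a longer default horizon (240 s) than the
    single-strategy default because the map's interesting feature — where
    the smallest exponents lie — is otherwise hidden under the finite-time
    transient bias of order ln(omega)/T.
    """
    if amplitude_grid is None or theta0_grid is None:
        a_def, t_def = default_grid()
        amplitude_grid = a_def if amplitude_grid is None else amplitude_grid
        theta0_grid = t_def if theta0_grid is None else theta0_grid
    amplitude_grid = np.asarray(amplitude_grid, dtype=float)
    theta0_grid = np.asarray(theta0_grid, dtype=float)
    want_gle = "gle" in measures
    want_sens = "sensitivity" in measures
    base = [m for m in measures if m not in ("predictability_index", "sensitivity")]
    shape = (len(amplitude_grid), len(theta0_grid))
    surfs = {m: np.full(shape, np.nan) for m in measures}
    # always collect the scatter summaries needed for the PI surface
    if "predictability_index" in measures:
        surfs.setdefault("strobe_force_variance", np.full(shape, np.nan))
        surfs.setdefault("strobe_force_variance_rel", np.full(shape, np.nan))
    failed = []
    mi_needed_for_sens = np.full(shape, np.nan)
    for i, a in enumerate(amplitude_grid):
        for k, th in enumerate(theta0_grid):
            strat = Strategy(float(a), fixed_frequency, float(th), fixed_omega0)
            try:
                ms = measure_strategy(
                    strat, params, duration, rate, include_gle=False,
                )
            except Exception as exc:
                log.warning("cell (A=%.3f, theta0=%.3f) failed: %s", a, th, exc)
                failed.append({"i": i, "k": k, "reason": str(exc)})
                continue
            for m in surfs:
                if m in ("predictability_index", "sensitivity", "gle"):
                    continue
                surfs[m][i, k] = getattr(ms, m)
            mi_needed_for_sens[i, k] = ms.mi
    if want_gle:
        cells = [
            (i, k)
            for i in range(len(amplitude_grid))
            for k in range(len(theta0_grid))
            if not any(f["i"] == i and f["k"] == k for f in failed)
        ]
        lams = global_lyapunov_batch(
            [
                Strategy(float(amplitude_grid[i]), fixed_frequency,
                         float(theta0_grid[k]), fixed_omega0)
                for i, k in cells
            ],
            params,
            duration=gle_duration,
        )
        for (i, k), lam in zip(cells, lams):
            surfs["gle"][i, k] = lam
    if "predictability_index" in measures:
        rel = surfs["strobe_force_variance_rel"]
        vmax = np.nanmax(rel)
        surfs["predictability_index"] = np.vectorize(
            lambda v: np.nan if np.isnan(v) else predictability_index(v, vmax)
        )(rel)
    if want_sens:
        mi_range = float(np.nanmax(mi_needed_for_sens) - np.nanmin(mi_needed_for_sens))
        for i, a in enumerate(amplitude_grid):
            for k, th in enumerate(theta0_grid):
                if np.isnan(mi_needed_for_sens[i, k]):
                    continue
                strat = Strategy(float(a), fixed_frequency, float(th), fixed_omega0)
                try:
                    surfs["sensitivity"][i, k] = mi_sensitivity(
                        strat, params, mi_range,
                        duration=sensitivity_duration, rate=rate,
                        base_mi=mi_needed_for_sens[i, k],
                    )
                except Exception as exc:
                    log.warning("sensitivity (A=%.3f, th=%.3f): %s", a, th, exc)
                    failed.append({"i": i, "k": k, "reason": f"sensitivity: {exc}"})
    return MeasureMap(
        amplitude_grid=amplitude_grid,
        theta0_grid=theta0_grid,
        fixed_frequency=fixed_frequency,
        fixed_omega0=fixed_omega0,
        surfaces=surfs,
        provenance={
            "duration_s": duration,
            "rate_hz": rate,
            "gle_duration_s": gle_duration if want_gle else None,
            "solver": "RK45 rtol=atol=1e-8",
            "failed_cells": failed,
        },
    )


def locate_optima(mmap: MeasureMap, criterion: str):
    """Grid arg-optimum of one criterion: (Strategy, value).

    Ties are broken toward larger amplitude, then larger theta0.
    """
    if criterion not in CRITERIA:
        raise KeyError(f"criterion must be one of {sorted(CRITERIA)}")
    name, argopt = CRITERIA[criterion]
    surf = mmap.surfaces[name]
    if np.all(np.isnan(surf)):
        raise ValueError(f"surface {name} is all-NaN")
    best = surf.flat[argopt(surf)]
    ii, kk = np.nonzero(surf == best)
    # tie-break: larger amplitude, then larger theta0
    order = np.lexsort((mmap.theta0_grid[kk], mmap.amplitude_grid[ii]))
    i, k = ii[order[-1]], kk[order[-1]]
    return mmap.strategy_at(i, k), float(surf[i, k])
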
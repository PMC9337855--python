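"""Plant time-series container, artifact cleaning, and self-start estimates.

A :class:`PlantSeries` holds one plant's rosette-area trajectory together
with its design labels.  Times are stored on the model clock (days since the
start of the temperature treatment); input files record days after
stratification, which the readers shift by the 14-day pre-treatment period.

Imaging artifacts (segmentation dropouts) show up as records with a smaller
area than an earlier time point.  Such negative-growth records are discarded
by a running-maximum filter before any model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .curves import exponential_size, powerlaw_size

#: days between stratification and the start of the temperature treatment
TREATMENT_START_DAS = 14.0

#: minimum surviving observations for a plant to be usable in model fits
MIN_USABLE_POINTS = 4


@dataclass(frozen=True)
class PlantSeries:
    """One plant's cleaned (or raw) rosette-area time series.

    times are days since treatment start, strictly increasing; areas are
    positive rosette areas (mm^2-scale units); temperature is the treatment
    label, e.g. "16C" or "6C".
    """

    plant_id: str
    accession: str
    experiment: str
    temperature: str
    times: np.ndarray
    areas: np.ndarray
    usable: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if t.size == 0:
            raise ValueError(f"plant {self.plant_id}: empty series")
        if t.size != a.size:
            raise ValueError(f"plant {self.plant_id}: times/areas length mismatch")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"plant {self.plant_id}: times must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError(f"plant {self.plant_id}: nonpositive areas")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "areas", a)

    def __len__(self) -> int:
        return self.times.size


def clean_series(raw: PlantSeries) -> PlantSeries:
    """Drop negative-growth records with a running-maximum filter.

    An observation is kept iff its area is >= the maximum over all previously
    kept areas (ties kept).  Plants left with fewer than 4 points are flagged
    unusable rather than dropped.  Idempotent.
    """
    areas = raw.areas
    keep = np.empty(len(raw), dtype=bool)
    running = -np.inf
    for i, a in enumerate(areas):
        keep[i] = a >= running
        if keep[i]:
            running = a
    n_kept = int(keep.sum())
    return replace(
        raw,
        times=raw.times[keep],
        areas=areas[keep],
        usable=n_kept >= MIN_USABLE_POINTS,
    )


#: beta grid profiled by the power-law self-start
_BETA_GRID = np.concatenate([np.arange(0.05, 0.99, 0.01), [0.99]])


def selfstart(series: PlantSeries, model_kind: str) -> tuple[float, float, float]:
    """Starting values (log M0, r, beta) from linearized least squares.

    exponential: OLS of log(area) on t.  power-law: profile over a beta grid;
    for each beta the model area**(1-beta) = M0**(1-beta) + r*(1-beta)*t is
    linear in t, fitted by OLS, scored by SSE on the original scale.
    Constant series degenerate to r = 0 with a warning.
    """
    t, y = series.times, series.areas
    if np.ptp(y) == 0:
        warnings.warn(
            f"plant {series.plant_id}: constant series, returning r=0",
            stacklevel=2,
        )
        return float(np.log(y.mean())), 0.0, 1.0 if model_kind == "exponential" else 0.9

    if model_kind == "exponential":
        slope, intercept = np.polyfit(t, np.log(y), 1)
        return float(intercept), float(slope), 1.0
    if model_kind != "powerlaw":
        raise ValueError(f"unknown model_kind {model_kind!r}")

    X = np.stack([np.ones_like(t), t], axis=1)
    best = None
    for beta in _BETA_GRID:
        a = 1.0 - beta
        z = y**a
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        c0, c1 = coef
        if c0 <= 0:
            continue
        M0 = c0 ** (1.0 / a)
        r = c1 / a
        base = c0 + c1 * t
        if np.any(base <= 0):
            continue
        sse = float(np.sum((base ** (1.0 / a) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, np.log(M0), r, beta)
    if best is None:
        # fall back to near-exponential start
        slope, intercept = np.polyfit(t, np.log(y), 1)
        return float(intercept), float(slope), 0.95
    return best[1], best[2], best[3]


def predicted_series(series: PlantSeries, logM0: float, r: float, beta: float):
    """Model curve evaluated on the series' own time grid."""
    if beta >= 1.0:
        return exponential_size(series.times, np.exp(logM0), r)
    return powerlaw_size(series.times, np.exp(logM0), r, beta)
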
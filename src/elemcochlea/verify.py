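"""Built-in verification measurements.

The discretisation-convergence study doubles the number of elements of the
human preset and measures the largest change in coupled BM response
magnitude over a logarithmic frequency grid at observation positions
spanning the BM.  Because every element centre of the coarse grid is also an
element centre of the doubled grid (x_n = nΔ and Δ halves), the comparison
is made at exactly coincident positions with no interpolation.

Responses more than ``floor_db`` below the peak response over the whole grid
are excluded: beyond the characteristic place the passive response decays
below the double-precision floor (dB → −∞), so a dynamic-range floor is a
numerical necessity; the default 120 dB is far beyond any plotted range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CochleaParams
from .solver import CochlearModel, default_frequency_grid

__all__ = ["ConvergenceResult", "convergence_study"]


@dataclass(frozen=True)
class ConvergenceResult:
    max_change_db: float
    n_coarse: int
    n_fine: int
    n_points_compared: int
    frequencies: np.ndarray
    worst_frequency_hz: float
    worst_position_m: float


def _response_db(model: CochlearModel, frequencies: np.ndarray,
                 element_ids: np.ndarray) -> np.ndarray:
    """20·log10 |v/v_st| at the given 1-based element ids."""
    out = np.empty((frequencies.size, element_ids.size))
    for i, f in enumerate(frequencies):
        v = model.solve(2.0 * np.pi * f).velocity
        with np.errstate(divide="ignore"):
            out[i] = 20.0 * np.log10(np.abs(v[element_ids - 1]))
    return out


def convergence_study(
    n_coarse: int = 512,
    f_min: float = 100.0,
    f_max: float = 20e3,
    points_per_decade: int = 100,
    floor_db: float = 120.0,
    params: CochleaParams | None = None,
) -> ConvergenceResult:
    """Largest |ΔdB| of the coupled response when N is doubled.

    Human preset (uniform scalae, 1D fluid coupling, locally-reacting BM)
    unless ``params`` overrides it.
    """
    if params is None:
        params = CochleaParams(n_elements=n_coarse)
    else:
        params = params.with_n_elements(n_coarse)
    n_fine = 2 * n_coarse
    freqs = default_frequency_grid(f_min, f_max, points_per_decade)
    coarse = CochlearModel.from_params(params)
    fine = CochlearModel.from_params(params.with_n_elements(n_fine))
    ids = np.arange(2, n_coarse)           # mechanical elements of the coarse grid
    db_c = _response_db(coarse, freqs, ids)
    db_f = _response_db(fine, freqs, 2 * ids)  # same physical positions x = nΔ
    peak = max(db_c.max(), db_f.max())
    mask = (db_c > peak - floor_db) & (db_f > peak - floor_db)
    diff = np.where(mask, np.abs(db_c - db_f), 0.0)
    i, j = np.unravel_index(np.argmax(diff), diff.shape)
    return ConvergenceResult(
        max_change_db=float(diff[i, j]),
        n_coarse=n_coarse,
        n_fine=n_fine,
        n_points_compared=int(mask.sum()),
        frequencies=freqs,
        worst_frequency_hz=float(freqs[i]),
        worst_position_m=float(coarse.params.x[ids[j] - 1]),
    )
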
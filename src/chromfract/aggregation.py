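"""Per-case aggregation of nucleus-level results.

A case (patient smear) is summarized by the arithmetic means of the
nucleus-level features, together with the cumulative-mean trace of the
fractal dimension in acquisition order.  The trace supports a sampling
sufficiency diagnostic: the per-case mean FD stabilizes after a few dozen
nuclei, which motivates acquiring at least 40 cells per smear; cases below
that count are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fractal import FractalResult
from .morphometry import MorphometryResult

__all__ = ["CaseSummary", "MIN_CELLS", "summarize_case", "stabilization_index"]

#: recommended minimum number of nuclei per case
MIN_CELLS = 40


@dataclass(frozen=True)
class CaseSummary:
    case_id: str
    n_cells: int
    mean_fd: float
    mean_r2: float
    mean_area_um2: float
    mean_form_factor: float
    cum_mean_fd: np.ndarray
    low_count: bool  # True when n_cells < MIN_CELLS


def summarize_case(
    case_id: str,
    results: Sequence[tuple[FractalResult, MorphometryResult]],
) -> CaseSummary:
    """Aggregate nucleus-level results for one case, in acquisition order."""
    if len(results) == 0:
        raise ValueError(f"case {case_id!r}: no nuclei to summarize")
    fds = np.array([fr.fd for fr, _ in results], dtype=float)
    r2s = np.array([fr.r_squared for fr, _ in results], dtype=float)
    areas = np.array([mr.area_um2 for _, mr in results], dtype=float)
    ffs = np.array([mr.form_factor for _, mr in results], dtype=float)
    cum = np.cumsum(fds) / np.arange(1, len(fds) + 1)
    low = len(results) < MIN_CELLS
    if low:
        warnings.warn(
            f"case {case_id!r}: only {len(results)} nuclei "
            f"(recommended minimum {MIN_CELLS})",
            stacklevel=2,
        )
    return CaseSummary(
        case_id=str(case_id),
        n_cells=len(results),
        mean_fd=float(fds.mean()),
        mean_r2=float(r2s.mean()),
        mean_area_um2=float(areas.mean()),
        mean_form_factor=float(ffs.mean()),
        cum_mean_fd=cum,
        low_count=low,
    )


def stabilization_index(
    cum_mean: Sequence[float], tol: float = 0.005, window: int = 5
) -> Optional[int]:
    """Smallest 1-based k whose next ``window`` cumulative means all lie
    within ``tol`` of the final value; None if the trace never stabilizes.

    Mirrors the visual criterion that per-case mean-FD traces settle after
    a few dozen nuclei; ``tol``/``window`` are explicit knobs because the
    original criterion was a judgment by eye.
    """
    cum = np.asarray(cum_mean, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > cum.size:
        raise ValueError(f"window {window} exceeds trace length {cum.size}")
    close = np.abs(cum - cum[-1]) <= tol
    for k in range(0, cum.size - window + 1):
        if close[k : k + window].all():
            return k + 1
    return None
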
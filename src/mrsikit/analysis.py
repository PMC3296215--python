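"""Slice-crosstalk statistics and sequence-timing arithmetic.

The crosstalk statistic compares metabolite amplitudes fitted from two
acquisitions of the same central slice, one with and one without spacing
between slices::

    d_m = (A_m,with_spacing - A_m,without_spacing) / A_m,with_spacing

Positive mean d indicates signal lost to crosstalk when the gaps are
removed.  The timing calculator implements the multisection budget
TR = T_sec x N_sec with T_acq = N/SW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "CrosstalkStat",
    "SequenceTiming",
    "relative_difference",
    "crosstalk_report",
    "compute_timing",
    "scan_duration",
]

log = logging.getLogger(__name__)


def relative_difference(a_with: float, a_without: float) -> float:
    """Relative amplitude difference (A_w - A_wo) / A_w."""
    if not (a_with > 0):
        raise InvalidParameterError(
            f"with-spacing amplitude must be > 0, got {a_with}"
        )
    return (a_with - a_without) / a_with


@dataclass
class CrosstalkStat:
    """Per-metabolite summary of the crosstalk statistic d."""

    metabolite: str
    d_values: np.ndarray
    mean: float
    sd: float
    n_voxels: int

    @property
    def standard_error(self) -> float:
        return self.sd / np.sqrt(self.n_voxels) if self.n_voxels > 0 else np.nan


def crosstalk_report(
    fits_with: pd.DataFrame,
    fits_without: pd.DataFrame,
    roi: list[tuple[int, int]] | None = None,
    metabolites: list[str] | None = None,
) -> dict[str, CrosstalkStat]:
    """Mean +/- SD of d per metabolite over a shared set of voxels.

    Both fit tables must carry columns (slice, y, x, metabolite, A) and
    refer to the same (central) slice geometry.  ``roi`` restricts the
    voxels as (y, x) pairs; voxels present in only one table are excluded
    with a logged count.  SDs are sample SDs (n-1).
    """
    for name, tab in (("fits_with", fits_with), ("fits_without", fits_without)):
        missing = {"y", "x", "metabolite", "A"} - set(tab.columns)
        if missing:
            raise InvalidParameterError(f"{name} lacks columns {sorted(missing)}")
    if metabolites is None:
        metabolites = sorted(set(fits_with["metabolite"]) & set(fits_without["metabolite"]))
    out: dict[str, CrosstalkStat] = {}
    for met in metabolites:
        w = fits_with[fits_with["metabolite"] == met]
        wo = fits_without[fits_without["metabolite"] == met]
        merged = w.merge(wo, on=["y", "x"], suffixes=("_w", "_wo"))
        n_dropped = len(w) + len(wo) - 2 * len(merged)
        if n_dropped:
            log.info("%s: %d voxel rows present in only one table, excluded", met, n_dropped)
        if roi is not None:
            keys = set(roi)
            merged = merged[[(y, x) in keys for y, x in zip(merged["y"], merged["x"])]]
        d = np.array(
            [relative_difference(aw, awo) for aw, awo in zip(merged["A_w"], merged["A_wo"])]
        )
        out[met] = CrosstalkStat(
            metabolite=met,
            d_values=d,
            mean=float(d.mean()) if d.size else np.nan,
            sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
            n_voxels=int(d.size),
        )
    return out


def crosstalk_table(stats: dict[str, CrosstalkStat]) -> pd.DataFrame:
    """Report rows (metabolite, mean, sd, n) in mean +/- SD layout."""
    return pd.DataFrame(
        {
            "metabolite": list(stats),
            "mean": [s.mean for s in stats.values()],
            "sd": [s.sd for s in stats.values()],
            "n": [s.n_voxels for s in stats.values()],
        }
    )


def format_crosstalk_text(stats: dict[str, CrosstalkStat]) -> str:
    """Aligned-text report, one metabolite per column (mean% +/- SD%)."""
    heads = "".join(f"{m:>18s}" for m in stats)
    cells = "".join(
        f"{100 * s.mean:>9.2f}% ± {100 * s.sd:>5.2f}%" for s in stats.values()
    )
    n = next(iter(stats.values())).n_voxels if stats else 0
    return f"(n = {n}){heads}\n        {cells}"


@dataclass(frozen=True)
class SequenceTiming:
    """Timing budget of the multisection sequence (all times in ms)."""

    t_p: float
    tau_1: float
    tau_2: float
    te: float
    t_d: float
    t_acq: float
    t_sec: float
    n_sec: int
    tr: float
    spectral_width: float | None = None
    n_points: int | None = None


def compute_timing(
    t_p: float = 0.0,
    te: float = 0.0,
    t_acq: float | None = None,
    t_d: float = 0.0,
    n_sec: int = 1,
    *,
    tau_1: float = 0.0,
    tau_2: float = 0.0,
    t_sec: float | None = None,
    spectral_width: float | None = None,
    n_points: int | None = None,
) -> SequenceTiming:
    """Assemble the per-slice time budget and the repetition time.

    ``t_acq`` may be given directly (ms) or derived as ``N/SW`` from
    ``n_points`` and ``spectral_width``.  When ``t_sec`` is not supplied
    it is assembled as ``T_p + tau_1/2 + TE + T_acq/2`` (the acquisition
    window is centered on the echo, TE after the excitation center; the
    pre-acquisition delay T_d lies inside the TE interval).  Always,
    ``TR = T_sec x N_sec``.
    """
    if n_sec < 1:
        raise InvalidParameterError("n_sec must be >= 1")
    if t_acq is None:
        if spectral_width and n_points:
            t_acq = 1000.0 * n_points / spectral_width
        else:
            t_acq = 0.0
    for name, v in (("t_p", t_p), ("te", te), ("t_acq", t_acq), ("t_d", t_d)):
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {v}")
    if t_sec is None:
        t_sec = t_p + tau_1 / 2.0 + te + t_acq / 2.0
    tr = t_sec * n_sec
    return SequenceTiming(
        t_p=t_p, tau_1=tau_1, tau_2=tau_2, te=te, t_d=t_d, t_acq=float(t_acq),
        t_sec=float(t_sec), n_sec=int(n_sec), tr=float(tr),
        spectral_width=spectral_width, n_points=n_points,
    )


def scan_duration(
    tr_ms: float, grid: tuple[int, int], sampling: str = "full"
) -> float:
    """Total phase-encoding scan time in seconds.

    ``sampling="full"`` acquires every (ky, kx) point of the grid;
    ``"circular"`` only those whose k-space radius does not exceed half
    the grid width (integer lattice including the DC point).
    """
    ny, nx = grid
    if ny < 1 or nx < 1:
        raise InvalidParameterError("grid dims must be >= 1")
    if sampling == "full":
        n_pe = ny * nx
    elif sampling == "circular":
        r = min(ny, nx) // 2
        ky = np.arange(ny) - ny // 2
        kx = np.arange(nx) - nx // 2
        n_pe = int(np.sum(ky[:, None] ** 2 + kx[None, :] ** 2 <= r * r))
    else:
        raise InvalidParameterError(f"unknown sampling scheme {sampling!r}")
    return n_pe * tr_ms / 1000.0
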
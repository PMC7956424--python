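"""Pseudo individual patient data from digitized Kaplan-Meier curves.

A published KM figure gives survival coordinates and a numbers-at-risk
table but not the underlying patient records.  The interval-wise iterative
algorithm here (the de-facto standard for this problem) allocates integer
event and censoring counts inside each inter-risk-table interval so that

* the product-limit estimate of the reconstructed records tracks the
  digitized survival at every coordinate as closely as integer counts
  allow, and
* the implied number at risk at each risk-table time matches the published
  count exactly whenever an integer allocation can achieve it.

Censoring times are spread uniformly within intervals; events sit at the
coordinate (drop) times.  Beyond the last risk-table time no censoring is
assumed, and subjects still at risk after the final coordinate are
administratively censored there, so the reconstructed cohort always has
exactly ``n0`` records.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["KMCurve", "PseudoIPD", "km_estimate", "reconstruct_ipd"]

log = logging.getLogger(__name__)


def km_estimate(
    times: Sequence[float], events: Sequence[float], grid: Sequence[float]
) -> np.ndarray:
    """Product-limit (Kaplan-Meier) estimate evaluated on ``grid``.

    The estimate is the right-continuous step function
    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times
    ``t_i`` with ``d_i`` events and ``n_i`` at risk.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    grid = np.asarray(grid, dtype=float)
    if len(times) == 0:
        raise ValueError("empty cohort")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be ascending")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    event_times = np.unique(t_sorted[e_sorted])
    # at risk just before each distinct event time; deaths at that time
    n_at_risk = len(times) - np.searchsorted(t_sorted, event_times, side="left")
    d = np.array([(t_sorted[e_sorted] == t).sum() for t in event_times])
    factors = 1.0 - d / n_at_risk
    surv_steps = np.cumprod(factors)
    idx = np.searchsorted(event_times, grid, side="right")
    out = np.ones_like(grid, dtype=float)
    nonzero = idx > 0
    out[nonzero] = surv_steps[idx[nonzero] - 1]
    return out


@dataclass(frozen=True)
class KMCurve:
    """A digitized KM curve: coordinates, risk table and initial cohort size."""

    coords: np.ndarray      # (N, 2): time months, survival
    risk_table: np.ndarray  # (J, 2): time months, number at risk
    n0: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        r = np.asarray(self.risk_table, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("coords must be an (N, 2) array")
        if np.any(np.diff(c[:, 0]) < 0):
            raise ValueError("coordinate times must be ascending")
        if c[0, 0] != 0 or abs(c[0, 1] - 1.0) > 1e-9:
            raise ValueError("first coordinate must be (0, 1.0)")
        if np.any(c[:, 1] < -1e-12) or np.any(c[:, 1] > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(r[:, 1]) > 0):
            raise ValueError("risk-table counts must be non-increasing")
        if r[0, 1] > self.n0:
            raise ValueError("risk-table counts cannot exceed n0")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)[:, 0]

    @property
    def survival(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)[:, 1]

    def to_files(self, coords_path: str | Path, risk_path: str | Path) -> None:
        buf = io.StringIO()
        buf.write("time,survival\n")
        for t, s in self.coords:
            buf.write(f"{t:.6f},{s:.6f}\n")
        Path(coords_path).write_text(buf.getvalue())
        buf = io.StringIO()
        buf.write("time,n_at_risk\n")
        for t, n in self.risk_table:
            buf.write(f"{t:.6f},{int(n)}\n")
        Path(risk_path).write_text(buf.getvalue())

    @classmethod
    def from_files(
        cls, coords_path: str | Path, risk_path: str | Path, n0: int | None = None
    ) -> "KMCurve":
        def _read(path):
            rows = Path(path).read_text().strip().splitlines()[1:]
            return np.array([[float(x) for x in line.split(",")] for line in rows])

        coords = _read(coords_path)
        risk = _read(risk_path)
        return cls(coords=coords, risk_table=risk, n0=int(n0 or risk[0, 1]))


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed patient records: one (time, event) pair per subject."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must align")

    def __len__(self) -> int:
        return len(self.times)

    def km(self, grid: Sequence[float]) -> np.ndarray:
        return km_estimate(self.times, self.events, grid)

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write("time,event\n")
        for t, e in zip(self.times, self.events):
            buf.write(f"{t:.6f},{int(e)}\n")
        Path(path).write_text(buf.getvalue())


def _allocate_interval(
    surv: np.ndarray,
    t_coords: np.ndarray,
    t_end: float,
    n_start: int,
    km_prev: float,
    n_censor: int,
):
    """Process one inter-risk-table interval with a fixed censoring count.

    Events are placed at coordinate times (as early as rounding allows);
    censorings are spread uniformly over the interval and interleaved in
    time order.  Returns the event counts per coordinate, censor times, the
    running KM value and the number remaining at risk at ``t_end``.
    """
    t_start = t_coords[0] if len(t_coords) else t_end
    if n_censor > 0:
        span_lo = t_start
        cen_times = span_lo + (np.arange(n_censor) + 0.5) / n_censor * (t_end - span_lo)
    else:
        cen_times = np.empty(0)
    d = np.zeros(len(t_coords), dtype=int)
    n = n_start
    km = km_prev
    cen_used = 0
    for i, t in enumerate(t_coords):
        if n <= 0:
            break
        if km > 0:
            d_i = int(np.floor(n * (1.0 - surv[i] / km) + 0.5))  # round half up
        else:
            d_i = 0
        d_i = max(0, min(d_i, n))
        if d_i > 0:
            km *= 1.0 - d_i / n
        d[i] = d_i
        n -= d_i
        # censor everything scheduled before the next coordinate
        t_next = t_coords[i + 1] if i + 1 < len(t_coords) else t_end
        k = int(np.searchsorted(cen_times, t_next, side="left")) - cen_used
        k = min(k, n)
        cen_used += k
        n -= k
    # any censorings not yet applied (e.g. scheduled at the very end)
    k = min(len(cen_times) - cen_used, n)
    cen_used += k
    n -= k
    return d, cen_times[:cen_used], km, n


def reconstruct_ipd(curve: KMCurve, total_events: int | None = None) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized curve and its risk table.

    Within each inter-risk-table interval the number of censorings is found
    by bisection (the implied number at risk at the interval end is monotone
    in it), with events allocated at coordinate times so the running KM
    matches the digitized survival.  If ``total_events`` is given, event
    allocations in the region beyond the last risk-table time are rescaled
    to meet it; otherwise that region is treated as censoring-free.

    Raises
    ------
    ValueError
        If the curve and risk table are inconsistent (survival rising), with
        the offending interval identified.
    """
    coords = np.asarray(curve.coords, dtype=float)
    risk = np.asarray(curve.risk_table, dtype=float)
    if len(risk) < 2:
        raise ValueError("risk table needs at least two entries")
    t_c, s_c = coords[:, 0], coords[:, 1]
    if np.any(np.diff(s_c) > 1e-9):
        bad = int(np.argmax(np.diff(s_c) > 1e-9))
        raise ValueError(
            f"survival rises between coordinates {bad} and {bad + 1} "
            f"(t={t_c[bad]:.3g} -> {t_c[bad + 1]:.3g}); repair the curve first"
        )
    s_c = np.minimum.accumulate(s_c)  # tolerate tiny float noise

    event_times: list[float] = []
    censor_times: list[float] = []
    km_run = 1.0
    n_run = int(risk[0, 1])

    for j in range(len(risk) - 1):
        t_lo, t_hi = risk[j, 0], risk[j + 1, 0]
        n_target = int(risk[j + 1, 1])
        mask = (t_c >= t_lo) & (t_c < t_hi)
        tc, sc = t_c[mask], s_c[mask]
        if n_target > n_run:
            raise ValueError(
                f"risk table rises across interval {j} ({n_run} -> {n_target})"
            )
        # the implied n at t_hi is monotone non-increasing in the censoring
        # count; find the smallest count reaching the target (ties resolved
        # toward placing events rather than censorings)
        def implied(c):
            return _allocate_interval(sc, tc, t_hi, n_run, km_run, c)

        lo, hi = 0, n_run - n_target
        while lo < hi:
            mid = (lo + hi) // 2
            if implied(mid)[3] <= n_target:
                hi = mid
            else:
                lo = mid + 1
        best = None
        for c in range(max(lo - 2, 0), min(lo + 3, n_run - n_target + 1)):
            d, cen, km_new, n_new = implied(c)
            if best is None or abs(n_new - n_target) < abs(best[4] - n_target):
                best = (c, d, cen, km_new, n_new)
        _, d, cen, km_run, n_run = best
        for t, k in zip(tc, d):
            event_times.extend([t] * int(k))
        censor_times.extend(cen.tolist())

    # region beyond the last risk-table time: no censoring assumed
    t_last_risk = risk[-1, 0]
    mask = t_c >= t_last_risk
    tc, sc = t_c[mask], s_c[mask]
    d, cen, km_run, n_run = _allocate_interval(
        sc, tc, t_c[-1] + 1e-9, n_run, km_run, 0
    )
    for t, k in zip(tc, d):
        event_times.extend([t] * int(k))

    # administrative censoring of survivors at the last coordinate time
    censor_times.extend([t_c[-1]] * n_run)

    if total_events is not None:
        # rescale the tail allocation: trade administrative censorings at the
        # final coordinate against events there until the known total matches
        deficit = int(total_events) - len(event_times)
        if deficit > 0:
            convert = min(deficit, n_run)
            censor_times = censor_times[: len(censor_times) - convert]
            event_times.extend([t_c[-1]] * convert)
        elif deficit < 0:
            at_last = sum(1 for t in event_times if t == t_c[-1])
            convert = min(-deficit, at_last)
            for _ in range(convert):
                event_times.remove(t_c[-1])
            censor_times.extend([t_c[-1]] * convert)

    # pad (should not trigger) so the record count is exactly n0
    n_total = len(event_times) + len(censor_times)
    if n_total < curve.n0:
        censor_times.extend([t_c[-1]] * (curve.n0 - n_total))
    elif n_total > curve.n0:
        censor_times = censor_times[: len(censor_times) - (n_total - curve.n0)]

    times = np.array(event_times + censor_times, dtype=float)
    events = np.array([1] * len(event_times) + [0] * len(censor_times))
    order = np.argsort(times, kind="stable")
    return PseudoIPD(times=np.maximum(times[order], 1e-9), events=events[order])
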
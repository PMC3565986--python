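"""Allelic binning: snap raw electrophoretic fragment sizes to a
repeat-unit lattice.

Capillary electrophoresis reports fragment sizes on a continuous scale,
but true alleles of a microsatellite differ by whole repeat units, so they
live on a lattice ``offset + k·period``.  The marker-specific offset
(set by the flanking sequence length plus systematic mobility shifts) is
estimated by least squares: the fitted offset minimizes

    Σ_i  min_k ( size_i − (offset + k·period) )²

The objective is piecewise quadratic in the offset — assignments of sizes
to lattice points change only where a size sits exactly half a period from
two lattice points — so the exact minimizer is found by enumerating those
breakpoints and solving each quadratic piece in closed form.  The fit is
deterministic; ties prefer the smallest offset in ``[0, period)``.

One lattice is fitted per marker (offsets are marker-specific).  Sizes
that land unusually far from their nearest lattice point are flagged
``off_ladder`` rather than silently binned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinLattice",
    "BinnedCall",
    "DEFAULT_OFF_LADDER_FRACTION",
    "fit_bin_lattice",
    "assign_bins",
]

#: A size further than this fraction of period/2 from its lattice point is
#: flagged off-ladder (and the lattice as a whole flagged ambiguous).
DEFAULT_OFF_LADDER_FRACTION = 0.35

_VALID_PERIODS = (2, 3, 4)


@dataclass(frozen=True)
class BinLattice:
    """A fitted repeat-unit lattice for one marker.

    ``bin_centers`` are the occupied lattice points (offset + k·period for
    the ks actually observed); ``residual_ss`` is the sum of squared
    deviations of the fitted sizes from their assigned centers;
    ``max_deviation`` the largest single deviation, and ``ambiguous``
    whether any fitted size exceeded the off-ladder threshold.
    """

    period: int
    offset: float
    bin_centers: tuple[float, ...]
    residual_ss: float
    max_deviation: float
    ambiguous: bool


@dataclass(frozen=True)
class BinnedCall:
    """One raw size snapped to the lattice."""

    raw_size: float
    bin_center: float
    binned_size: int
    off_ladder: bool


def _lattice_ss(residues: np.ndarray, offset: float, period: int) -> tuple[float, np.ndarray]:
    """Sum of squared wrapped deviations of residues from ``offset``."""
    d = (residues - offset + period / 2.0) % period - period / 2.0
    return float(np.sum(d * d)), d


def fit_bin_lattice(sizes: Iterable[float], period: int) -> BinLattice:
    """Least-squares lattice fit for one marker's raw fragment sizes.

    Exact minimization of Σ_i min_k (size_i − (offset + k·period))² over
    the circular offset domain [0, period): the objective is piecewise
    quadratic with breakpoints half a period opposite each residue, and
    each piece is solved in closed form (mean of the locally adjusted
    residues, clamped to the piece).  Ties break toward the smallest
    offset.

    Sizes must lie in (50, 600) bp — the sizing range of the capillary
    standard — and the period must be 2, 3 or 4.
    """
    sizes_arr = np.asarray(sorted(float(s) for s in sizes), dtype=float)
    if sizes_arr.size == 0:
        raise ValueError("fit_bin_lattice requires at least one size")
    if period not in _VALID_PERIODS:
        raise ValueError(f"period must be one of {_VALID_PERIODS}, got {period}")
    if np.any(sizes_arr <= 50) or np.any(sizes_arr >= 600):
        raise ValueError("fragment sizes must lie within (50, 600) bp")

    residues = sizes_arr % period
    breakpoints = np.unique((residues + period / 2.0) % period)
    best_ss = np.inf
    best_offset = 0.0
    m = breakpoints.size
    for j in range(m):
        lo = breakpoints[j]
        hi = breakpoints[(j + 1) % m] if m > 1 else lo + period
        if hi <= lo:
            hi += period
        mid = (lo + hi) / 2.0
        # assignment is fixed within (lo, hi): adjust residues near mid
        k = np.round((residues - mid) / period)
        adjusted = residues - k * period
        opt = float(np.clip(np.mean(adjusted), lo, hi))
        ss = float(np.sum((adjusted - opt) ** 2))
        offset = opt % period
        if ss < best_ss - 1e-12 or (abs(ss - best_ss) <= 1e-12 and offset < best_offset):
            best_ss = ss
            best_offset = offset

    k = np.round((sizes_arr - best_offset) / period)
    centers = best_offset + k * period
    deviations = np.abs(sizes_arr - centers)
    threshold = DEFAULT_OFF_LADDER_FRACTION * period / 2.0
    return BinLattice(
        period=period,
        offset=best_offset,
        bin_centers=tuple(float(c) for c in np.unique(centers)),
        residual_ss=float(np.sum((sizes_arr - centers) ** 2)),
        max_deviation=float(deviations.max()),
        ambiguous=bool(np.any(deviations > threshold)),
    )


def assign_bins(
    sizes: Iterable[float],
    lattice: BinLattice,
    off_ladder_fraction: float = DEFAULT_OFF_LADDER_FRACTION,
) -> list[BinnedCall]:
    """Snap sizes to the fitted lattice.

    Each size maps to its nearest lattice point ``offset + k·period`` and
    is reported as the nearest integer to that point; a size further than
    ``off_ladder_fraction × period/2`` from its point is flagged
    ``off_ladder``.  Binning is translation-equivariant: shifting every
    size by a whole number of periods shifts the bins identically.
    """
    out: list[BinnedCall] = []
    p = lattice.period
    threshold = off_ladder_fraction * p / 2.0
    for s in sizes:
        s = float(s)
        k = round((s - lattice.offset) / p)
        center = lattice.offset + k * p
        out.append(
            BinnedCall(
                raw_size=s,
                bin_center=center,
                binned_size=int(np.floor(center + 0.5)),
                off_ladder=bool(abs(s - center) > threshold + 1e-12),
            )
        )
    return out


def bin_raw_sizes(
    raw, periods: dict[str, int], off_ladder_fraction: float = DEFAULT_OFF_LADDER_FRACTION
):
    """Bin a raw-sizes table (sample, marker, size1, size2) marker by marker.

    ``periods`` maps marker name → motif period.  Returns a copy of the
    frame with integer ``allele1``/``allele2`` columns and an
    ``off_ladder`` flag column; missing calls pass through as missing.
    One lattice is fitted per marker from all its non-missing sizes.
    """
    import pandas as pd

    df = raw.copy()
    df["allele1"] = pd.array([None] * len(df), dtype="Int64")
    df["allele2"] = pd.array([None] * len(df), dtype="Int64")
    df["off_ladder"] = False
    for marker, group in df.groupby("marker", sort=False):
        if marker not in periods:
            raise KeyError(f"no period configured for marker {marker!r}")
        mask = group["size1"].notna()
        pool = pd.concat([group.loc[mask, "size1"], group.loc[mask, "size2"]])
        if pool.empty:
            continue
        lattice = fit_bin_lattice(pool.tolist(), periods[marker])
        for idx in group.index[mask]:
            calls = assign_bins(
                [df.at[idx, "size1"], df.at[idx, "size2"]], lattice, off_ladder_fraction
            )
            df.at[idx, "allele1"] = calls[0].binned_size
            df.at[idx, "allele2"] = calls[1].binned_size
            df.at[idx, "off_ladder"] = calls[0].off_ladder or calls[1].off_ladder
    return df
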
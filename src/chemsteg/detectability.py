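"""Steganalysis-style exposure metrics for encoded surfaces.

These are the computations an analyst without the key could run against
a surface: the sorted mean-peak intensity curve, the census of masses
seen at exactly one location, the shared-compound fraction of an extract
library, and integrated signal profiles along a line of cells.  The
package's concealment claim is operationalized by comparing the curve
statistics of an encoded grid against an untreated one with a
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .chemchannel import MATCH_TOL, ExtractLibrary, SpectrumGrid, mean_spectrum

__all__ = [
    "sorted_peak_curve",
    "unique_mass_count",
    "unique_mass_curve",
    "shared_fraction",
    "signal_profile",
    "curve_distinguishability",
]


def sorted_peak_curve(
    grid: SpectrumGrid, tol: float = MATCH_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-spectrum peak intensities sorted descending.

    Returns ``(rank, mean_intensity)`` with rank starting at 1; the curve
    is non-increasing by construction.
    """
    _, mean_int, _ = mean_spectrum(grid, tol)
    vals = np.sort(mean_int)[::-1]
    return np.arange(1, vals.size + 1), vals


def _singleton_intensities(grid: SpectrumGrid, tol: float) -> np.ndarray:
    """Intensities of masses observed at exactly one grid location."""
    centers, _, _ = mean_spectrum(grid, tol)
    count = np.zeros(centers.size, dtype=np.int64)
    best = np.zeros(centers.size)
    for mz, inten in zip(grid.mz, grid.intensity):
        if mz.size == 0:
            continue
        idx = np.searchsorted(centers, mz)
        left = np.clip(idx - 1, 0, centers.size - 1)
        right = np.clip(idx, 0, centers.size - 1)
        use_left = np.abs(mz - centers[left]) <= np.abs(mz - centers[right])
        nearest = np.where(use_left, left, right)
        hit = np.zeros(centers.size, dtype=bool)
        hit[nearest] = True
        count += hit
        np.maximum.at(best, nearest, inten)
    return best[count == 1]


def unique_mass_count(
    grid: SpectrumGrid, cutoff: float, tol: float = MATCH_TOL
) -> int:
    """Masses seen at exactly one location with intensity above ``cutoff``.

    The census is over masses globally unique to a single grid location;
    the cutoff thresholds the intensity of that single occurrence, so the
    count is non-increasing in the cutoff.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    vals = _singleton_intensities(grid, tol)
    return int(np.sum(vals > cutoff))


def unique_mass_curve(
    grid: SpectrumGrid, cutoffs, tol: float = MATCH_TOL
) -> np.ndarray:
    """:func:`unique_mass_count` evaluated over a ladder of cutoffs."""
    cutoffs = np.asarray(cutoffs, dtype=np.float64)
    if np.any(cutoffs < 0):
        raise ValueError("cutoffs must be non-negative")
    vals = _singleton_intensities(grid, tol)
    return np.array([int(np.sum(vals > c)) for c in cutoffs])


def shared_fraction(library: ExtractLibrary) -> dict:
    """Fraction of compounds shared across extracts.

    Per extract: ``1 - unique/(shared + unique)``; ``pooled`` weighs all
    extracts together.  Requires at least two extracts for the notion of
    "unique to one extract" to be meaningful.
    """
    if library.n_extracts < 2:
        raise ValueError("shared fraction needs at least 2 extracts")
    per = {}
    tot_unique = 0
    tot_all = 0
    for sig in library.signatures:
        n_unique = sig.unique_mz.size
        n_all = sig.shared_mz.size + n_unique
        per[sig.extract_id] = 1.0 - n_unique / n_all
        tot_unique += n_unique
        tot_all += n_all
    per["pooled"] = 1.0 - tot_unique / tot_all
    return per


def signal_profile(
    grid: SpectrumGrid,
    identifying_masses,
    row: int,
    tol: float = MATCH_TOL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total vs identifying integrated signal along one grid row.

    Returns ``(cols, total_signal, identifying_signal)`` for every cell of
    grid row ``row``.  The identifying subset is summed over peaks within
    ``tol`` of the supplied masses.
    """
    masses = np.sort(np.asarray(identifying_masses, dtype=np.float64))
    if masses.size == 0:
        raise ValueError("identifying mass set is empty")
    if not 0 <= row < grid.geometry.rows:
        raise ValueError(f"row {row} outside grid")
    sel = np.where(grid.cells[:, 0] == row)[0]
    order = np.argsort(grid.cells[sel, 1])
    sel = sel[order]
    total = np.zeros(sel.size)
    ident = np.zeros(sel.size)
    for i, j in enumerate(sel):
        mz, inten = grid.mz[j], grid.intensity[j]
        total[i] = inten.sum()
        if mz.size == 0:
            continue
        pos = np.searchsorted(masses, mz)
        left = np.clip(pos - 1, 0, masses.size - 1)
        right = np.clip(pos, 0, masses.size - 1)
        near = np.minimum(np.abs(mz - masses[left]), np.abs(mz - masses[right]))
        ident[i] = inten[near <= tol].sum()
    return grid.cells[sel, 1], total, ident


def curve_distinguishability(
    grid_a: SpectrumGrid, grid_b: SpectrumGrid, tol: float = MATCH_TOL
) -> dict:
    """KS comparison of two grids' exposure curves.

    Two-sample Kolmogorov-Smirnov tests on (a) the log mean-peak
    intensity distributions and (b) the per-location total-signal
    distributions.  Large p-values mean an analyst comparing the two
    curves cannot tell the surfaces apart.
    """
    _, ia = sorted_peak_curve(grid_a, tol)
    _, ib = sorted_peak_curve(grid_b, tol)
    ks_peaks = stats.ks_2samp(np.log10(ia[ia > 0]), np.log10(ib[ib > 0]))
    tot_a = np.array([x.sum() for x in grid_a.intensity])
    tot_b = np.array([x.sum() for x in grid_b.intensity])
    ks_total = stats.ks_2samp(np.log10(tot_a), np.log10(tot_b))
    cutoffs = np.logspace(2, 7, 11)
    ua = unique_mass_curve(grid_a, cutoffs, tol)
    ub = unique_mass_curve(grid_b, cutoffs, tol)
    ks_unique = stats.ks_2samp(ua, ub)
    return {
        "peak_curve_stat": float(ks_peaks.statistic),
        "peak_curve_p": float(ks_peaks.pvalue),
        "total_signal_stat": float(ks_total.statistic),
        "total_signal_p": float(ks_total.pvalue),
        "unique_curve_stat": float(ks_unique.statistic),
        "unique_curve_p": float(ks_unique.pvalue),
    }
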
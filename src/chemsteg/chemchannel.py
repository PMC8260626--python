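"""Synthetic write/read channel: banknote-like substrate, extract library,
droplet deposition and noisy FT-ICR-style acquisition.

The substrate model emulates the chemical fingerprint of a worn banknote
surface measured by laser-desorption FT-ICR imaging: a handful of very
intense dye peaks (the strongest being the phthalocyanine lock mass at
m/z 575.0788), a log-linear tail of more than a thousand trace compounds,
and a sprinkling of trace masses seen at exactly one surface location.
Extracts are solvent pulls of that same chemistry: their compound profile
is proportional to the substrate's (so redepositing them perturbs the
cover only along directions it already occupies), plus a few low-abundance
masses unique to each extraction region, which are what the readout model
latches onto.

Spectra are centroided peak lists; instrument resolution enters as a small
per-peak m/z jitter and a per-location calibration shift that the lock
mass removes.  All generators are deterministic in their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .framing import DEFAULT_DISPENSE_NL
from .geometry import GridGeometry

__all__ = [
    "SubstrateModel",
    "ExtractModel",
    "ExtractSignature",
    "ExtractLibrary",
    "SpectrumGrid",
    "level_multipliers",
    "simulate_substrate",
    "simulate_extracts",
    "deposit",
    "acquire",
    "pooled_masses",
    "mean_spectrum",
]

LOCK_MASS = 575.0788
MATCH_TOL = 0.005  # Da; nearest peak wins, ties to lower m/z


@dataclass(frozen=True)
class SubstrateModel:
    """Statistical description of the untreated cover surface.

    Intensities are arbitrary instrument units.  Dye peaks decay
    log-linearly from ``dye_intensity_scale`` over ``dye_decades``; trace
    compounds continue the tail from ``trace_intensity_scale`` over
    ``trace_decades`` (about four decades, matching the sorted mean-peak
    curve of a real bill).  ``unique_mass_fraction`` of the catalog is
    seen at exactly one surface location.  The compound catalog itself is
    a fixed property of the object (seeded by ``catalog_seed``); the
    per-location realization varies with the simulation seed.
    """

    mz_min: float = 150.0
    mz_max: float = 900.0
    lock_mass: float = LOCK_MASS
    n_dye_peaks: int = 50
    n_trace_compounds: int = 4000
    dye_intensity_scale: float = 1e9
    dye_decades: float = 2.0
    trace_intensity_scale: float = 1e7
    trace_decades: float = 4.0
    unique_mass_fraction: float = 0.0013
    log_intensity_sigma: float = 0.25  # natural-log spatial variation
    dye_absent_factor: float = 0.3  # dye attenuation in the dye-free class
    class_block: int = 4  # side of the two-class checker blocks
    catalog_seed: int = 20500

    def __post_init__(self) -> None:
        if self.mz_max <= self.mz_min:
            raise ValueError("empty m/z range")
        if not self.mz_min < self.lock_mass < self.mz_max:
            raise ValueError("lock mass outside m/z range")
        if self.n_dye_peaks < 1 or self.n_trace_compounds < 1:
            raise ValueError("catalog sizes must be positive")


def substrate_catalog(model: SubstrateModel) -> dict:
    """Fixed compound catalog of the cover object.

    Returns arrays ``mz`` (sorted), ``base_intensity`` and ``is_dye``.
    The strongest entry is the lock mass; sorted base intensities decay
    monotonically (dyes first, then the trace tail).
    """
    rng = np.random.default_rng(model.catalog_seed)
    n_dye, n_tr = model.n_dye_peaks, model.n_trace_compounds
    masses = rng.uniform(model.mz_min, model.mz_max, n_dye + n_tr)
    masses[0] = model.lock_mass
    dye_int = model.dye_intensity_scale * np.logspace(
        0, -model.dye_decades, n_dye
    )
    trace_int = model.trace_intensity_scale * np.logspace(
        0, -model.trace_decades, n_tr
    ) * rng.uniform(0.5, 1.0, n_tr)
    base = np.concatenate([dye_int, np.sort(trace_int)[::-1]])
    is_dye = np.zeros(n_dye + n_tr, dtype=bool)
    is_dye[:n_dye] = True
    # sporadic compounds: trace masses confined to a single surface spot
    # (which spot is a property of the realization, not the catalog)
    n_cat = n_dye + n_tr
    p_sporadic = model.unique_mass_fraction * n_cat / n_tr
    is_sporadic = np.zeros(n_cat, dtype=bool)
    is_sporadic[n_dye:] = rng.random(n_tr) < p_sporadic
    order = np.argsort(masses)
    return {
        "mz": masses[order],
        "base_intensity": base[order],
        "is_dye": is_dye[order],
        "is_sporadic": is_sporadic[order],
    }


@dataclass
class SpectrumGrid:
    """Per-location centroided spectra plus grid metadata."""

    geometry: GridGeometry
    cells: np.ndarray  # (n_loc, 2) int (row, col)
    mz: list  # per location: float64 array, strictly increasing
    intensity: list  # per location: float64 array, >= 0
    lock_mass: float = LOCK_MASS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if len(self.mz) != len(self.intensity) or len(self.mz) != len(self.cells):
            raise ValueError("per-location arrays disagree in length")

    @property
    def n_locations(self) -> int:
        return len(self.mz)

    def cell_index(self, row: int, col: int) -> int:
        hit = np.where((self.cells[:, 0] == row) & (self.cells[:, 1] == col))[0]
        if hit.size == 0:
            raise KeyError(f"no spectrum at grid cell ({row}, {col})")
        return int(hit[0])

    def copy(self) -> "SpectrumGrid":
        return SpectrumGrid(
            geometry=self.geometry,
            cells=self.cells.copy(),
            mz=[m.copy() for m in self.mz],
            intensity=[i.copy() for i in self.intensity],
            lock_mass=self.lock_mass,
            meta=dict(self.meta),
        )


def _class_map(geometry: GridGeometry, block: int) -> np.ndarray:
    rr, cc = np.meshgrid(
        np.arange(geometry.rows), np.arange(geometry.cols), indexing="ij"
    )
    return ((rr // block + cc // block) % 2).astype(np.int8)


def simulate_substrate(
    seed: int, geometry: GridGeometry, model: SubstrateModel | None = None
) -> SpectrumGrid:
    """Generate the untreated cover grid.

    Each location carries the shared catalog scaled by a two-class dye
    pattern and lognormal spatial jitter, plus any location-unique trace
    masses assigned to it.  Masses are the true compound masses;
    calibration shift and peak jitter are measurement effects and enter
    at acquisition time.
    """
    model = model or SubstrateModel()
    if geometry.n_cells < 1:
        raise ValueError("empty geometry")
    cat = substrate_catalog(model)
    rng = np.random.default_rng(seed)
    n_loc = geometry.n_cells
    cells = np.stack(
        [np.repeat(np.arange(geometry.rows), geometry.cols),
         np.tile(np.arange(geometry.cols), geometry.rows)],
        axis=1,
    )
    classes = _class_map(geometry, model.class_block)[cells[:, 0], cells[:, 1]]

    # each sporadic catalog mass lives at one realization-specific location
    n_cat = cat["mz"].size
    unique_mask = cat["is_sporadic"]
    unique_home = np.full(n_cat, -1, dtype=np.int64)
    unique_home[unique_mask] = rng.integers(0, n_loc, unique_mask.sum())

    shared_mask = ~unique_mask
    mz_list, int_list = [], []
    for j in range(n_loc):
        present = shared_mask | (unique_home == j)
        base = cat["base_intensity"][present].copy()
        dye_here = cat["is_dye"][present]
        if classes[j] == 1:
            base[dye_here] *= model.dye_absent_factor
        jitter = np.exp(
            model.log_intensity_sigma * rng.standard_normal(base.size)
            - 0.5 * model.log_intensity_sigma**2
        )
        mz_list.append(cat["mz"][present].copy())
        int_list.append(base * jitter)
    return SpectrumGrid(
        geometry=geometry,
        cells=cells,
        mz=mz_list,
        intensity=int_list,
        lock_mass=model.lock_mass,
        meta={
            "seed": int(seed),
            "n_unique_masses": int(unique_mask.sum()),
            "catalog_size": int(n_cat),
            "unique_mz": cat["mz"][unique_mask].copy(),
            "class_map": classes,
        },
    )


def level_multipliers(levels: int, decades: float = 2.0) -> np.ndarray:
    """Concentration multiplier per symbol: 0 for absence, then log-spaced.

    Symbol ``levels - 1`` is the undiluted extract (multiplier 1); symbol 1
    is ``10 ** -decades``; symbol 0 dispenses nothing.
    """
    if levels < 2 or levels & (levels - 1):
        raise ValueError(f"levels must be a power of two >= 2, got {levels}")
    out = np.zeros(levels)
    if levels == 2:
        out[1] = 1.0
    else:
        out[1:] = np.logspace(-decades, 0.0, levels - 1)
    return out


@dataclass(frozen=True)
class ExtractModel:
    """Generative description of a library of near-identical extracts.

    Each extract's shared profile is the substrate catalog scaled to
    ``intensity_scale`` at its strongest compound (so a full-strength
    deposit perturbs every background mass by a relative epsilon), with
    mild per-extract lognormal enrichment.  ``n_unique_per_extract``
    low-abundance masses per extract, absent from the cover catalog and
    from every other extract, carry the identifiable signal.
    """

    substrate: SubstrateModel = field(default_factory=SubstrateModel)
    intensity_scale: float = 1e5
    n_unique_per_extract: int = 4
    unique_decay: float = 0.5  # intensity ratio between successive unique masses
    enrichment_sigma: float = 0.5  # lognormal spread of per-compound enrichment
    levels: int = 32
    dilution_decades: float = 2.0
    first_unique_masses: tuple = (184.07, 478.33)  # extract 0, by convention
    # the identifying masses are themselves natural trace compounds of the
    # cover, so they also occur sporadically in the untreated background —
    # this interference is what makes the extracts hard to detect
    ambient_presence_prob: float = 0.25
    ambient_intensity: float = 1e3  # median interfering intensity, a.u.
    ambient_sigma: float = 1.0  # lognormal spread (natural log)

    def __post_init__(self) -> None:
        if self.n_unique_per_extract < 1:
            raise ValueError("each extract needs at least one unique mass")


@dataclass
class ExtractSignature:
    """One extract: shared compound profile + unique identifying masses."""

    extract_id: int
    shared_mz: np.ndarray
    shared_intensity: np.ndarray
    unique_mz: np.ndarray
    unique_intensity: np.ndarray

    @property
    def all_mz(self) -> np.ndarray:
        return np.concatenate([self.shared_mz, self.unique_mz])

    @property
    def all_intensity(self) -> np.ndarray:
        return np.concatenate([self.shared_intensity, self.unique_intensity])


@dataclass
class ExtractLibrary:
    """M extract signatures plus the shared dilution series."""

    signatures: list
    levels: int
    multipliers: np.ndarray  # per symbol, increasing; multipliers[0] == 0
    model: ExtractModel

    @property
    def n_extracts(self) -> int:
        return len(self.signatures)

    @property
    def dilution_series(self) -> np.ndarray:
        """Nonzero concentration multipliers, strictly decreasing."""
        return self.multipliers[1:][::-1].copy()

    def unique_masses(self, extract_id: int | None = None) -> np.ndarray:
        if extract_id is not None:
            return self.signatures[extract_id].unique_mz.copy()
        return np.concatenate([s.unique_mz for s in self.signatures])


def simulate_extracts(
    seed: int, n_extracts: int, model: ExtractModel | None = None
) -> ExtractLibrary:
    """Draw a library of M near-identical extract signatures.

    Unique-mass sets are pairwise disjoint and avoid the substrate catalog
    by at least the matching tolerance; extract 0 receives the
    conventional identifying masses first.
    """
    model = model or ExtractModel()
    if n_extracts < 1:
        raise ValueError("n_extracts must be >= 1")
    cat = substrate_catalog(model.substrate)
    rng = np.random.default_rng(seed)
    # extracts carry the cover's ubiquitous chemistry; compounds confined
    # to single surface spots are not part of the common profile
    ubiq = ~cat["is_sporadic"]
    shared_mz = cat["mz"][ubiq]
    profile_base = cat["base_intensity"][ubiq] / cat["base_intensity"].max()
    taken = list(cat["mz"])
    preset = list(model.first_unique_masses)

    def draw_unique() -> float:
        if preset:
            return preset.pop(0)
        while True:
            m = rng.uniform(model.substrate.mz_min, model.substrate.mz_max)
            if min(abs(m - t) for t in taken) > 4 * MATCH_TOL:
                return m

    signatures = []
    for e in range(n_extracts):
        enrich = np.exp(
            model.enrichment_sigma * rng.standard_normal(profile_base.size)
            - 0.5 * model.enrichment_sigma**2
        )
        shared = model.intensity_scale * profile_base * enrich
        umz = np.array([draw_unique() for _ in range(model.n_unique_per_extract)])
        taken.extend(umz.tolist())
        uint = model.intensity_scale * model.unique_decay ** np.arange(
            model.n_unique_per_extract
        )
        signatures.append(
            ExtractSignature(
                extract_id=e,
                shared_mz=shared_mz.copy(),
                shared_intensity=shared,
                unique_mz=umz,
                unique_intensity=uint,
            )
        )
    return ExtractLibrary(
        signatures=signatures,
        levels=model.levels,
        multipliers=level_multipliers(model.levels, model.dilution_decades),
        model=model,
    )


def ambient_interference(
    grid: SpectrumGrid, library: ExtractLibrary, seed: int | None = None
) -> SpectrumGrid:
    """Sporadic natural occurrences of the extracts' identifying masses.

    Because every extract is a solvent pull of the cover's own chemistry,
    its identifying compounds pre-exist on the surface: at each location,
    each unique mass appears with probability ``ambient_presence_prob`` at
    a lognormal trace intensity.  This is the interference floor that
    limits presence/absence readout, and it applies to the untreated grid
    before any deposition.
    """
    model = library.model
    out = grid.copy()
    if model.ambient_presence_prob <= 0:
        return out
    rng = np.random.default_rng(seed)
    umz = np.sort(library.unique_masses())
    for j in range(out.n_locations):
        hit = rng.random(umz.size) < model.ambient_presence_prob
        if not np.any(hit):
            continue
        inten = model.ambient_intensity * np.exp(
            model.ambient_sigma * rng.standard_normal(int(hit.sum()))
        )
        out.mz[j], out.intensity[j] = _add_peaks(
            out.mz[j], out.intensity[j], umz[hit], inten
        )
    return out


def _add_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    add_mz: np.ndarray,
    add_int: np.ndarray,
    tol: float = MATCH_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge added peaks into a sorted peak list.

    An added peak within ``tol`` of an existing peak (nearest wins, ties
    to lower m/z) reinforces it; otherwise it is inserted.
    """
    if add_mz.size == 0:
        return mz, intensity
    pos = np.searchsorted(mz, add_mz)
    left = np.clip(pos - 1, 0, max(mz.size - 1, 0))
    right = np.clip(pos, 0, max(mz.size - 1, 0))
    if mz.size:
        dl = np.abs(add_mz - mz[left])
        dr = np.abs(add_mz - mz[right])
        use_left = dl <= dr  # tie -> lower m/z
        nearest = np.where(use_left, left, right)
        dist = np.where(use_left, dl, dr)
        matched = dist <= tol
    else:
        nearest = np.zeros(add_mz.size, dtype=int)
        matched = np.zeros(add_mz.size, dtype=bool)
    intensity = intensity.copy()
    np.add.at(intensity, nearest[matched], add_int[matched])
    new_mz = add_mz[~matched]
    new_int = add_int[~matched]
    if new_mz.size:
        mz = np.concatenate([mz, new_mz])
        intensity = np.concatenate([intensity, new_int])
        order = np.argsort(mz)
        mz = mz[order]
        intensity = intensity[order]
    return mz, intensity


def deposit(
    grid: SpectrumGrid,
    picklist,
    library: ExtractLibrary,
    write_sigma: float = 0.0,
    failure_rate: float = 0.0,
    seed: int | None = None,
    reference_volume_nl: float = DEFAULT_DISPENSE_NL,
) -> SpectrumGrid:
    """Apply picklist transfers to a grid (additive superposition).

    Each transfer adds ``signature x multiplier(level) x volume ratio``
    to the destination spectrum.  ``write_sigma`` is the lognormal
    droplet/surface efficiency spread; with probability ``failure_rate`` a
    transfer largely fails (1% of nominal material arrives).  With both at
    zero the operation is exactly ``treated - untreated = summed scaled
    signatures``.
    """
    out = grid.copy()
    if len(picklist) == 0:
        return out
    rng = np.random.default_rng(seed)
    pending_mz: dict[int, list] = {}
    pending_int: dict[int, list] = {}
    for row in picklist.itertuples(index=False):
        e = int(row.extract_id)
        if not 0 <= e < library.n_extracts:
            raise KeyError(f"unknown extract id {e}")
        level = int(row.level_index)
        if not 0 < level < library.levels:
            raise ValueError(f"level {level} outside (0, {library.levels})")
        j = out.cell_index(int(row.dest_row), int(row.dest_col))
        sig = library.signatures[e]
        scale = library.multipliers[level] * float(row.volume_nl) / reference_volume_nl
        if write_sigma > 0:
            scale *= np.exp(
                write_sigma * rng.standard_normal() - 0.5 * write_sigma**2
            )
        if failure_rate > 0 and rng.random() < failure_rate:
            scale *= 0.01
        pending_mz.setdefault(j, []).append(sig.all_mz)
        pending_int.setdefault(j, []).append(sig.all_intensity * scale)
    for j, chunks in pending_mz.items():
        add_mz = np.concatenate(chunks)
        add_int = np.concatenate(pending_int[j])
        order = np.argsort(add_mz)
        out.mz[j], out.intensity[j] = _add_peaks(
            out.mz[j], out.intensity[j], add_mz[order], add_int[order]
        )
    return out


def acquire(
    grid: SpectrumGrid,
    k_reads: int,
    seed: int | None = None,
    read_sigma: float = 0.25,
    shot_scale: float = 1.0,
    mz_sigma: float = 5e-4,
    calibration_sigma: float = 0.002,
    detection_limit: float = 1.0,
) -> SpectrumGrid:
    """Average ``k_reads`` noisy acquisitions of every location.

    Per read, each peak intensity is scattered by a mean-preserving
    lognormal factor (``read_sigma``) plus sqrt-intensity shot noise; the
    averaged per-peak m/z wobbles by ``mz_sigma / sqrt(k)``, and the whole
    location drifts by a common calibration shift of ``calibration_sigma``
    Da (removed later by lock-mass alignment).  Averaging k reads shrinks
    the intensity noise standard error as 1/sqrt(k).  Averaged peaks
    below ``detection_limit`` are dropped (centroiding threshold).  With
    all noise scales at zero the grid is returned unchanged.
    """
    if k_reads < 1:
        raise ValueError("k_reads must be >= 1")
    out = grid.copy()
    if read_sigma == 0 and shot_scale == 0 and mz_sigma == 0 and calibration_sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for j in range(out.n_locations):
        inten = out.intensity[j]
        n = inten.size
        if n == 0:
            continue
        reads = inten[None, :] * np.exp(
            read_sigma * rng.standard_normal((k_reads, n)) - 0.5 * read_sigma**2
        )
        if shot_scale > 0:
            reads = reads + shot_scale * np.sqrt(inten)[None, :] * rng.standard_normal(
                (k_reads, n)
            )
        avg = np.clip(reads.mean(axis=0), 0.0, None)
        shift = calibration_sigma * rng.standard_normal()
        mz = (
            out.mz[j]
            + shift
            + (mz_sigma / np.sqrt(k_reads)) * rng.standard_normal(n)
        )
        keep = avg >= detection_limit
        mz, avg = mz[keep], avg[keep]
        order = np.argsort(mz)
        out.mz[j] = mz[order]
        out.intensity[j] = avg[order]
    out.meta["k_reads"] = int(k_reads)
    return out


def pooled_masses(grid: SpectrumGrid, tol: float = MATCH_TOL) -> np.ndarray:
    """Cluster all observed m/z values across the grid into consensus masses.

    Peaks are pooled by sorting and splitting wherever the gap between
    neighbours exceeds ``tol``; the consensus mass is the cluster mean.
    """
    allmz = np.sort(np.concatenate([m for m in grid.mz if m.size]))
    if allmz.size == 0:
        return allmz
    breaks = np.where(np.diff(allmz) > tol)[0] + 1
    groups = np.split(allmz, breaks)
    return np.array([g.mean() for g in groups])


def mean_spectrum(
    grid: SpectrumGrid, tol: float = MATCH_TOL
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid-mean intensity and location count per consensus mass.

    Returns ``(masses, mean_intensity, n_locations_present)``; absent
    locations contribute zero intensity to the mean.
    """
    centers = pooled_masses(grid, tol)
    total = np.zeros(centers.size)
    count = np.zeros(centers.size, dtype=np.int64)
    for mz, inten in zip(grid.mz, grid.intensity):
        if mz.size == 0:
            continue
        idx = np.searchsorted(centers, mz)
        left = np.clip(idx - 1, 0, centers.size - 1)
        right = np.clip(idx, 0, centers.size - 1)
        use_left = np.abs(mz - centers[left]) <= np.abs(mz - centers[right])
        nearest = np.where(use_left, left, right)
        np.add.at(total, nearest, inten)
        present = np.zeros(centers.size, dtype=bool)
        present[nearest] = True
        count += present
    return centers, total / grid.n_locations, count
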
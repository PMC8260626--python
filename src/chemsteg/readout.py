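"""Message recovery from a spectrum grid.

The reader's chain: lock-mass alignment of every spectrum, conversion of
intensities to background-referenced SNR, noise-floor feature filtering,
per-extract random-forest regression of the continuous concentration
level (trained on pilot spots with known levels), then the digital
inverse chain — quantize, desymbolize, de-interleave, combine
repetitions, turbo decode, debinarize.

Concentration regression is deliberately supervised: a pilot pattern of
spots with known levels, derivable by the reader from the shared
interleaver seed, plays the role of training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .bitcodec import TurboConfig, bsc_llr, raw_error_rate, turbo_decode
from .chemchannel import MATCH_TOL, SpectrumGrid, pooled_masses
from .framing import FramePlan, debinarize_key, quantize_levels, unframe

__all__ = [
    "LockMassError",
    "NormalizedSpectrum",
    "ReadoutModel",
    "lock_align",
    "lock_align_grid",
    "snr_normalize",
    "feature_matrix",
    "select_features",
    "fit_readout",
    "decode_message",
]

# Fraction of per-spectrum intensities (lowest first) treated as the
# background population when estimating (mu, sigma) for SNR.  Centroided
# peak lists contain only real peaks, so the weakest quartile stands in
# for the sub-noise-floor samples of a profile spectrum.
BACKGROUND_QUANTILE = 0.25


class LockMassError(ValueError):
    """No usable lock-mass peak; the location is unreadable."""


def lock_align(
    mz: np.ndarray,
    intensity: np.ndarray,
    lock_mass: float,
    window: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Shift a spectrum so its lock-mass peak sits exactly on ``lock_mass``.

    The strongest peak within ``window`` Da of the nominal lock mass is
    the reference; the constant shift placing it on the lock mass is
    applied to every m/z.  Idempotent.  Returns ``(aligned_mz, shift)``.
    """
    near = np.abs(mz - lock_mass) <= window
    if not np.any(near):
        raise LockMassError(
            f"no peak within {window} Da of lock mass {lock_mass}"
        )
    cand = np.where(near)[0]
    ref = cand[np.argmax(intensity[cand])]
    shift = lock_mass - mz[ref]
    return mz + shift, shift


def lock_align_grid(grid: SpectrumGrid, window: float = 0.05) -> SpectrumGrid:
    """Lock-align every location; unreadable locations are flagged in meta."""
    out = grid.copy()
    failed = []
    shifts = np.zeros(out.n_locations)
    for j in range(out.n_locations):
        try:
            out.mz[j], shifts[j] = lock_align(
                out.mz[j], out.intensity[j], out.lock_mass, window
            )
        except LockMassError:
            failed.append(j)
    out.meta["lock_shifts"] = shifts
    out.meta["unreadable"] = failed
    return out


@dataclass
class NormalizedSpectrum:
    """A spectrum on the SNR scale: ``snr = (I - mu) / sigma``."""

    mz: np.ndarray
    snr: np.ndarray
    mu: float
    sigma: float


def snr_normalize(
    mz: np.ndarray,
    intensity: np.ndarray,
    background_quantile: float = BACKGROUND_QUANTILE,
) -> NormalizedSpectrum:
    """Convert intensities to signal-to-noise ratios.

    ``mu`` and ``sigma`` are the mean and standard deviation of the
    background population, taken as the intensities at or below the
    ``background_quantile`` quantile of the spectrum.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.size < 10:
        raise ValueError("need at least 10 peaks to estimate the background")
    cut = np.quantile(intensity, background_quantile)
    bg = intensity[intensity <= cut]
    mu = float(bg.mean())
    sigma = float(bg.std())
    if sigma == 0.0:
        raise ValueError("degenerate spectrum: background sigma is zero")
    return NormalizedSpectrum(
        mz=np.asarray(mz, dtype=np.float64),
        snr=(intensity - mu) / sigma,
        mu=mu,
        sigma=sigma,
    )


def feature_matrix(
    grid: SpectrumGrid,
    masses: np.ndarray,
    tol: float = MATCH_TOL,
    background_quantile: float = BACKGROUND_QUANTILE,
) -> np.ndarray:
    """SNR of each catalog mass at each location, shape (n_loc, n_masses).

    A mass with no peak within ``tol`` reads as zero intensity, i.e.
    ``-mu / sigma`` on the SNR scale.
    """
    masses = np.asarray(masses, dtype=np.float64)
    out = np.empty((grid.n_locations, masses.size))
    for j in range(grid.n_locations):
        norm = snr_normalize(grid.mz[j], grid.intensity[j], background_quantile)
        mzj = norm.mz
        if mzj.size == 0:
            out[j] = -norm.mu / norm.sigma
            continue
        pos = np.searchsorted(mzj, masses)
        left = np.clip(pos - 1, 0, mzj.size - 1)
        right = np.clip(pos, 0, mzj.size - 1)
        use_left = np.abs(masses - mzj[left]) <= np.abs(masses - mzj[right])
        nearest = np.where(use_left, left, right)
        dist = np.abs(masses - mzj[nearest])
        vals = norm.snr[nearest]
        vals = np.where(dist <= tol, vals, -norm.mu / norm.sigma)
        out[j] = vals
    return out


def select_features(
    grid: SpectrumGrid,
    floor: float = 2.0,
    tol: float = MATCH_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep consensus masses whose grid-mean SNR clears the noise floor.

    Mirrors the noise-floor filtering step of real data processing (there:
    millions of raw m/z channels down to ~1e5); here the candidate set is
    the pooled consensus masses of the grid.  Returns ``(masses,
    mean_snr)`` ordered by m/z.
    """
    if grid.n_locations == 0:
        raise ValueError("empty grid")
    masses = pooled_masses(grid, tol)
    snr = feature_matrix(grid, masses, tol)
    mean_snr = snr.mean(axis=0)
    keep = mean_snr >= floor
    if not np.any(keep):
        raise ValueError(
            f"no masses clear SNR floor {floor}; maximum grid-mean SNR is "
            f"{mean_snr.max():.3f} - lower the floor"
        )
    return masses[keep], mean_snr[keep]


@dataclass
class _ExtractRegressor:
    feature_idx: np.ndarray
    forest: RandomForestRegressor
    heldout_true: np.ndarray
    heldout_pred: np.ndarray


@dataclass
class ReadoutModel:
    """Trained concentration readout: one forest per extract.

    ``predict`` returns continuous level indices, shape
    (n_locations, n_extracts); quantization to integer symbols happens
    later so repetition combining can stay soft.
    """

    feature_masses: np.ndarray
    levels: int
    regressors: list
    train_fraction: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n_extracts(self) -> int:
        return len(self.regressors)

    def predict(self, grid: SpectrumGrid) -> np.ndarray:
        snr = feature_matrix(grid, self.feature_masses)
        out = np.empty((grid.n_locations, self.n_extracts))
        for e, reg in enumerate(self.regressors):
            out[:, e] = reg.forest.predict(snr[:, reg.feature_idx])
        return out

    def heldout_scatter(self, extract_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Held-out (written level, predicted level) pairs for one extract."""
        reg = self.regressors[extract_id]
        return reg.heldout_true.copy(), reg.heldout_pred.copy()

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ReadoutModel":
        import joblib

        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a ReadoutModel")
        return obj

    def export_features(self, path) -> None:
        """Write the feature list as TSV (m/z, grid-mean SNR if known)."""
        df = pd.DataFrame(
            {
                "mz": self.feature_masses,
                "mean_snr": self.meta.get(
                    "mean_snr", np.full(self.feature_masses.size, np.nan)
                ),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def fit_readout(
    grid: SpectrumGrid,
    labels: pd.DataFrame,
    levels: int,
    split: float = 0.1,
    seed: int = 0,
    snr_floor: float = 2.0,
    n_trees: int = 200,
    top_k_features: int = 8,
) -> ReadoutModel:
    """Train the per-extract concentration regressors on pilot spots.

    ``labels`` has columns ``location`` (index into the grid),
    ``extract_id`` and ``level``.  ``split`` is the *training* fraction
    (default 10% train / 90% held out); held-out predictions are stored
    on the model for diagnostics.  For each extract the ``top_k_features``
    masses most correlated with the training labels are used, which keeps
    the forest effective when pilot data are scarce.
    """
    required = {"location", "extract_id", "level"}
    if not required.issubset(labels.columns):
        raise ValueError(f"labels need columns {sorted(required)}")
    if not 0 < split < 1:
        raise ValueError("split must be a fraction in (0, 1)")
    masses, mean_snr = select_features(grid, floor=snr_floor)
    snr = feature_matrix(grid, masses)
    regressors = []
    rng = np.random.default_rng(seed)
    for e in sorted(labels["extract_id"].unique()):
        sub = labels[labels["extract_id"] == e]
        loc = sub["location"].to_numpy(dtype=int)
        y = sub["level"].to_numpy(dtype=float)
        idx_train, idx_test = train_test_split(
            np.arange(loc.size),
            train_size=split,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        y_train = y[idx_train]
        if np.unique(y_train).size < 2:
            raise ValueError(
                f"extract {e}: training labels contain fewer than 2 distinct "
                "levels; enlarge the pilot pattern or the training split"
            )
        X = snr[loc]
        # supervised screening: keep the masses most correlated with level
        xt = X[idx_train]
        xc = xt - xt.mean(axis=0)
        yc = y_train - y_train.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum()) + 1e-30
        corr = np.abs(xc.T @ yc) / denom
        k = min(top_k_features, masses.size)
        feat_idx = np.sort(np.argsort(corr)[::-1][:k])
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(xt[:, feat_idx], y_train)
        pred = forest.predict(X[idx_test][:, feat_idx])
        regressors.append(
            _ExtractRegressor(
                feature_idx=feat_idx,
                forest=forest,
                heldout_true=y[idx_test],
                heldout_pred=pred,
            )
        )
    return ReadoutModel(
        feature_masses=masses,
        levels=levels,
        regressors=regressors,
        train_fraction=split,
        seed=seed,
        meta={"mean_snr": mean_snr},
    )


def decode_message(
    grid: SpectrumGrid,
    plan: FramePlan,
    model: ReadoutModel,
    cfg: TurboConfig,
    data_locations: np.ndarray | None = None,
    key_mode: str = "uuid",
    true_codeword: np.ndarray | None = None,
    llr_crossover: float = 0.1,
) -> tuple[str, dict]:
    """Recover the key text from an acquired grid.

    Continuous level predictions for the ``plan.n_locations`` data spots
    (grid locations ``data_locations``, default the first N) are combined
    across the R interleaved repetitions of each coded bit, hard-decided,
    and turbo decoded with hard-decision LLRs at a nominal crossover.
    Returns ``(key, stats)``; ``stats['raw_error_rate']`` is filled when
    the true codeword is supplied.
    """
    if model.n_extracts < plan.n_extracts:
        raise ValueError(
            f"model covers {model.n_extracts} extracts, plan needs "
            f"{plan.n_extracts}"
        )
    if data_locations is None:
        data_locations = np.arange(plan.n_locations)
    data_locations = np.asarray(data_locations, dtype=int)
    if data_locations.size != plan.n_locations:
        raise ValueError("data_locations length must equal plan.n_locations")
    pred = model.predict(grid)  # (n_loc, n_extracts)
    level_matrix = pred[data_locations][:, : plan.n_extracts].T  # (M, N)
    codeword = unframe(level_matrix, plan, soft=plan.levels == 2)
    info = turbo_decode(bsc_llr(codeword, llr_crossover), cfg)
    key = debinarize_key(info, mode=key_mode)
    stats: dict = {
        "n_codeword_bits": int(codeword.size),
        "n_info_bits": int(info.size),
        "levels": int(plan.levels),
        "repetitions": int(plan.repetitions),
        "quantized_levels": quantize_levels(level_matrix, plan.levels),
    }
    if true_codeword is not None:
        stats["raw_error_rate"] = raw_error_rate(codeword, true_codeword)
    return key, stats
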
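"""End-to-end orchestration: key -> picklist -> simulated grid -> key.

This module owns the run configuration (one structured document holding
every knob of every stage) and the glue between the digital layers
(bitcodec, framing), the physical channel simulation (chemchannel) and
the reader (readout).  The command-line interface is a thin wrapper
around these functions.

Pilot spots: the writer appends a block of locations with known levels
after the data region.  Their levels are generated from the shared
interleaver seed, so the legitimate reader — who knows the seed —
regenerates the training labels without any extra side channel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .bitcodec import TurboConfig, raw_error_rate, turbo_encode
from .chemchannel import (
    ExtractLibrary,
    ExtractModel,
    SpectrumGrid,
    SubstrateModel,
    acquire,
    ambient_interference,
    deposit,
    simulate_extracts,
    simulate_substrate,
)
from .framing import FramePlan, binarize_key, make_picklist
from .geometry import GridGeometry
from .interleave import lcg_permutation
from .readout import decode_message, fit_readout, lock_align_grid

__all__ = [
    "ChannelConfig",
    "ReadoutConfig",
    "RunConfig",
    "EncodeResult",
    "build_library",
    "load_config",
    "dump_config",
    "encode_key",
    "pilot_levels",
    "simulate_run",
    "decode_run",
    "run_round_trip",
    "evaluate_sweep",
]


@dataclass(frozen=True)
class ChannelConfig:
    """Physical noise knobs for deposition and acquisition."""

    write_sigma: float = 0.05  # lognormal droplet/surface efficiency spread
    failure_rate: float = 0.02  # probability a transfer largely fails
    k_reads: int = 4  # spectra averaged per location
    read_sigma: float = 0.25  # lognormal per-read intensity scatter
    shot_scale: float = 1.0  # sqrt-intensity shot-noise coefficient
    mz_sigma: float = 5e-4  # per-read m/z jitter, Da
    calibration_sigma: float = 0.002  # per-location mass drift, Da
    detection_limit: float = 1.0  # centroiding intensity threshold


@dataclass(frozen=True)
class ReadoutConfig:
    """Reader-side training and decoding knobs."""

    train_split: float = 0.8  # fraction of pilot spots used for training
    snr_floor: float = 2.0  # noise-floor feature filter
    n_trees: int = 200
    top_k_features: int = 8
    llr_crossover: float = 0.1  # nominal BSC level for hard-decision LLRs


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one write/read run."""

    geometry: GridGeometry = field(default_factory=GridGeometry)
    turbo: TurboConfig = field(default_factory=TurboConfig)
    substrate: SubstrateModel = field(default_factory=SubstrateModel)
    extract: ExtractModel = field(default_factory=ExtractModel)
    channel: ChannelConfig = field(default_factory=ChannelConfig)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    n_extracts: int = 3
    levels: int = 4
    repetitions: int = 1
    interleaver_seed: int = 7919
    n_pilot_locations: int = 48
    key_mode: str = "uuid"
    seed: int = 1

    def __post_init__(self) -> None:
        # keep the extract library's dilution grid in lockstep with the plan
        object.__setattr__(
            self,
            "extract",
            dataclasses.replace(
                self.extract, levels=self.levels, substrate=self.substrate
            ),
        )


def _from_dict(cls, data: dict):
    """Build a (nested) dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise TypeError(f"expected mapping for {cls.__name__}, got {type(data)}")
    names = {f.name: f for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        ftype = names[k].type
        target = {
            "GridGeometry": GridGeometry,
            "TurboConfig": TurboConfig,
            "SubstrateModel": SubstrateModel,
            "ExtractModel": ExtractModel,
            "ChannelConfig": ChannelConfig,
            "ReadoutConfig": ReadoutConfig,
        }.get(str(ftype).split(".")[-1].strip("'\" "))
        kwargs[k] = _from_dict(target, v) if target and isinstance(v, dict) else v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are an error."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return _from_dict(RunConfig, data)


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _to_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if f.init
        }
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_to_dict(config), f, sort_keys=False)


@dataclass
class EncodeResult:
    """Everything the writer produces for one key."""

    picklist: pd.DataFrame
    plan: FramePlan
    data_cells: np.ndarray  # (N, 2) grid cells carrying the payload
    pilot_cells: np.ndarray  # (P, 2) grid cells carrying training levels
    pilot_labels: pd.DataFrame  # location/extract_id/level rows
    codeword: np.ndarray  # the transmitted turbo codeword (for stats)
    level_matrix: np.ndarray  # M x N written symbols


def pilot_levels(seed: int, n_extracts: int, n_pilots: int, levels: int) -> np.ndarray:
    """Deterministic pilot level pattern, shape (n_extracts, n_pilots).

    Cycles through all levels then shuffles with the seed-regenerable
    permutation, independently per extract, so every level appears
    near-uniformly and the reader can regenerate the labels from the
    shared seed alone.
    """
    out = np.empty((n_extracts, n_pilots), dtype=np.int64)
    for e in range(n_extracts):
        base = np.tile(np.arange(levels), -(-n_pilots // levels))[:n_pilots]
        perm = lcg_permutation(seed * 1000 + 17 * e + 1, n_pilots)
        out[e] = base[perm]
    return out


def _cells_rowmajor(geometry: GridGeometry, start: int, count: int) -> np.ndarray:
    idx = np.arange(start, start + count)
    if count and idx[-1] >= geometry.n_cells:
        raise ValueError(
            f"{start + count} locations exceed the "
            f"{geometry.rows}x{geometry.cols} grid"
        )
    return np.stack([idx // geometry.cols, idx % geometry.cols], axis=1)


def encode_key(key: str, config: RunConfig) -> EncodeResult:
    """Binarize, turbo encode, frame and emit the full picklist.

    Data spots occupy the first N grid cells (row-major); pilot spots
    with seed-derivable known levels follow immediately after.
    """
    bits = binarize_key(key, mode=config.key_mode)
    codeword = turbo_encode(bits, config.turbo)
    plan = FramePlan.for_payload(
        codeword.size,
        n_extracts=config.n_extracts,
        levels=config.levels,
        repetitions=config.repetitions,
        interleaver_seed=config.interleaver_seed,
    )
    from .framing import frame  # local import keeps module load light

    matrix = frame(codeword, plan)
    data_cells = _cells_rowmajor(config.geometry, 0, plan.n_locations)
    pilot_cells = _cells_rowmajor(
        config.geometry, plan.n_locations, config.n_pilot_locations
    )
    plevels = pilot_levels(
        config.interleaver_seed,
        config.n_extracts,
        config.n_pilot_locations,
        config.levels,
    )
    pick_data = make_picklist(matrix, config.geometry, cells=data_cells)
    pick_pilot = make_picklist(plevels, config.geometry, cells=pilot_cells)
    picklist = pd.concat([pick_data, pick_pilot], ignore_index=True)
    cols = config.geometry.cols
    rows = []
    for e in range(config.n_extracts):
        for p in range(config.n_pilot_locations):
            rows.append(
                {
                    "location": int(pilot_cells[p, 0] * cols + pilot_cells[p, 1]),
                    "extract_id": e,
                    "level": int(plevels[e, p]),
                }
            )
    pilot_labels = pd.DataFrame(rows)
    return EncodeResult(
        picklist=picklist,
        plan=plan,
        data_cells=data_cells,
        pilot_cells=pilot_cells,
        pilot_labels=pilot_labels,
        codeword=codeword,
        level_matrix=matrix,
    )


def build_library(config: RunConfig) -> ExtractLibrary:
    return simulate_extracts(config.seed + 101, config.n_extracts, config.extract)


def simulate_run(
    picklist: pd.DataFrame, config: RunConfig, library: ExtractLibrary | None = None
) -> SpectrumGrid:
    """Untreated substrate + deposition + noisy averaged acquisition."""
    library = library or build_library(config)
    grid = simulate_substrate(config.seed + 202, config.geometry, config.substrate)
    grid = ambient_interference(grid, library, seed=config.seed + 250)
    ch = config.channel
    treated = deposit(
        grid,
        picklist,
        library,
        write_sigma=ch.write_sigma,
        failure_rate=ch.failure_rate,
        seed=config.seed + 303,
    )
    return acquire(
        treated,
        ch.k_reads,
        seed=config.seed + 404,
        read_sigma=ch.read_sigma,
        shot_scale=ch.shot_scale,
        mz_sigma=ch.mz_sigma,
        calibration_sigma=ch.calibration_sigma,
        detection_limit=ch.detection_limit,
    )


def decode_run(
    grid: SpectrumGrid,
    plan: FramePlan,
    config: RunConfig,
    true_codeword: np.ndarray | None = None,
):
    """Reader side: align, train on regenerated pilot labels, decode."""
    aligned = lock_align_grid(grid)
    plevels = pilot_levels(
        plan.interleaver_seed,
        plan.n_extracts,
        config.n_pilot_locations,
        plan.levels,
    )
    cols = config.geometry.cols
    pilot_cells = _cells_rowmajor(
        config.geometry, plan.n_locations, config.n_pilot_locations
    )
    rows = []
    for e in range(plan.n_extracts):
        for p in range(config.n_pilot_locations):
            rows.append(
                {
                    "location": int(pilot_cells[p, 0] * cols + pilot_cells[p, 1]),
                    "extract_id": e,
                    "level": int(plevels[e, p]),
                }
            )
    labels = pd.DataFrame(rows)
    ro = config.readout
    model = fit_readout(
        aligned,
        labels,
        levels=plan.levels,
        split=ro.train_split,
        seed=config.seed + 505,
        snr_floor=ro.snr_floor,
        n_trees=ro.n_trees,
        top_k_features=ro.top_k_features,
    )
    data_cells = _cells_rowmajor(config.geometry, 0, plan.n_locations)
    data_locations = data_cells[:, 0] * cols + data_cells[:, 1]
    key, stats = decode_message(
        aligned,
        plan,
        model,
        config.turbo,
        data_locations=data_locations,
        key_mode=config.key_mode,
        true_codeword=true_codeword,
        llr_crossover=ro.llr_crossover,
    )
    return key, stats, model


def run_round_trip(key: str, config: RunConfig) -> dict:
    """Full write/simulate/read cycle; returns recovery statistics."""
    enc = encode_key(key, config)
    library = build_library(config)
    grid = simulate_run(enc.picklist, config, library)
    recovered, stats, model = decode_run(
        grid, enc.plan, config, true_codeword=enc.codeword
    )
    true_bits = binarize_key(key, mode=config.key_mode)
    rec_bits = binarize_key(recovered, mode=config.key_mode) if recovered else None
    decoded_err = (
        raw_error_rate(rec_bits, true_bits) if rec_bits is not None else 1.0
    )
    stats.update(
        {
            "key_in": key,
            "key_out": recovered,
            "exact_match": recovered == key,
            "decoded_bit_error_rate": decoded_err,
        }
    )
    return stats


def evaluate_sweep(
    key: str,
    config: RunConfig,
    repetitions_values,
    k_read_values,
    replicate_seeds,
) -> pd.DataFrame:
    """Raw/decoded error rates over write-repetition and read-average sweeps."""
    rows = []
    for r in repetitions_values:
        for k in k_read_values:
            for s in replicate_seeds:
                cfg = dataclasses.replace(
                    config,
                    repetitions=int(r),
                    channel=dataclasses.replace(config.channel, k_reads=int(k)),
                    seed=int(s),
                )
                stats = run_round_trip(key, cfg)
                rows.append(
                    {
                        "repetitions": int(r),
                        "k_reads": int(k),
                        "seed": int(s),
                        "raw_error_rate": stats.get("raw_error_rate", np.nan),
                        "decoded_bit_error_rate": stats["decoded_bit_error_rate"],
                        "exact_match": stats["exact_match"],
                    }
                )
    return pd.DataFrame(rows)
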
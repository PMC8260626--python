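"""Payload framing: from a text secret to L-ary liquid-transfer symbols.

The writer-side chain is

    key text -> bits -> turbo codeword -> repeat R times -> zero-pad
             -> interleave -> L-ary symbols -> M x N level matrix -> picklist

and every step here is exactly invertible (repetition inversion averages the
R copies).  Symbols are 0-based: symbol 0 means "dispense nothing", the
remaining L-1 symbols select log-spaced dilutions of an extract, so the
presence/absence scheme is simply L = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import GridGeometry
from .interleave import check_permutation, lcg_permutation

__all__ = [
    "FramePlan",
    "binarize_key",
    "debinarize_key",
    "make_interleaver",
    "interleave",
    "deinterleave",
    "symbolize",
    "desymbolize",
    "quantize_levels",
    "frame",
    "unframe",
    "make_picklist",
    "capacity",
]

DEFAULT_DISPENSE_NL = 2.5

PICKLIST_COLUMNS = [
    "source_plate",
    "source_well",
    "extract_id",
    "level_index",
    "dest_row",
    "dest_col",
    "volume_nl",
]


@dataclass(frozen=True)
class FramePlan:
    """Framing parameters shared by writer and reader.

    ``n_extracts`` (M) extracts times ``n_locations`` (N) surface spots,
    each transfer carrying ``log2(levels)`` bits, must hold the payload
    repeated ``repetitions`` (R) times plus ``pad_length`` filler zeros.
    """

    n_extracts: int
    n_locations: int
    levels: int = 2
    repetitions: int = 1
    interleaver_seed: int = 7919
    pad_length: int = 0

    def __post_init__(self) -> None:
        if self.n_extracts < 1 or self.n_locations < 1:
            raise ValueError("n_extracts and n_locations must be positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.levels < 2 or self.levels & (self.levels - 1):
            raise ValueError(f"levels must be a power of two >= 2, got {self.levels}")
        if self.pad_length < 0:
            raise ValueError("pad_length must be non-negative")

    @property
    def bits_per_transfer(self) -> int:
        return self.levels.bit_length() - 1

    @property
    def slot_bits(self) -> int:
        """Total raw-bit capacity of the M x N frame."""
        return self.n_extracts * self.n_locations * self.bits_per_transfer

    @classmethod
    def for_payload(
        cls,
        n_payload_bits: int,
        n_extracts: int,
        levels: int = 2,
        repetitions: int = 1,
        interleaver_seed: int = 7919,
        n_locations: int | None = None,
    ) -> "FramePlan":
        """Build a plan for a given payload, sizing N minimally if omitted."""
        b = levels.bit_length() - 1
        need = n_payload_bits * repetitions
        if n_locations is None:
            n_locations = math.ceil(need / (n_extracts * b))
        plan = cls(
            n_extracts=n_extracts,
            n_locations=n_locations,
            levels=levels,
            repetitions=repetitions,
            interleaver_seed=interleaver_seed,
        )
        pad = plan.slot_bits - need
        if pad < 0:
            raise ValueError(
                f"payload of {need} raw bits exceeds frame capacity "
                f"{plan.slot_bits}; need n_locations >= "
                f"{math.ceil(need / (n_extracts * b))}"
            )
        return replace(plan, pad_length=pad)


_UUID_DASHES = (8, 12, 16, 20)


def binarize_key(text: str, mode: str = "uuid") -> np.ndarray:
    """Convert a secret string to a bit array (MSB first).

    ``uuid`` mode strips dashes and reads hex nibbles (a UUID gives 128
    bits); ``bytes`` mode encodes UTF-8 bytes at 8 bits per byte.
    """
    if mode == "uuid":
        hexstr = text.replace("-", "").lower()
        if not hexstr:
            raise ValueError("empty key")
        try:
            nibbles = [int(c, 16) for c in hexstr]
        except ValueError as exc:
            raise ValueError(f"non-hex character in key {text!r}") from exc
        bits = np.zeros(4 * len(nibbles), dtype=np.uint8)
        for i, v in enumerate(nibbles):
            for j in range(4):
                bits[4 * i + j] = (v >> (3 - j)) & 1
        return bits
    if mode == "bytes":
        raw = text.encode("utf-8")
        if not raw:
            raise ValueError("empty key")
        return np.unpackbits(np.frombuffer(raw, dtype=np.uint8))
    raise ValueError(f"unknown binarization mode {mode!r}")


def debinarize_key(bits, mode: str = "uuid") -> str:
    """Invert :func:`binarize_key`; 128-bit UUID-mode output is re-dashed."""
    arr = np.asarray(bits, dtype=np.uint8).ravel()
    if mode == "uuid":
        if arr.size % 4:
            raise ValueError("bit length must be a multiple of 4 in uuid mode")
        weights = np.array([8, 4, 2, 1], dtype=np.uint8)
        nibbles = arr.reshape(-1, 4) @ weights
        hexstr = "".join(f"{v:x}" for v in nibbles)
        if len(hexstr) == 32:
            parts, prev = [], 0
            for cut in _UUID_DASHES:
                parts.append(hexstr[prev:cut])
                prev = cut
            parts.append(hexstr[prev:])
            return "-".join(parts)
        return hexstr
    if mode == "bytes":
        if arr.size % 8:
            raise ValueError("bit length must be a multiple of 8 in bytes mode")
        return np.packbits(arr).tobytes().decode("utf-8")
    raise ValueError(f"unknown binarization mode {mode!r}")


def make_interleaver(seed: int, n: int) -> np.ndarray:
    """Seed-regenerable permutation of ``0..n-1`` (LCG + Fisher-Yates)."""
    return lcg_permutation(seed, n)


def interleave(seq, idx) -> np.ndarray:
    """Permute ``seq`` so output position k holds ``seq[idx[k]]``."""
    idx = check_permutation(idx)
    arr = np.asarray(seq)
    if arr.shape[0] != idx.size:
        raise ValueError("sequence and index lengths differ")
    return arr[idx]


def deinterleave(seq, idx) -> np.ndarray:
    """Invert :func:`interleave` (gather by the argsort of ``idx``)."""
    idx = check_permutation(idx)
    arr = np.asarray(seq)
    if arr.shape[0] != idx.size:
        raise ValueError("sequence and index lengths differ")
    out = np.empty_like(arr)
    out[idx] = arr
    return out


def _bits_per_symbol(levels: int) -> int:
    if levels < 2 or levels & (levels - 1):
        raise ValueError(f"levels must be a power of two >= 2, got {levels}")
    return levels.bit_length() - 1


def symbolize(bits, levels: int) -> np.ndarray:
    """Group bits (MSB first) into integer symbols in ``[0, levels)``."""
    b = _bits_per_symbol(levels)
    arr = np.asarray(bits, dtype=np.int64).ravel()
    if arr.size % b:
        raise ValueError(f"bit length {arr.size} not divisible by {b}")
    weights = 1 << np.arange(b - 1, -1, -1)
    return (arr.reshape(-1, b) * weights).sum(axis=1)


def desymbolize(symbols, levels: int) -> np.ndarray:
    """Expand symbols back into their MSB-first bit groups."""
    b = _bits_per_symbol(levels)
    sym = np.asarray(symbols, dtype=np.int64).ravel()
    if np.any((sym < 0) | (sym >= levels)):
        raise ValueError(f"symbols out of range [0, {levels})")
    shifts = np.arange(b - 1, -1, -1)
    return ((sym[:, None] >> shifts) & 1).astype(np.uint8).ravel()


def quantize_levels(pred, levels: int) -> np.ndarray:
    """Round continuous level predictions to the nearest integer level.

    Exact midpoints round down (30.5 -> 30); output clipped to
    ``[0, levels - 1]``.
    """
    arr = np.asarray(pred, dtype=np.float64)
    q = np.ceil(arr - 0.5)
    return np.clip(q, 0, levels - 1).astype(np.int64)


def frame(bits, plan: FramePlan) -> np.ndarray:
    """Repeat, pad, interleave and symbolize a codeword into an M x N matrix.

    Rows index extracts, columns index surface locations; the symbol stream
    fills the matrix row-major.
    """
    arr = np.asarray(bits, dtype=np.uint8).ravel()
    n = arr.size
    if n == 0:
        raise ValueError("cannot frame an empty payload")
    expected_pad = plan.slot_bits - n * plan.repetitions
    if expected_pad < 0:
        b = plan.bits_per_transfer
        raise ValueError(
            f"payload of {n * plan.repetitions} raw bits exceeds capacity "
            f"{plan.slot_bits}; need n_locations >= "
            f"{math.ceil(n * plan.repetitions / (plan.n_extracts * b))}"
        )
    if plan.pad_length != expected_pad:
        raise ValueError(
            f"plan.pad_length={plan.pad_length} inconsistent with payload "
            f"(expected {expected_pad}); build plans with FramePlan.for_payload"
        )
    raw = np.concatenate(
        [np.tile(arr, plan.repetitions), np.zeros(plan.pad_length, dtype=np.uint8)]
    )
    idx = make_interleaver(plan.interleaver_seed, raw.size)
    shuffled = interleave(raw, idx)
    symbols = symbolize(shuffled, plan.levels)
    return symbols.reshape(plan.n_extracts, plan.n_locations)


def unframe(values, plan: FramePlan, soft: bool = False) -> np.ndarray:
    """Invert :func:`frame`, combining the R repetitions of each coded bit.

    ``values`` is the M x N matrix of recovered levels.  With
    ``soft=True`` and two levels the entries may be continuous presence
    estimates in [0, 1], which are averaged across repetitions before the
    final threshold; otherwise entries are quantized to integer levels and
    expanded to bits first.  The combined bit is 1 when the repetition mean
    exceeds 0.5 (an exact tie rounds down to 0).
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.shape != (plan.n_extracts, plan.n_locations):
        raise ValueError(
            f"matrix shape {arr.shape} does not match plan "
            f"({plan.n_extracts}, {plan.n_locations})"
        )
    stream = arr.reshape(-1)
    if soft and plan.levels == 2:
        bit_vals = np.clip(stream, 0.0, 1.0)
    else:
        symbols = quantize_levels(stream, plan.levels)
        bit_vals = desymbolize(symbols, plan.levels).astype(np.float64)
    idx = make_interleaver(plan.interleaver_seed, bit_vals.size)
    ordered = deinterleave(bit_vals, idx)
    if plan.pad_length:
        ordered = ordered[: ordered.size - plan.pad_length]
    if ordered.size % plan.repetitions:
        raise ValueError("payload length inconsistent with repetitions")
    copies = ordered.reshape(plan.repetitions, -1)
    combined = copies.mean(axis=0)
    return (combined > 0.5).astype(np.uint8)


def _default_cells(n_locations: int, geometry: GridGeometry) -> np.ndarray:
    if n_locations > geometry.rows * geometry.cols:
        raise ValueError(
            f"{n_locations} locations exceed the {geometry.rows}x{geometry.cols} grid"
        )
    j = np.arange(n_locations)
    return np.stack([j // geometry.cols, j % geometry.cols], axis=1)


def make_picklist(
    matrix,
    geometry: GridGeometry,
    volume_nl: float = DEFAULT_DISPENSE_NL,
    cells: np.ndarray | None = None,
    source_plate: str = "library1",
) -> pd.DataFrame:
    """Turn a level matrix into liquid-handler dispense instructions.

    One CSV row per (extract, location) with a nonzero level; level 0 means
    "leave the spot untouched" and emits nothing.  Locations map to grid
    cells row-major unless explicit ``cells`` (row, col) are given.  Source
    wells name the library plate position of the extract dilution
    (row letter = extract, column = level).
    """
    if volume_nl <= 0:
        raise ValueError("volume must be positive")
    mat = np.asarray(matrix, dtype=np.int64)
    if mat.ndim != 2:
        raise ValueError("level matrix must be 2-D (extracts x locations)")
    m, n = mat.shape
    cells = _default_cells(n, geometry) if cells is None else np.asarray(cells)
    if cells.shape != (n, 2):
        raise ValueError("cells must be (n_locations, 2) row/col pairs")
    if np.any(cells < 0) or np.any(cells[:, 0] >= geometry.rows) or np.any(
        cells[:, 1] >= geometry.cols
    ):
        raise ValueError("destination outside grid")
    rows = []
    for e in range(m):
        for j in range(n):
            level = int(mat[e, j])
            if level == 0:
                continue
            rows.append(
                {
                    "source_plate": source_plate,
                    "source_well": f"{chr(ord('A') + e)}{level:02d}",
                    "extract_id": e,
                    "level_index": level,
                    "dest_row": int(cells[j, 0]),
                    "dest_col": int(cells[j, 1]),
                    "volume_nl": float(volume_nl),
                }
            )
    return pd.DataFrame(rows, columns=PICKLIST_COLUMNS)


def capacity(
    spots: int, spot_volume_nl: float, dispense_volume_nl: float, bits_per_transfer: int
) -> int:
    """Raw-bit payload limit of a surface.

    Each spot accepts ``floor(spot_volume / dispense_volume)`` transfers,
    each carrying ``bits_per_transfer`` bits.
    """
    if spots <= 0 or spot_volume_nl <= 0 or dispense_volume_nl <= 0:
        raise ValueError("all capacity arguments must be positive")
    if bits_per_transfer <= 0:
        raise ValueError("bits_per_transfer must be positive")
    if dispense_volume_nl > spot_volume_nl:
        raise ValueError("dispense volume exceeds spot volume")
    return int(spot_volume_nl // dispense_volume_nl) * spots * bits_per_transfer
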
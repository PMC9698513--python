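"""Square binary fiducial markers: dictionary generation, matching, rendering.

A marker is a square grid of black/white payload cells surrounded by a
one-cell black border.  The payload encodes the marker identity; identities
are drawn from a :class:`MarkerDictionary` whose codewords are mutually
separated (under every in-plane quarter-turn) by a minimum Hamming distance,
so that a bounded number of mis-read cells can never flip one identity into
another.  Bit polarity is black = 1: thresholded ink is the signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerDictionary",
    "MarkerBitmap",
    "build_dictionary",
    "encode",
    "decode_bitmap",
    "match_candidate",
    "render_marker",
]


def _rotations(code: np.ndarray) -> list[np.ndarray]:
    """The four quarter-turn variants of a codeword, counter-clockwise."""
    return [np.rot90(code, k) for k in range(4)]


def rotational_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Minimum Hamming distance between ``a`` and any quarter-turn of ``b``."""
    return min(int(np.sum(a != r)) for r in _rotations(b))


@dataclass(frozen=True)
class MarkerDictionary:
    """Rotation-discriminating codebook of square binary fiducials.

    Parameters
    ----------
    grid_size : int
        Payload cells per side (>= 3).
    codewords : dict[int, np.ndarray]
        Per-id boolean ``grid_size x grid_size`` payload matrices
        (True = black cell).
    min_hamming : int
        Guaranteed minimum pairwise Hamming distance under all relative
        quarter-turns, and between distinct rotations of one codeword.
    """

    grid_size: int
    codewords: dict[int, np.ndarray] = field(repr=False)
    min_hamming: int

    @property
    def ids(self) -> list[int]:
        return sorted(self.codewords)

    @property
    def correction_capacity(self) -> int:
        """Cells that may flip without changing the matched identity."""
        return (self.min_hamming - 1) // 2

    def validate(self) -> None:
        """Check codebook invariants; raise ``ValueError`` on violation."""
        ids = self.ids
        for i in ids:
            c = self.codewords[i]
            if c.shape != (self.grid_size, self.grid_size):
                raise ValueError(f"codeword {i} has shape {c.shape}")
            for k in range(1, 4):
                if int(np.sum(c != np.rot90(c, k))) < self.min_hamming:
                    raise ValueError(
                        f"codeword {i} too close to its own rotation {k}"
                    )
        for a_pos, i in enumerate(ids):
            for j in ids[a_pos + 1:]:
                d = rotational_distance(self.codewords[i], self.codewords[j])
                if d < self.min_hamming:
                    raise ValueError(
                        f"codewords {i} and {j} at rotational distance {d} "
                        f"< {self.min_hamming}"
                    )

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        n = self.grid_size * self.grid_size
        width = (n + 3) // 4
        words = {}
        for i in self.ids:
            bits = self.codewords[i].flatten()
            value = 0
            for b in bits:
                value = (value << 1) | int(b)
            words[str(i)] = format(value, f"0{width}x")
        return json.dumps(
            {
                "grid_size": self.grid_size,
                "min_hamming": self.min_hamming,
                "codewords": words,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MarkerDictionary":
        obj = json.loads(text)
        g = int(obj["grid_size"])
        n = g * g
        codewords = {}
        for key, hexstr in obj["codewords"].items():
            value = int(hexstr, 16)
            bits = [(value >> (n - 1 - k)) & 1 for k in range(n)]
            codewords[int(key)] = np.array(bits, dtype=bool).reshape(g, g)
        return cls(grid_size=g, codewords=codewords,
                   min_hamming=int(obj["min_hamming"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MarkerDictionary":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass(frozen=True)
class MarkerBitmap:
    """Bordered marker bitmap: payload grid plus a 1-cell black border."""

    bits: np.ndarray  # bool, (grid_size+2) x (grid_size+2), True = black

    @property
    def grid_size(self) -> int:
        return self.bits.shape[0] - 2

    @property
    def payload(self) -> np.ndarray:
        return self.bits[1:-1, 1:-1]

    def border_ok(self) -> bool:
        b = self.bits
        return bool(b[0].all() and b[-1].all()
                    and b[:, 0].all() and b[:, -1].all())


def build_dictionary(n_ids: int, grid_size: int = 4, min_hamming: int = 3,
                     seed: int = 0, max_attempts_per_id: int = 20_000
                     ) -> MarkerDictionary:
    """Greedily generate a marker dictionary with a seeded RNG.

    Candidate payloads are drawn uniformly at random and accepted when they
    keep rotational Hamming distance >= ``min_hamming`` from every accepted
    codeword and from their own nontrivial rotations (so the decode rotation
    is recoverable even under the correctable number of bit errors).

    Raises
    ------
    ValueError
        If preconditions fail, or if the search budget is exhausted before
        ``n_ids`` codewords are placed (capacity error).
    """
    if n_ids < 1:
        raise ValueError("n_ids must be >= 1")
    if grid_size < 3:
        raise ValueError("grid_size must be >= 3")
    if min_hamming < 1:
        raise ValueError("min_hamming must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_id * n_ids
    while len(accepted) < n_ids:
        if attempts >= budget:
            raise ValueError(
                f"capacity error: placed {len(accepted)}/{n_ids} codewords "
                f"(grid_size={grid_size}, min_hamming={min_hamming}) within "
                f"the search budget"
            )
        attempts += 1
        cand = rng.random((grid_size, grid_size)) < 0.5
        # self-rotation separation (also excludes 4-fold symmetric patterns)
        if any(int(np.sum(cand != np.rot90(cand, k))) < min_hamming
               for k in range(1, 4)):
            continue
        if any(rotational_distance(cand, c) < min_hamming for c in accepted):
            continue
        accepted.append(cand)
    codewords = {i: accepted[i] for i in range(n_ids)}
    return MarkerDictionary(grid_size=grid_size, codewords=codewords,
                            min_hamming=min_hamming)


def encode(marker_id: int, dictionary: MarkerDictionary) -> MarkerBitmap:
    """Bordered bitmap for ``marker_id`` (KeyError-style lookup error)."""
    if marker_id not in dictionary.codewords:
        raise KeyError(f"unknown marker id {marker_id}")
    g = dictionary.grid_size
    bits = np.ones((g + 2, g + 2), dtype=bool)
    bits[1:-1, 1:-1] = dictionary.codewords[marker_id]
    return MarkerBitmap(bits=bits)


def match_candidate(bits: MarkerBitmap | np.ndarray,
                    dictionary: MarkerDictionary
                    ) -> tuple[int, int] | None:
    """Match a payload against the dictionary under all four rotations.

    Accepts either a :class:`MarkerBitmap` (payload extracted, border not
    re-checked here) or a bare payload matrix.  Returns ``(id, rotation)``
    where ``rotation`` counts counter-clockwise quarter-turns applied to the
    canonical codeword to produce the observed payload, or ``None`` when the
    best match exceeds the correction capacity ``floor((min_hamming-1)/2)``.
    """
    payload = bits.payload if isinstance(bits, MarkerBitmap) else np.asarray(
        bits, dtype=bool)
    g = dictionary.grid_size
    if payload.shape != (g, g):
        raise ValueError(
            f"payload shape {payload.shape} does not match grid_size {g}")
    tol = dictionary.correction_capacity
    best: tuple[int, int, int] | None = None  # (distance, id, rotation)
    for marker_id in dictionary.ids:
        code = dictionary.codewords[marker_id]
        for rot in range(4):
            d = int(np.sum(payload != np.rot90(code, rot)))
            if best is None or d < best[0]:
                best = (d, marker_id, rot)
    if best is None or best[0] > tol:
        return None
    return best[1], best[2]


def render_marker(marker_id: int, dictionary: MarkerDictionary,
                  side_px: int, quiet_zone: bool = False) -> np.ndarray:
    """Render a marker as an 8-bit grayscale image (0 = black ink).

    ``side_px`` must be a positive multiple of ``grid_size + 2`` so each cell
    maps to an integer pixel block (crisp nearest-neighbour upsampling).
    With ``quiet_zone`` a white margin of one cell width is added around the
    bordered bitmap.
    """
    bitmap = encode(marker_id, dictionary)
    cells = dictionary.grid_size + 2
    if side_px <= 0 or side_px % cells != 0:
        raise ValueError(
            f"side_px must be a positive multiple of {cells}, got {side_px}")
    scale = side_px // cells
    img = np.where(np.kron(bitmap.bits, np.ones((scale, scale), dtype=bool)),
                   np.uint8(0), np.uint8(255))
    if quiet_zone:
        out = np.full((side_px + 2 * scale, side_px + 2 * scale), 255,
                      dtype=np.uint8)
        out[scale:-scale, scale:-scale] = img
        return out
    return img


def decode_bitmap(image: np.ndarray, grid_size: int,
                  threshold: float | None = None) -> MarkerBitmap:
    """Re-grid a crisp marker image back into a bordered bitmap.

    Inverse of :func:`render_marker` for axis-aligned, unwarped images whose
    side is a multiple of ``grid_size + 2``; each cell is bit-assigned by the
    mean intensity of its pixel block against ``threshold`` (default 128).
    """
    img = np.asarray(image, dtype=float)
    cells = grid_size + 2
    if img.shape[0] != img.shape[1] or img.shape[0] % cells != 0:
        raise ValueError("image side must be a multiple of grid_size + 2")
    scale = img.shape[0] // cells
    thr = 128.0 if threshold is None else float(threshold)
    means = img.reshape(cells, scale, cells, scale).mean(axis=(1, 3))
    return MarkerBitmap(bits=means < thr)
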
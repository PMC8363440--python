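"""Core block-matching engine for speckle tracking.

Similarity between a template block and a candidate block is the sum of
absolute differences (SAD).  A block of side ``2^M`` is represented as a
pyramid of ``M+1`` layers, layer ``l`` having side ``2^l``: each coarser
layer is the 2x2 sum-pool of the finer one.  By the triangle inequality the
SAD of any coarse layer is a lower bound on the SAD of the finest layer, so
a candidate can be abandoned as soon as a coarse-layer SAD already meets the
best full-resolution SAD found so far.  This pruning never changes the
optimum: the pyramid-pruned search returns exactly the exhaustive-search
answer at a fraction of the arithmetic.

Three search strategies are provided over a square window of integer
displacements:

* :func:`global_search` — exhaustive evaluation of every candidate
  (guaranteed optimum, the accuracy reference).
* :func:`bmp_search` — the pruned search; identical result, fewer
  full-resolution evaluations.
* :func:`log_search` — 2-D logarithmic (step-halving) descent; fast but may
  stop at a local SAD minimum on multimodal surfaces.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left; a
displacement ``(dr, dc)`` is the candidate block origin minus the window
centre.  Ties in SAD are always broken by lexicographic ``(dr, dc)`` order,
smallest first, which makes every strategy deterministic and lets the pruned
and exhaustive searches agree bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "BlockMatchError",
    "SizeMismatchError",
    "InvalidBlockError",
    "NoValidCandidateError",
    "Frame",
    "Block",
    "BlockPyramid",
    "SearchWindow",
    "MatchResult",
    "sad",
    "build_block_pyramid",
    "sad_at_layer",
    "global_search",
    "bmp_search",
    "log_search",
]


class BlockMatchError(Exception):
    """Base class for block-matching errors."""


class SizeMismatchError(BlockMatchError):
    """Blocks or pyramids of incompatible shapes were compared."""


class InvalidBlockError(BlockMatchError):
    """A block violates its invariants (e.g. side not a power of two)."""


class NoValidCandidateError(BlockMatchError):
    """A search window contains no displacement keeping the block in-frame."""


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class Frame:
    """A single grayscale image with isotropic physical pixel spacing.

    Intensities may be on any nonnegative scale (raw scanner units or
    [0, 1] floats); SAD is computed on the values as given.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("Frame.pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("Frame.pixels must be finite")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Block:
    """A square power-of-two-sided patch cut from a frame.

    ``origin_rc`` is the (row, col) of the top-left pixel in the source
    frame; it is carried for bookkeeping and not used by :func:`sad`.
    """

    pixels: np.ndarray
    origin_rc: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise InvalidBlockError("block must be square")
        if not _is_power_of_two(px.shape[0]):
            raise InvalidBlockError(
                f"block side must be a power of two, got {px.shape[0]}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def from_frame(cls, frame: Frame, origin_rc: tuple[int, int], side: int) -> "Block":
        r, c = origin_rc
        if r < 0 or c < 0 or r + side > frame.height_px or c + side > frame.width_px:
            raise InvalidBlockError(
                f"block of side {side} at origin {origin_rc} does not fit in a "
                f"{frame.height_px}x{frame.width_px} frame"
            )
        return cls(frame.pixels[r : r + side, c : c + side], origin_rc)


@dataclass(frozen=True)
class BlockPyramid:
    """Sum-pooled multi-resolution representation of a block.

    ``layers[l]`` has side ``2^l``; ``layers[-1]`` is the original block and
    each coarser layer is the exact 2x2 sum-pool of the next finer one, so
    the single cell of layer 0 holds the sum of all block pixels.
    """

    layers: tuple[np.ndarray, ...]

    @property
    def depth(self) -> int:
        """M such that the finest layer has side 2^M."""
        return len(self.layers) - 1


def _pool2x2(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    return a.reshape(n // 2, 2, n // 2, 2).sum(axis=(1, 3))


def build_block_pyramid(b: Block) -> BlockPyramid:
    """Build the full sum-pool pyramid of a block (layer 0 = grand sum)."""
    layers = [b.pixels]
    while layers[-1].shape[0] > 1:
        layers.append(_pool2x2(layers[-1]))
    return BlockPyramid(tuple(reversed(layers)))


def sad(a: Block, b: Block) -> float:
    """Sum of absolute per-pixel differences between two equal-sided blocks."""
    if a.side != b.side:
        raise SizeMismatchError(f"block sides differ: {a.side} vs {b.side}")
    return float(np.abs(a.pixels - b.pixels).sum())


def sad_at_layer(pa: BlockPyramid, pb: BlockPyramid, layer: int) -> float:
    """SAD between the given layer of two pyramids of equal depth.

    Nondecreasing in ``layer``: each coarse value lower-bounds every finer
    one, which is what licenses pruning.
    """
    if pa.depth != pb.depth:
        raise SizeMismatchError(
            f"pyramid depths differ: {pa.depth} vs {pb.depth}"
        )
    if not 0 <= layer <= pa.depth:
        raise ValueError(f"layer {layer} outside [0, {pa.depth}]")
    return float(np.abs(pa.layers[layer] - pb.layers[layer]).sum())


@dataclass(frozen=True)
class SearchWindow:
    """Square set of candidate displacements around a predicted block origin.

    Candidates are all integer ``(dr, dc)`` with ``max(|dr|, |dc|) <=
    radius_px`` for which the displaced block stays inside the frame;
    out-of-frame candidates are excluded, not padded.
    """

    center_rc: tuple[int, int]
    radius_px: int

    def __post_init__(self) -> None:
        if self.radius_px < 0:
            raise ValueError("radius_px must be nonnegative")

    def bounds(self, block_side: int, frame_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Inclusive (dr_lo, dr_hi, dc_lo, dc_hi) of in-frame candidates.

        Raises :class:`NoValidCandidateError` when empty.
        """
        h, w = frame_shape
        r0, c0 = self.center_rc
        dr_lo = max(-self.radius_px, -r0)
        dr_hi = min(self.radius_px, h - block_side - r0)
        dc_lo = max(-self.radius_px, -c0)
        dc_hi = min(self.radius_px, w - block_side - c0)
        if dr_lo > dr_hi or dc_lo > dc_hi:
            raise NoValidCandidateError(
                f"no displacement keeps a side-{block_side} block inside a "
                f"{h}x{w} frame from origin {self.center_rc} at radius "
                f"{self.radius_px}"
            )
        return dr_lo, dr_hi, dc_lo, dc_hi


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one block match: best displacement, its finest-layer SAD,
    and search-cost counters."""

    displacement_rc: tuple[int, int]
    sad: float
    n_candidates_evaluated: int
    n_pruned: int = 0


def global_search(template: Block, frame: Frame, window: SearchWindow) -> MatchResult:
    """Exhaustive search: finest-layer SAD of every candidate.

    Returns the minimum-SAD displacement; ties resolve to the
    lexicographically smallest ``(dr, dc)``.
    """
    B = template.side
    dr_lo, dr_hi, dc_lo, dc_hi = window.bounds(B, frame.pixels.shape)
    r0, c0 = window.center_rc
    region = frame.pixels[r0 + dr_lo : r0 + dr_hi + B, c0 + dc_lo : c0 + dc_hi + B]
    windows = sliding_window_view(region, (B, B))
    sads = np.abs(windows - template.pixels).sum(axis=(2, 3))
    # np.argmin returns the first flat (row-major) minimum, which is exactly
    # the lexicographic (dr, dc) tie-break.
    idx = int(np.argmin(sads))
    n_dc = sads.shape[1]
    dr = dr_lo + idx // n_dc
    dc = dc_lo + idx % n_dc
    return MatchResult((dr, dc), float(sads.flat[idx]), sads.size, n_pruned=0)


def bmp_search(template: Block, frame: Frame, window: SearchWindow) -> MatchResult:
    """Pyramid-pruned search; identical optimum to :func:`global_search`.

    Each candidate is scored layer by layer from coarse to fine and
    abandoned as soon as a layer's SAD meets the best finest-layer SAD so
    far — legal because coarse SAD lower-bounds fine SAD.  ``n_pruned``
    counts candidates abandoned before the finest layer.
    """
    B = template.side
    dr_lo, dr_hi, dc_lo, dc_hi = window.bounds(B, frame.pixels.shape)
    r0, c0 = window.center_rc
    tpl = build_block_pyramid(template)
    M = tpl.depth

    best_d: tuple[int, int] | None = None
    best_sad = math.inf
    n_eval = 0
    n_pruned = 0
    for dr in range(dr_lo, dr_hi + 1):
        for dc in range(dc_lo, dc_hi + 1):
            r, c = r0 + dr, c0 + dc
            cand = Block(frame.pixels[r : r + B, c : c + B], (r, c))
            cpyr = build_block_pyramid(cand)
            n_eval += 1
            for layer in range(M + 1):
                s = sad_at_layer(tpl, cpyr, layer)
                if s >= best_sad:
                    if layer < M:
                        n_pruned += 1
                    break
            else:
                # strict improvement only: first minimum in lexicographic
                # order wins ties, matching global_search
                best_sad = s
                best_d = (dr, dc)
    if best_d is None:  # first candidate had sad == inf never happens; safety
        raise NoValidCandidateError("no candidate could be evaluated")
    return MatchResult(best_d, best_sad, n_eval, n_pruned)


def log_search(template: Block, frame: Frame, window: SearchWindow) -> MatchResult:
    """2-D logarithmic search: step-halving descent over a plus pattern.

    Starting from the window centre with step ``s = max(1, ceil(w/2))``, the
    centre and its 4 axial neighbours at distance ``s`` are scored; the
    search recentres on the minimum, halving the step whenever the centre
    wins; at ``s = 1`` the full 8-neighbourhood is scored and the search
    stops at a local minimum.  Evaluations are cached so no candidate is
    scored twice; on multimodal SAD surfaces the result may be a non-global
    local minimum.
    """
    B = template.side
    dr_lo, dr_hi, dc_lo, dc_hi = window.bounds(B, frame.pixels.shape)
    r0, c0 = window.center_rc
    tpl = template.pixels
    fpx = frame.pixels
    cache: dict[tuple[int, int], float] = {}

    def valid(d: tuple[int, int]) -> bool:
        return dr_lo <= d[0] <= dr_hi and dc_lo <= d[1] <= dc_hi

    def ev(d: tuple[int, int]) -> float:
        s = cache.get(d)
        if s is None:
            r, c = r0 + d[0], c0 + d[1]
            s = float(np.abs(fpx[r : r + B, c : c + B] - tpl).sum())
            cache[d] = s
        return s

    # start at the in-bounds displacement closest to zero
    center = (min(max(0, dr_lo), dr_hi), min(max(0, dc_lo), dc_hi))
    step = max(1, math.ceil(window.radius_px / 2))
    ev(center)

    while True:
        if step > 1:
            pattern = [(center[0] - step, center[1]), (center[0] + step, center[1]),
                       (center[0], center[1] - step), (center[0], center[1] + step)]
        else:
            pattern = [
                (center[0] + dr, center[1] + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            ]
        candidates = [d for d in pattern if valid(d)]
        # total order (sad, dr, dc): strict decrease on every move =>
        # termination, and the lexicographic tie-break of the other searches
        best = min(
            [(ev(center), *center)] + [(ev(d), *d) for d in candidates]
        )
        if (best[1], best[2]) != center:
            center = (best[1], best[2])
            continue
        if step > 1:
            step //= 2
        else:
            return MatchResult(center, cache[center], len(cache), n_pruned=0)
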
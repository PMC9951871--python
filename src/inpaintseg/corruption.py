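"""Corruption mask generation and application for inpainting pretext tasks.

Two pretext tasks are supported:

* **context prediction** -- square ``K x K`` patches of a (normalized) image
  are set to zero and the network reconstructs the original image;
* **context restoration** -- pairs of non-overlapping ``K x K`` patches are
  swapped, which corrupts spatial arrangement while exactly preserving the
  image's pixel-value distribution.

Patches are added iteratively until the number of corrupted pixels equals or
exceeds one quarter of the image area, so the amount of corruption per image
is fixed and comparable across patch sizes.  Patch anchors are drawn either
fully at random (overlaps allowed; corruption counted as the union of patch
pixels) or by Poisson-disc sampling, which keeps all patch centers at least
``K * sqrt(2)`` apart -- the smallest Euclidean center distance that
guarantees two axis-aligned ``K x K`` patches cannot overlap.

Masks are geometry only (image independent).  For efficiency a bank of base
masks is precomputed before training and augmented on the fly by quarter-turn
rotations; a bank of 100 base masks therefore provides 400 effective masks.

Anchor convention: ``(row, col)`` of the top-left corner, 0-based, patch
extent ``[r, r+K) x [c, c+K)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from numba import njit

__all__ = [
    "CorruptionError",
    "PredictionMask",
    "RestorationMask",
    "MaskBank",
    "sample_anchors_random",
    "sample_anchors_poisson",
    "build_prediction_mask",
    "build_restoration_mask",
    "apply_prediction",
    "apply_restoration",
    "apply_mask",
    "rotate_mask",
    "build_mask_bank",
    "draw_mask",
    "save_mask_bank",
    "load_mask_bank",
]

Task = Literal["prediction", "restoration"]
Sampler = Literal["random", "poisson"]

#: fraction of the image area that must be corrupted before patch placement stops
DEFAULT_AREA_FRACTION = 0.25


class CorruptionError(RuntimeError):
    """Raised when a corruption mask cannot be constructed."""


def _check_patch(image_shape: tuple[int, int], patch_size: int) -> None:
    h, w = image_shape
    if patch_size < 1:
        raise ValueError(f"patch_size must be >= 1, got {patch_size}")
    if patch_size > min(h, w):
        raise ValueError(
            f"patch_size {patch_size} exceeds smallest image dimension of {image_shape}"
        )


# ---------------------------------------------------------------------------
# mask types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionMask:
    """Context-prediction corruption geometry: patches whose pixels are zeroed.

    ``anchors`` may overlap (random sampler); ``covered`` is the union of all
    patch pixels.
    """

    patch_size: int
    anchors: tuple[tuple[int, int], ...]
    image_shape: tuple[int, int]

    @property
    def covered(self) -> np.ndarray:
        """Boolean grid of corrupted pixels (union of all patches)."""
        grid = np.zeros(self.image_shape, dtype=bool)
        k = self.patch_size
        for r, c in self.anchors:
            grid[r : r + k, c : c + k] = True
        return grid

    @property
    def n_covered(self) -> int:
        return int(np.count_nonzero(self.covered))

    @property
    def covered_fraction(self) -> float:
        return self.n_covered / (self.image_shape[0] * self.image_shape[1])


@dataclass(frozen=True)
class RestorationMask:
    """Context-restoration geometry: pairs of disjoint patches to be swapped."""

    patch_size: int
    pairs: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    image_shape: tuple[int, int]

    @property
    def anchors(self) -> tuple[tuple[int, int], ...]:
        return tuple(a for pair in self.pairs for a in pair)

    @property
    def covered(self) -> np.ndarray:
        grid = np.zeros(self.image_shape, dtype=bool)
        k = self.patch_size
        for r, c in self.anchors:
            grid[r : r + k, c : c + k] = True
        return grid

    @property
    def n_covered(self) -> int:
        return int(np.count_nonzero(self.covered))

    @property
    def covered_fraction(self) -> float:
        return self.n_covered / (self.image_shape[0] * self.image_shape[1])


@dataclass(frozen=True)
class MaskBank:
    """Precomputed corruption masks, augmented at draw time by quarter turns.

    The effective number of masks available during training is
    ``4 * len(base_masks)`` because each draw picks a base mask and one of the
    four rotations {0, 90, 180, 270} degrees uniformly at random.
    """

    task: Task
    sampler: Sampler
    patch_size: int
    image_shape: tuple[int, int]
    base_masks: tuple[PredictionMask | RestorationMask, ...] = field(repr=False)
    seed: int | None = None

    @property
    def effective_size(self) -> int:
        return 4 * len(self.base_masks)

    def __len__(self) -> int:
        return len(self.base_masks)


# ---------------------------------------------------------------------------
# anchor samplers
# ---------------------------------------------------------------------------

def sample_anchors_random(
    image_shape: tuple[int, int], patch_size: int, rng: np.random.Generator
) -> Iterator[tuple[int, int]]:
    """Yield an endless stream of patch anchors, uniform over all in-bounds
    positions ``[0, H-K] x [0, W-K]``."""
    _check_patch(image_shape, patch_size)
    h, w = image_shape
    k = patch_size
    while True:
        yield (int(rng.integers(0, h - k + 1)), int(rng.integers(0, w - k + 1)))


@njit(cache=True)
def _dart_throw(h, w, k, n_needed, max_darts, seed):  # pragma: no cover - numba
    """Rejection ("dart throwing") sampler for anchors whose centers are all
    at least k*sqrt(2) apart.  Returns (anchors, n_placed)."""
    np.random.seed(seed)
    rmax = h - k
    cmax = w - k
    # cell size k: any two anchors in the same cell are < k*sqrt(2) apart,
    # so each cell holds at most one accepted point; conflicts can only come
    # from cells within +-2 in each direction.
    gr = rmax // k + 1
    gc = cmax // k + 1
    grid = -np.ones((gr, gc), dtype=np.int64)
    pts = np.empty((n_needed, 2), dtype=np.int64)
    d2min = 2 * k * k
    count = 0
    for _ in range(max_darts):
        r = np.random.randint(0, rmax + 1)
        c = np.random.randint(0, cmax + 1)
        gi = r // k
        gj = c // k
        ok = True
        for i in range(max(0, gi - 2), min(gr, gi + 3)):
            for j in range(max(0, gj - 2), min(gc, gj + 3)):
                idx = grid[i, j]
                if idx >= 0:
                    dr = pts[idx, 0] - r
                    dc = pts[idx, 1] - c
                    if dr * dr + dc * dc < d2min:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            pts[count, 0] = r
            pts[count, 1] = c
            grid[gi, gj] = count
            count += 1
            if count == n_needed:
                break
    return pts, count


def sample_anchors_poisson(
    image_shape: tuple[int, int],
    patch_size: int,
    rng: np.random.Generator,
    n_anchors: int,
    max_restarts: int = 200,
) -> np.ndarray:
    """Sample ``n_anchors`` patch anchors by Poisson-disc dart throwing.

    All pairwise anchor (equivalently center) Euclidean distances are
    >= ``K * sqrt(2)``, which guarantees the patches are pairwise disjoint.
    Dart throwing can jam below the requested count when the packing is
    dense, so the sampler restarts from scratch with a fresh sub-seed up to
    ``max_restarts`` times before giving up.

    Raises
    ------
    CorruptionError
        If the requested number of disjoint patches could not be placed.
    """
    _check_patch(image_shape, patch_size)
    h, w = image_shape
    k = patch_size
    if k > min(h, w) / 3:
        raise ValueError(
            f"patch_size {k} too large for Poisson-disc quarter-area coverage on "
            f"{image_shape}; require K <= min(H, W) / 3"
        )
    max_darts = max(20_000, 300 * n_anchors)
    for _ in range(max_restarts):
        seed = int(rng.integers(0, 2**31 - 1))
        pts, count = _dart_throw(h, w, k, n_anchors, max_darts, seed)
        if count == n_anchors:
            return pts[:count].copy()
    raise CorruptionError(
        f"could not place {n_anchors} disjoint {k}x{k} patches on {image_shape} "
        f"after {max_restarts} dart-throwing restarts"
    )


# ---------------------------------------------------------------------------
# mask builders
# ---------------------------------------------------------------------------

def _n_disjoint_needed(image_shape, patch_size, per_step, area_fraction):
    """Number of placement steps so that (n-1) steps are below the area target
    and n steps meet or exceed it (disjoint patches; per_step patches each)."""
    target = area_fraction * image_shape[0] * image_shape[1]
    step_area = per_step * patch_size * patch_size
    return int(np.ceil(target / step_area))


def build_prediction_mask(
    image_shape: tuple[int, int],
    patch_size: int,
    sampler: Sampler,
    rng: np.random.Generator,
    area_fraction: float = DEFAULT_AREA_FRACTION,
) -> PredictionMask:
    """Place K x K patches iteratively until the union of corrupted pixels
    equals or exceeds ``area_fraction`` (default 1/4) of the image area.

    With the random sampler patches may overlap and coverage is counted as the
    union; with the Poisson-disc sampler all patches are disjoint.  The last
    placed patch is the one that first meets the target, so the corrupted
    fraction is always < ``area_fraction + K^2 / (H * W)``.
    """
    _check_patch(image_shape, patch_size)
    h, w = image_shape
    k = patch_size
    target = area_fraction * h * w
    if sampler == "poisson":
        n = _n_disjoint_needed(image_shape, k, 1, area_fraction)
        pts = sample_anchors_poisson(image_shape, k, rng, n)
        anchors = tuple((int(r), int(c)) for r, c in pts)
        return PredictionMask(k, anchors, image_shape)
    if sampler != "random":
        raise ValueError(f"unknown sampler {sampler!r}")
    covered = np.zeros(image_shape, dtype=bool)
    count = 0
    anchors: list[tuple[int, int]] = []
    for r, c in sample_anchors_random(image_shape, k, rng):
        block = covered[r : r + k, c : c + k]
        count += k * k - int(np.count_nonzero(block))
        block[:] = True
        anchors.append((r, c))
        if count >= target:
            break
    return PredictionMask(k, tuple(anchors), image_shape)


def build_restoration_mask(
    image_shape: tuple[int, int],
    patch_size: int,
    sampler: Sampler,
    rng: np.random.Generator,
    area_fraction: float = DEFAULT_AREA_FRACTION,
) -> RestorationMask:
    """Select pairs of non-overlapping K x K patches iteratively until the
    union of corrupted pixels equals or exceeds ``area_fraction`` of the image.

    The two patches of a pair are always disjoint.  With the random sampler
    different pairs may overlap each other (coverage is the union); with the
    Poisson-disc sampler all patches across all pairs are disjoint and the
    sampled anchors are paired randomly.
    """
    _check_patch(image_shape, patch_size)
    h, w = image_shape
    k = patch_size
    target = area_fraction * h * w
    if sampler == "poisson":
        n_pairs = _n_disjoint_needed(image_shape, k, 2, area_fraction)
        pts = sample_anchors_poisson(image_shape, k, rng, 2 * n_pairs)
        order = rng.permutation(2 * n_pairs)
        pairs = tuple(
            (
                (int(pts[order[2 * i], 0]), int(pts[order[2 * i], 1])),
                (int(pts[order[2 * i + 1], 0]), int(pts[order[2 * i + 1], 1])),
            )
            for i in range(n_pairs)
        )
        return RestorationMask(k, pairs, image_shape)
    if sampler != "random":
        raise ValueError(f"unknown sampler {sampler!r}")
    covered = np.zeros(image_shape, dtype=bool)
    count = 0
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    stream = sample_anchors_random(image_shape, k, rng)
    while count < target:
        # redraw until the two patches of the pair are disjoint
        while True:
            a = next(stream)
            b = next(stream)
            if abs(a[0] - b[0]) >= k or abs(a[1] - b[1]) >= k:
                break
        for r, c in (a, b):
            block = covered[r : r + k, c : c + k]
            count += k * k - int(np.count_nonzero(block))
            block[:] = True
        pairs.append((a, b))
    return RestorationMask(k, tuple(pairs), image_shape)


# ---------------------------------------------------------------------------
# corruption application
# ---------------------------------------------------------------------------

def _check_image(image: np.ndarray, mask) -> None:
    if image.ndim not in (2, 3):
        raise ValueError(f"expected (H, W) or (C, H, W) image, got shape {image.shape}")
    if tuple(image.shape[-2:]) != tuple(mask.image_shape):
        raise ValueError(
            f"image spatial shape {image.shape[-2:]} does not match mask shape {mask.image_shape}"
        )


def apply_prediction(image: np.ndarray, mask: PredictionMask) -> np.ndarray:
    """Zero the masked pixels of a normalized image (all channels alike)."""
    _check_image(image, mask)
    out = image.copy()
    out[..., mask.covered] = 0
    return out


def apply_restoration(image: np.ndarray, mask: RestorationMask) -> np.ndarray:
    """Swap each pair of patches; the pixel-value multiset of the image is
    exactly preserved.  The same spatial swap is applied to every channel."""
    _check_image(image, mask)
    out = image.copy()
    k = mask.patch_size
    for (r1, c1), (r2, c2) in mask.pairs:
        block1 = out[..., r1 : r1 + k, c1 : c1 + k].copy()
        out[..., r1 : r1 + k, c1 : c1 + k] = out[..., r2 : r2 + k, c2 : c2 + k]
        out[..., r2 : r2 + k, c2 : c2 + k] = block1
    return out


def apply_mask(image: np.ndarray, mask: PredictionMask | RestorationMask) -> np.ndarray:
    """Apply either corruption type based on the mask's type."""
    if isinstance(mask, PredictionMask):
        return apply_prediction(image, mask)
    if isinstance(mask, RestorationMask):
        return apply_restoration(image, mask)
    raise TypeError(f"unknown mask type {type(mask)!r}")


# ---------------------------------------------------------------------------
# rotation augmentation and mask banks
# ---------------------------------------------------------------------------

def _rotate_anchor(anchor, quarter_turns, image_shape, k):
    """Rotate a patch anchor counter-clockwise by 90-degree steps.

    Derived from ``out[i, j] = in[j, W-1-i]`` (numpy rot90): a patch with
    rows [r, r+K) and cols [c, c+K) maps under one CCW turn to anchor
    ``(W - c - K, r)``.
    """
    h, w = image_shape
    r, c = anchor
    for _ in range(quarter_turns % 4):
        r, c = w - c - k, r
        h, w = w, h
    return (int(r), int(c))


def rotate_mask(
    mask: PredictionMask | RestorationMask, quarter_turns: int
) -> PredictionMask | RestorationMask:
    """Rotate a mask counter-clockwise by ``quarter_turns`` * 90 degrees.

    Coverage count and all geometric invariants are preserved; 0 and 180
    degree turns are valid for any shape, 90/270 require a square image.
    """
    if quarter_turns % 4 in (1, 3) and mask.image_shape[0] != mask.image_shape[1]:
        raise ValueError(
            f"90/270 degree mask rotation requires a square image, got {mask.image_shape}"
        )
    q = quarter_turns % 4
    if q == 0:
        return mask
    k = mask.patch_size
    if isinstance(mask, PredictionMask):
        anchors = tuple(_rotate_anchor(a, q, mask.image_shape, k) for a in mask.anchors)
        return PredictionMask(k, anchors, mask.image_shape)
    pairs = tuple(
        (
            _rotate_anchor(a, q, mask.image_shape, k),
            _rotate_anchor(b, q, mask.image_shape, k),
        )
        for a, b in mask.pairs
    )
    return RestorationMask(k, pairs, mask.image_shape)


def build_mask_bank(
    task: Task,
    sampler: Sampler,
    patch_size: int,
    image_shape: tuple[int, int],
    n_base: int = 100,
    rng: np.random.Generator | int | None = None,
    area_fraction: float = DEFAULT_AREA_FRACTION,
) -> MaskBank:
    """Precompute ``n_base`` corruption masks (default 100, i.e. 400 effective
    masks under rotation augmentation).  Deterministic given a seed."""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    builder = build_prediction_mask if task == "prediction" else build_restoration_mask
    if task not in ("prediction", "restoration"):
        raise ValueError(f"unknown task {task!r}")
    masks = tuple(
        builder(image_shape, patch_size, sampler, rng, area_fraction)
        for _ in range(n_base)
    )
    return MaskBank(task, sampler, patch_size, tuple(image_shape), masks,
                    seed=None if seed is None else int(seed))


def draw_mask(bank: MaskBank, rng: np.random.Generator) -> PredictionMask | RestorationMask:
    """Draw one mask: uniform base-mask choice x uniform quarter-turn."""
    if len(bank.base_masks) == 0:
        raise ValueError("cannot draw from an empty mask bank")
    idx = int(rng.integers(0, len(bank.base_masks)))
    turns = int(rng.integers(0, 4))
    return rotate_mask(bank.base_masks[idx], turns)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _mask_to_obj(mask) -> dict:
    if isinstance(mask, PredictionMask):
        return {"anchors": [list(a) for a in mask.anchors]}
    return {"pairs": [[list(a), list(b)] for a, b in mask.pairs]}


def save_mask_bank(bank: MaskBank, path) -> None:
    """Serialize a bank to a single JSON archive; reload is bit-exact."""
    obj = {
        "task": bank.task,
        "sampler": bank.sampler,
        "patch_size": bank.patch_size,
        "image_shape": list(bank.image_shape),
        "seed": bank.seed,
        "masks": [_mask_to_obj(m) for m in bank.base_masks],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_mask_bank(path) -> MaskBank:
    with open(path) as fh:
        obj = json.load(fh)
    shape = tuple(obj["image_shape"])
    k = obj["patch_size"]
    masks = []
    for m in obj["masks"]:
        if "anchors" in m:
            masks.append(
                PredictionMask(k, tuple((int(r), int(c)) for r, c in m["anchors"]), shape)
            )
        else:
            masks.append(
                RestorationMask(
                    k,
                    tuple(
                        ((int(a[0]), int(a[1])), (int(b[0]), int(b[1])))
                        for a, b in m["pairs"]
                    ),
                    shape,
                )
            )
    return MaskBank(obj["task"], obj["sampler"], k, shape, tuple(masks), seed=obj["seed"])
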
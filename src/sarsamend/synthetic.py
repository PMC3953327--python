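"""EM-like phantom generation with exact ground truth.

Real ssTEM sections show bright cytoplasm compartments bounded by dark
membranes, with intracellular organelles (mitochondria etc.) appearing
as dark blobs and substantial acquisition noise. The phantoms emulate
exactly those features: a Voronoi partition of the canvas stands in for
the cell mosaic, its ridges are rendered as dark membranes of
controllable width, elliptical clutter blobs are dropped strictly inside
cells, and additive Gaussian noise is applied last. Because the
generator knows the partition, it returns a pixel-exact membrane
centerline and region labelling alongside the image, and can degrade
the centerline with controlled gaps for amendment experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = ["PhantomSpec", "GapRecord", "generate_phantom", "inject_gaps"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic EM phantom.

    clutter_density is in blobs per 1000 px^2; noise_sigma is the std of
    the additive Gaussian noise on the [0, 1] intensity scale.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 12
    membrane_width: int = 3
    membrane_darkness: float = 0.6
    clutter_density: float = 0.15
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.membrane_width < 1:
            raise ValueError("membrane_width must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class GapRecord:
    """Bookkeeping for one injected gap."""

    curve_id: int
    removed: tuple[tuple[int, int], ...]
    length: int
    endpoints_created: tuple[tuple[int, int], ...]


_BACKGROUND = 0.85
_CLUTTER_DROP = 0.35


def _place_seeds(rng: np.random.Generator, shape, n_cells: int) -> np.ndarray:
    """Uniform seed points with a minimum-separation rejection rule."""
    h, w = shape
    min_sep = 0.5 * np.sqrt(h * w / n_cells)
    pts: list[tuple[float, float]] = []
    for _ in range(2000 * n_cells):
        cand = (rng.uniform(0, h), rng.uniform(0, w))
        if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep for p in pts):
            pts.append(cand)
            if len(pts) == n_cells:
                return np.asarray(pts)
    raise ValueError(f"cannot place {n_cells} cells with separation {min_sep:.1f} on {shape}")


def _skeleton_with_border(membrane: np.ndarray, pad: int) -> np.ndarray:
    """Thin the membrane band to a centerline that still reaches the border.

    Thinning retracts line ends, so a membrane that terminates at the
    canvas edge would lose its border contact and stop separating its
    two cells. The mask is replicate-padded before thinning so the
    retraction happens outside the crop.
    """
    padded = np.pad(membrane, pad, mode="edge")
    skel = skeletonize(padded)
    return skel[pad:-pad, pad:-pad]


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one phantom; returns (image, truth boundary map, labels).

    The truth map is the 1-px (8-connected) membrane centerline; labels
    assign each cell a positive region ID and 0 to centerline pixels.
    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    if h * w < 64 * spec.n_cells:  # cells below ~8x8 px cannot carry membranes
        raise ValueError(
            f"canvas {spec.shape} cannot fit {spec.n_cells} cells of >= 64 px^2"
        )
    seeds = _place_seeds(rng, spec.shape, spec.n_cells)

    rows, cols = np.mgrid[0:h, 0:w]
    d = np.hypot(rows[..., None] - seeds[:, 0], cols[..., None] - seeds[:, 1])
    labels = np.argmin(d, axis=-1) + 1
    if spec.n_cells > 1:
        # membrane core: one pixel per label change, grown to a
        # constant-width band by a distance transform (real membranes
        # keep their width regardless of orientation)
        core = np.zeros((h, w), dtype=bool)
        core[:-1, :] |= labels[:-1, :] != labels[1:, :]
        core[:, :-1] |= labels[:, :-1] != labels[:, 1:]
        membrane = ndimage.distance_transform_edt(~core) <= (spec.membrane_width - 1) / 2
    else:
        membrane = np.zeros((h, w), dtype=bool)

    img = np.full((h, w), _BACKGROUND)
    img[membrane] = _BACKGROUND - spec.membrane_darkness

    n_blobs = rng.poisson(spec.clutter_density * h * w / 1000.0)
    if spec.n_cells > 1:
        interior = ndimage.distance_transform_edt(~membrane) > 2.0 * spec.membrane_width
    else:
        interior = np.ones((h, w), dtype=bool)
    interior_px = np.argwhere(interior)
    for _ in range(n_blobs):
        if interior_px.size == 0:
            break
        cy, cx = interior_px[rng.integers(len(interior_px))]
        ax_a = rng.uniform(1.5, 4.5)
        ax_b = rng.uniform(1.5, 4.5)
        phi = rng.uniform(0, np.pi)
        rr = rows - cy
        cc = cols - cx
        u = rr * np.cos(phi) + cc * np.sin(phi)
        v = -rr * np.sin(phi) + cc * np.cos(phi)
        blob = (u / ax_a) ** 2 + (v / ax_b) ** 2 <= 1.0
        img[blob & interior] -= _CLUTTER_DROP

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    if spec.n_cells > 1:
        truth = _skeleton_with_border(membrane, pad=max(4, 2 * spec.membrane_width))
    else:
        truth = np.zeros((h, w), dtype=bool)
    out_labels = labels.astype(np.int32)
    out_labels[truth] = 0
    return img, truth, out_labels


_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _degree(b: np.ndarray) -> np.ndarray:
    return ndimage.convolve(b.astype(np.int32), _NEIGH_KERNEL, mode="constant", cval=0)


def _walk_run(b, deg, start, length) -> list[tuple[int, int]] | None:
    """Collect a run of ``length`` consecutive degree-2 curve pixels around start."""
    run = [start]
    # grow alternately in the two directions from start
    frontier = [start, start]
    prev = [None, None]
    direction = 0
    while len(run) < length:
        progressed = False
        for direction in (0, 1):
            if len(run) >= length:
                break
            r, c = frontier[direction]
            nbrs = [
                (r + dr, c + dc)
                for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr or dc)
                and 0 <= r + dr < b.shape[0] and 0 <= c + dc < b.shape[1]
                and b[r + dr, c + dc]
                and (r + dr, c + dc) not in run
                and (r + dr, c + dc) != prev[direction]
            ]
            nbrs = [p for p in nbrs if deg[p] == 2]
            if not nbrs:
                continue
            nxt = nbrs[0]
            prev[direction] = frontier[direction]
            frontier[direction] = nxt
            run.append(nxt)
            progressed = True
        if not progressed:
            return None
    return run


def inject_gaps(boundary_map, n_gaps: int, length_range: tuple[int, int],
                seed: int = 0) -> tuple[np.ndarray, list[GapRecord]]:
    """Remove ``n_gaps`` disjoint runs of curve pixels from a boundary map.

    Gap lengths are drawn uniformly from ``length_range`` (inclusive);
    removed runs consist of interior curve pixels only (every removed
    pixel and both flanking pixels have exactly 2 marked neighbours, so
    each gap creates exactly 2 new endpoints) and distinct gaps keep at
    least 5 px apart. Deterministic per seed; raises when the map cannot
    host the requested gaps.
    """
    rng = np.random.default_rng(seed)
    b = (np.asarray(boundary_map) != 0).copy()
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length range")
    comp_labels, _ = ndimage.label(b, structure=np.ones((3, 3)))
    deg = _degree(b)
    candidates = np.argwhere(b & (deg == 2))
    if candidates.size == 0 and n_gaps > 0:
        raise ValueError("no candidate gap sites in map")
    records: list[GapRecord] = []
    removed_all: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 500 * max(n_gaps, 1)
    while len(records) < n_gaps:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could only place {len(records)} of {n_gaps} gaps after {attempts} attempts"
            )
        start = tuple(candidates[rng.integers(len(candidates))])
        length = int(rng.integers(lo, hi + 1))
        run = _walk_run(b, deg, start, length)
        if run is None:
            continue
        # flanking keepers must become clean endpoints
        flanks = _run_flanks(b, run)
        if flanks is None or any(deg[f] != 2 for f in flanks):
            continue
        if removed_all and _min_dist(run, removed_all) < 5.0:
            continue
        for p in run:
            b[p] = False
        removed_all.extend(run)
        records.append(
            GapRecord(
                curve_id=int(comp_labels[start]),
                removed=tuple((int(r), int(c)) for r, c in run),
                length=len(run),
                endpoints_created=tuple((int(r), int(c)) for r, c in flanks),
            )
        )
        deg = _degree(b)
        candidates = np.argwhere(b & (deg == 2))
    return b, records


def _run_flanks(b, run) -> tuple[tuple[int, int], tuple[int, int]] | None:
    run_set = set(run)
    flanks = []
    for r, c in run:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                p = (r + dr, c + dc)
                if (dr or dc) and 0 <= p[0] < b.shape[0] and 0 <= p[1] < b.shape[1] \
                        and b[p] and p not in run_set and p not in flanks:
                    flanks.append(p)
    if len(flanks) != 2:
        return None
    return flanks[0], flanks[1]


def _min_dist(run, existing) -> float:
    ra = np.asarray(run, dtype=float)
    ea = np.asarray(existing, dtype=float)
    d = np.hypot(ra[:, None, 0] - ea[None, :, 0], ra[:, None, 1] - ea[None, :, 1])
    return float(d.min())
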
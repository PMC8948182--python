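"""Synthetic contact maps with planted stripes and loops.

The generator emulates the universal features of cis contact data that the
detector relies on: a power-law distance decay of contact frequency,
Poisson count noise at a controllable depth, vertical/horizontal stripes
anchored on the diagonal (variable width, length, enhancement and row
continuity), and focal loops (corner dots) as negative controls.  All
randomness is seed-deterministic.

Planting operates on the noise-free expectation matrix; Poisson noise, if
requested, is applied once at realization time (``apply_noise``), so the
planted enhancement factors act multiplicatively on the expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

from .contact_io import ContactMatrix

__all__ = [
    "SyntheticMapSpec",
    "StripeTruth",
    "LoopTruth",
    "RecoveryMetrics",
    "generate_background",
    "plant_stripe",
    "plant_loop",
    "apply_noise",
    "build_scene",
    "benchmark_scene",
    "evaluate_recovery",
    "write_cooler",
    "write_dense_tsv",
]


@dataclass
class SyntheticMapSpec:
    """Parameters of a synthetic cis contact map.

    ``base_intensity`` is the expected count at the diagonal; at offset d
    the expectation decays as ``base_intensity * (d+1)**(-alpha)``.  The
    default depth (100 counts at the diagonal, ~50 at offset 1) keeps the
    near-diagonal region well above 20 counts/pixel, i.e. a deeply
    sequenced library at the chosen resolution.
    """

    n_bins: int = 2000
    resolution: int = 10_000
    alpha: float = 1.0
    base_intensity: float = 100.0
    noise: str = "poisson"  # 'poisson' or 'none'
    chromosome: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


@dataclass
class StripeTruth:
    """Ground truth of one planted stripe (bin coordinates)."""

    orientation: str  # '5p' or '3p'
    anchor_start: int
    anchor_end: int  # half-open
    domain_length: int
    enhancement: float = 6.0
    continuity: float = 1.0

    def __post_init__(self) -> None:
        if self.enhancement < 1:
            raise ValueError("enhancement must be >= 1 (1 = no-op)")
        if not (0.0 < self.continuity <= 1.0):
            raise ValueError("continuity must lie in (0, 1]")

    @property
    def domain(self) -> tuple:
        if self.orientation == "5p":
            return (self.anchor_start, self.anchor_start + self.domain_length)
        return (self.anchor_end - self.domain_length, self.anchor_end)


@dataclass
class LoopTruth:
    """Ground truth of one planted loop (corner dot)."""

    anchor1: int
    anchor2: int
    enhancement: float = 6.0
    radius: float = 2.0


@dataclass
class RecoveryMetrics:
    recall: float
    precision: float
    matched: list  # per-truth matched flag
    n_predictions: int


def _expectation(spec: SyntheticMapSpec) -> np.ndarray:
    d = np.abs(np.arange(spec.n_bins)[:, None] - np.arange(spec.n_bins)[None, :])
    return spec.base_intensity * (d + 1.0) ** (-spec.alpha)


def generate_background(spec: SyntheticMapSpec) -> ContactMatrix:
    """Decay-only background, realized under ``spec.noise``."""
    m = ContactMatrix(
        chromosome=spec.chromosome,
        resolution=spec.resolution,
        values=_expectation(spec),
        norm_tag="raw",
    )
    if spec.noise == "poisson":
        m = apply_noise(m, seed=spec.seed)
    return m


def _stripe_mask(t: StripeTruth, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    d_lo, d_hi = t.domain
    if not (0 <= t.anchor_start < t.anchor_end <= n_bins and 0 <= d_lo and d_hi <= n_bins):
        raise ValueError("stripe truth outside matrix bounds")
    rows = np.arange(d_lo, d_hi)
    if t.continuity < 1.0:
        k = max(1, round(t.continuity * rows.size))
        rows = np.sort(rng.choice(rows, size=k, replace=False))
    mask = np.zeros((n_bins, n_bins), dtype=bool)
    for c in range(t.anchor_start, t.anchor_end):
        mask[rows, c] = True
        mask[c, rows] = True
    return mask


def plant_stripe(
    m: ContactMatrix,
    t: StripeTruth,
    rng: np.random.Generator | None = None,
    occupied: np.ndarray | None = None,
) -> ContactMatrix:
    """Multiply the expectation by the enhancement over the stripe body.

    ``m`` must be a noise-free expectation matrix.  When an ``occupied``
    mask is passed, overlap with a previously planted feature raises and
    the mask is updated in place.
    """
    rng = rng or np.random.default_rng(0)
    mask = _stripe_mask(t, m.n_bins, rng)
    if occupied is not None:
        if np.any(occupied & mask):
            raise ValueError("planted stripe overlaps an existing feature")
        occupied |= mask
    out = m.values.copy()
    out[mask] *= t.enhancement
    return replace(m, values=out)


def plant_loop(
    m: ContactMatrix,
    t: LoopTruth,
    occupied: np.ndarray | None = None,
) -> ContactMatrix:
    """Plant a Gaussian corner dot of peak factor f at (a1, a2) and mirror.

    The multiplicative profile is truncated beyond 4*radius, so far-field
    pixels are exactly unchanged.
    """
    n = m.n_bins
    a, b = t.anchor1, t.anchor2
    if not (0 <= a < n and 0 <= b < n) or a == b:
        raise ValueError("loop anchors must be distinct and within bounds")
    rad = int(np.ceil(4 * t.radius))
    r = np.arange(max(a - rad, 0), min(a + rad + 1, n))
    c = np.arange(max(b - rad, 0), min(b + rad + 1, n))
    rr, cc = np.meshgrid(r, c, indexing="ij")
    dist2 = (rr - a) ** 2 + (cc - b) ** 2
    bump = 1.0 + (t.enhancement - 1.0) * np.exp(-dist2 / (2.0 * t.radius**2))
    bump[dist2 > (4 * t.radius) ** 2] = 1.0
    if occupied is not None:
        touched = np.zeros((n, n), dtype=bool)
        touched[np.ix_(r, c)] = bump > 1.0
        touched[np.ix_(c, r)] |= (bump > 1.0).T
        if np.any(occupied & touched):
            raise ValueError("planted loop overlaps an existing feature")
        occupied |= touched
    out = m.values.copy()
    out[np.ix_(r, c)] *= bump
    out[np.ix_(c, r)] *= bump.T
    return replace(m, values=out)


def apply_noise(m: ContactMatrix, seed: int = 0) -> ContactMatrix:
    """Poisson-sample the upper triangle of the expectation and mirror it."""
    rng = np.random.default_rng(seed)
    n = m.n_bins
    iu = np.triu_indices(n)
    counts = rng.poisson(m.values[iu]).astype(float)
    out = np.zeros_like(m.values)
    out[iu] = counts
    out.T[iu] = counts
    return replace(m, values=out)


def build_scene(
    spec: SyntheticMapSpec,
    stripes: list[StripeTruth] = (),
    loops: list[LoopTruth] = (),
) -> tuple[ContactMatrix, list[StripeTruth], list[LoopTruth]]:
    """Background + planted features, realized under ``spec.noise``."""
    rng = np.random.default_rng(spec.seed)
    m = ContactMatrix(spec.chromosome, spec.resolution, _expectation(spec), norm_tag="raw")
    occupied = np.zeros((spec.n_bins, spec.n_bins), dtype=bool)
    for t in stripes:
        m = plant_stripe(m, t, rng=rng, occupied=occupied)
    for t in loops:
        m = plant_loop(m, t, occupied=occupied)
    if spec.noise == "poisson":
        m = apply_noise(m, seed=spec.seed)
    return m, list(stripes), list(loops)


#: the repository's standard end-to-end scene: three 5' stripes, two 3'
#: stripes (enhancement x6, full continuity) and three loops on a 2000-bin
#: chromosome at 10 kb.
BENCHMARK_STRIPES = (
    StripeTruth("5p", 200, 203, 60, 6.0, 1.0),
    StripeTruth("5p", 700, 702, 40, 6.0, 1.0),
    StripeTruth("5p", 1200, 1204, 80, 6.0, 1.0),
    StripeTruth("3p", 450, 453, 50, 6.0, 1.0),
    StripeTruth("3p", 1650, 1652, 45, 6.0, 1.0),
)
BENCHMARK_LOOPS = (
    LoopTruth(300, 340, 6.0, 2.0),
    LoopTruth(900, 950, 6.0, 2.0),
    LoopTruth(1400, 1460, 6.0, 2.0),
)


def benchmark_scene(seed: int = 0, noise: str = "poisson"):
    """The default benchmark scene, realized at the given seed."""
    spec = SyntheticMapSpec(n_bins=2000, resolution=10_000, noise=noise, seed=seed)
    return build_scene(spec, list(BENCHMARK_STRIPES), list(BENCHMARK_LOOPS))


def evaluate_recovery(predicted, truths: list[StripeTruth], tol_bins: int = 3) -> RecoveryMetrics:
    """Match predictions to planted stripes by anchor overlap.

    A prediction matches a truth when orientations agree and the anchor
    intervals overlap once the truth anchor is padded by ``tol_bins``.
    Matching is greedy by overlap size; each truth takes at most one
    prediction.  With zero predictions, precision is reported as 1.
    """
    preds = list(predicted)
    matched = [False] * len(truths)
    used = [False] * len(preds)
    pairs = []
    for ti, t in enumerate(truths):
        lo, hi = t.anchor_start - tol_bins, t.anchor_end + tol_bins
        for pi, p in enumerate(preds):
            c = p.stripe if hasattr(p, "stripe") else p
            if c.orientation != t.orientation:
                continue
            ov = min(hi, c.anchor[1]) - max(lo, c.anchor[0])
            if ov > 0:
                pairs.append((ov, ti, pi))
    for _, ti, pi in sorted(pairs, key=lambda x: (-x[0], x[1], x[2])):
        if not matched[ti] and not used[pi]:
            matched[ti] = True
            used[pi] = True
    n_match = sum(matched)
    recall = n_match / len(truths) if truths else 1.0
    precision = sum(used) / len(preds) if preds else 1.0
    return RecoveryMetrics(recall=recall, precision=precision, matched=matched, n_predictions=len(preds))


def write_cooler(m: ContactMatrix, path, multires: bool = False) -> None:
    """Write a matrix in the cooler HDF5 layout (.cool, or .mcool group).

    Stores the upper triangle (including the diagonal) as a pixel table;
    integral matrices are stored with an integer count dtype.  Reading the
    file back through ``read_contact_matrix`` reproduces the matrix
    exactly.
    """
    n = m.n_bins
    iu = np.triu_indices(n)
    v = m.values[iu]
    nz = v != 0
    b1, b2, counts = iu[0][nz], iu[1][nz], v[nz]
    integral = np.all(counts == np.rint(counts))
    with h5py.File(path, "w") as f:
        root = f.create_group(f"resolutions/{m.resolution}") if multires else f
        root.attrs["format"] = "HDF5::Cooler"
        root.attrs["format-version"] = 3
        root.attrs["bin-size"] = m.resolution
        root.attrs["bin-type"] = "fixed"
        chroms = root.create_group("chroms")
        chroms.create_dataset("name", data=np.array([m.chromosome.encode()], dtype="S32"))
        chroms.create_dataset("length", data=np.array([m.bin_start + n * m.resolution], dtype=np.int64))
        starts = m.bin_start + np.arange(n, dtype=np.int64) * m.resolution
        bins = root.create_group("bins")
        bins.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        bins.create_dataset("start", data=starts)
        bins.create_dataset("end", data=starts + m.resolution)
        pixels = root.create_group("pixels")
        pixels.create_dataset("bin1_id", data=b1.astype(np.int64))
        pixels.create_dataset("bin2_id", data=b2.astype(np.int64))
        pixels.create_dataset(
            "count", data=counts.astype(np.int64) if integral else counts
        )
        indexes = root.create_group("indexes")
        indexes.create_dataset("chrom_offset", data=np.array([0, n], dtype=np.int64))
        bin1_offset = np.searchsorted(b1, np.arange(n + 1))
        indexes.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))


def write_dense_tsv(m: ContactMatrix, path) -> None:
    """Plain dense-matrix text dump for debugging."""
    np.savetxt(path, m.values, delimiter="\t", fmt="%.10g")
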
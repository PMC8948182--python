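"""Candidate stripe search on edge maps.

Vertical stripe borders appear in Canny edge maps of contact-map images as
long vertical lines.  This module filters edge pixels by gradient
orientation, assembles gap-tolerant vertical runs, refines and pairs them
into candidate stripes, and merges duplicates found across overlapping
windows and rendering parameters.

Orientation convention: the Sobel response of the binary edge map is
summarized as the edge-tangent angle theta = arctan2(G_x, G_y) folded to
[0, 180), so that the flanking columns of a vertical line score exactly
90 degrees along the line's whole length.  The retained pixels (which sit
one column to the right of the true border) are shifted one column left,
and line refinement against the original edge map removes the spurious
left-flank copy.  This is the only reading under which the documented
one-column reflection, the left shift, and the refinement step act
together coherently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .contact_io import ContactMatrix, BinIndexMap
from .image_pipeline import EdgeMap, edge_stack, positive_quantile_thresholds

__all__ = [
    "WindowSpan",
    "VerticalLineSegment",
    "RefinedLine",
    "CandidateStripe",
    "sliding_windows",
    "orientation_filter",
    "find_vertical_runs",
    "refine_lines",
    "extend_to_diagonal",
    "pair_lines",
    "merge_candidates",
    "detect_stripes",
]

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


@dataclass(frozen=True)
class WindowSpan:
    """Half-open bin span of one diagonal window."""

    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class VerticalLineSegment:
    """A gap-tolerant vertical run of edge pixels (rows strictly increasing)."""

    pixels: list  # [(row, col), ...]
    gap_count: int = 0

    @property
    def top(self) -> int:
        return self.pixels[0][0]

    @property
    def bottom(self) -> int:
        return self.pixels[-1][0]

    @property
    def span(self) -> int:
        return self.bottom - self.top + 1

    @property
    def mean_col(self) -> float:
        return float(np.mean([c for _, c in self.pixels]))


@dataclass
class RefinedLine:
    """A grouped, refined vertical line with its representative column."""

    col: int
    top: int
    bottom: int
    n_pixels: int


@dataclass
class CandidateStripe:
    """A paired-edge stripe candidate in chromosome bin coordinates.

    ``anchor`` is the half-open bin interval of the stripe base on the
    diagonal; ``domain`` the half-open bin interval it contacts.  For a 5'
    stripe the anchor coincides with the domain's low end, for a 3' stripe
    with its high end.
    """

    chromosome: str
    orientation: str  # '5p' or '3p'
    anchor: tuple  # (start_bin, end_bin)
    domain: tuple  # (start_bin, end_bin)
    resolution: int
    bin_start: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def width_bins(self) -> int:
        return self.anchor[1] - self.anchor[0]

    @property
    def length_bins(self) -> int:
        return self.domain[1] - self.domain[0]

    @property
    def anchor_bp(self) -> tuple:
        return (
            self.bin_start + self.anchor[0] * self.resolution,
            self.bin_start + self.anchor[1] * self.resolution,
        )

    @property
    def domain_bp(self) -> tuple:
        return (
            self.bin_start + self.domain[0] * self.resolution,
            self.bin_start + self.domain[1] * self.resolution,
        )


def sliding_windows(n_bins: int, window: int = 400, step: int = 200) -> list[WindowSpan]:
    """Diagonal windows covering [0, n_bins); the last ends exactly at n_bins."""
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if n_bins <= window:
        return [WindowSpan(0, n_bins)]
    starts = list(range(0, n_bins - window + 1, step))
    if starts[-1] + window < n_bins:
        starts.append(n_bins - window)
    return [WindowSpan(s, s + window) for s in starts]


def orientation_filter(e: EdgeMap) -> EdgeMap:
    """Retain near-vertical structure and shift one column left.

    The 3x3 Sobel kernels are correlated with the binary edge matrix; a
    pixel is retained when its edge-tangent angle (folded to [0, 180))
    lies in [60, 120] and the gradient is not identically zero.  Retained
    pixels sit on the columns flanking a vertical line, one column to the
    right (and left) of it; the final one-column left shift places the
    right-flank response onto the true border column.
    """
    E = e.edges.astype(float)
    gx = ndimage.correlate(E, SOBEL_X, mode="constant")
    gy = ndimage.correlate(E, SOBEL_Y, mode="constant")
    theta = np.degrees(np.arctan2(gx, gy)) % 180.0
    keep = (theta >= 60.0) & (theta <= 120.0) & ~((gx == 0) & (gy == 0))
    shifted = np.zeros_like(keep)
    shifted[:, :-1] = keep[:, 1:]
    return EdgeMap(edges=shifted)


def find_vertical_runs(
    e: EdgeMap, min_length: int = 10, max_gap: int = 5, jitter: int = 1
) -> list[VerticalLineSegment]:
    """Assemble maximal near-vertical runs from a filtered edge map.

    Runs descend row by row; each step may move the column by up to
    ``jitter`` and up to ``max_gap`` missing rows in total are bridged.
    Only runs spanning at least ``min_length`` rows are returned, and each
    pixel belongs to at most one run (greedy top-to-bottom assignment;
    ties prefer the column closest to the run's current mean column, then
    the smaller column).
    """
    avail = e.edges.copy()
    h, w = avail.shape
    runs: list[VerticalLineSegment] = []
    for r0, c0 in zip(*np.nonzero(e.edges)):
        if not avail[r0, c0]:
            continue
        avail[r0, c0] = False
        pixels = [(int(r0), int(c0))]
        col_sum, gaps, pending, last = int(c0), 0, 0, int(c0)
        r = int(r0) + 1
        while r < h:
            rep = col_sum / len(pixels)
            cand = [c for c in range(last - jitter, last + jitter + 1) if 0 <= c < w and avail[r, c]]
            if cand:
                c = min(cand, key=lambda cc: (abs(cc - rep), cc))
                avail[r, c] = False
                pixels.append((r, c))
                col_sum += c
                last = c
                gaps += pending
                pending = 0
            else:
                pending += 1
                if gaps + pending > max_gap:
                    break
            r += 1
        seg = VerticalLineSegment(pixels, gap_count=gaps)
        if seg.span >= min_length:
            runs.append(seg)
        else:
            # too short: release pixels so later starts may reuse them
            for rr, cc in pixels:
                avail[rr, cc] = True
            avail[r0, c0] = False
    return runs


def refine_lines(
    segments: list[VerticalLineSegment],
    e_original: EdgeMap,
    group_col_tol: int = 2,
    group_row_tol: int = 2,
) -> list[RefinedLine]:
    """Drop pixels absent from the pre-shift edge map and group duplicates.

    Segment pixels that are background in the original Canny edge image are
    removed (this deletes the spurious left-flank lines produced by the
    orientation shift).  Overlapping/adjacent survivors are grouped and each
    group is summarized by the length-weighted mean of its member columns.
    """
    cleaned = []
    for seg in segments:
        px = [(r, c) for r, c in seg.pixels if e_original.edges[r, c]]
        if px:
            cleaned.append(VerticalLineSegment(px, seg.gap_count))
    if not cleaned:
        return []
    # union-find grouping on column and row proximity
    parent = list(range(len(cleaned)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(cleaned)), 2):
        a, b = cleaned[i], cleaned[j]
        if abs(a.mean_col - b.mean_col) <= group_col_tol and (
            a.top - group_row_tol <= b.bottom and b.top - group_row_tol <= a.bottom
        ):
            parent[find(i)] = find(j)
    groups: dict[int, list[VerticalLineSegment]] = {}
    for i, seg in enumerate(cleaned):
        groups.setdefault(find(i), []).append(seg)
    out = []
    for members in groups.values():
        lens = np.array([len(m.pixels) for m in members], dtype=float)
        cols = np.array([m.mean_col for m in members])
        # round half up so ties move toward the longer-line side's neighbor
        rep = int(np.floor((cols * lens).sum() / lens.sum() + 0.5))
        out.append(
            RefinedLine(
                col=rep,
                top=min(m.top for m in members),
                bottom=max(m.bottom for m in members),
                n_pixels=int(lens.sum()),
            )
        )
    out.sort(key=lambda l: (l.col, l.top))
    return out


def extend_to_diagonal(line: RefinedLine) -> RefinedLine:
    """Extend a line's near-diagonal end to the diagonal pixel of its column.

    In a diagonal-anchored square window the diagonal pixel of column c is
    row c; whichever end of the run is nearer the diagonal is moved onto
    it, never shortening the run.
    """
    if line.top >= line.col:  # run below the diagonal (5' geometry)
        return replace(line, top=line.col)
    if line.bottom <= line.col:  # run above the diagonal (3' geometry)
        return replace(line, bottom=line.col)
    return line


def pair_lines(lines: list[RefinedLine], max_width: int = 8) -> list[list[RefinedLine]]:
    """Serially chain column-sorted lines closer than ``max_width`` columns.

    Each maximal chain of two or more lines defines one candidate stripe
    (an edge pair); unpaired single lines are discarded.
    """
    lines = sorted(lines, key=lambda l: (l.col, l.top))
    chains: list[list[RefinedLine]] = []
    cur: list[RefinedLine] = []
    for line in lines:
        if cur and line.col - cur[-1].col < max_width:
            cur.append(line)
        else:
            if len(cur) >= 2:
                chains.append(cur)
            cur = [line]
    if len(cur) >= 2:
        chains.append(cur)
    return chains


def _ratio(c: CandidateStripe) -> float:
    return c.length_bins / c.width_bins


def merge_candidates(cands: list[CandidateStripe]) -> list[CandidateStripe]:
    """Collapse anchor-overlapping same-orientation candidates.

    Groups sharing at least one anchor bin are replaced by the member with
    the largest length/width ratio (ties: longer domain, then smaller
    anchor start).
    """
    out: list[CandidateStripe] = []
    keyfn = lambda c: (c.chromosome, c.orientation)
    for _, group_iter in itertools.groupby(sorted(cands, key=lambda c: (keyfn(c), c.anchor)), keyfn):
        group = list(group_iter)
        cluster: list[CandidateStripe] = []
        hi = -1
        for c in group:
            if cluster and c.anchor[0] < hi:
                cluster.append(c)
                hi = max(hi, c.anchor[1])
            else:
                if cluster:
                    out.append(_best_of(cluster))
                cluster = [c]
                hi = c.anchor[1]
        if cluster:
            out.append(_best_of(cluster))
    out.sort(key=lambda c: (c.chromosome, c.anchor[0], c.orientation))
    return out


def _best_of(cluster: list[CandidateStripe]) -> CandidateStripe:
    return max(cluster, key=lambda c: (_ratio(c), c.length_bins, -c.anchor[0]))


def _search_one_orientation(values, params, flip: bool):
    """Find 5'-geometry chains on ``values`` (already mirrored when flip)."""
    n = values.shape[0]
    found = []
    try:
        m_levels = positive_quantile_thresholds(values, params.quantiles)
    except ValueError:
        return found
    for w in sliding_windows(n, params.window, params.step):
        sub_all = values[w.start : w.end, w.start : w.end]
        keep = np.flatnonzero(sub_all.any(axis=1))
        if keep.size < params.min_length:
            continue
        local_map = BinIndexMap(keep)
        sub = sub_all[np.ix_(keep, keep)]
        if not np.any(sub > 0):
            continue
        for m_level, q in zip(m_levels, params.quantiles):
            for high_in in params.high_in_sweep:
                e = edge_stack(
                    sub, m_level, high_in, blur_kernel=params.blur_kernel, sigma=params.canny_sigma
                )
                filt = orientation_filter(e)
                runs = find_vertical_runs(filt, params.min_length, params.max_gap)
                lines = refine_lines(runs, e)
                # keep lines whose bulk lies below the diagonal (5' geometry
                # here; the mirrored pass handles the other side)
                lines = [l for l in lines if (l.bottom - l.col) > (l.col - l.top)]
                lines = [extend_to_diagonal(l) for l in lines]
                for chain in pair_lines(lines, params.max_width):
                    a_lo = local_map.to_original(min(l.col for l in chain)) + w.start
                    a_hi = local_map.to_original(max(l.col for l in chain)) + w.start + 1
                    # domain runs from the diagonal (anchor start) outward
                    d_lo = a_lo
                    d_hi = local_map.to_original(max(l.bottom for l in chain)) + w.start + 1
                    found.append((a_lo, a_hi, d_lo, d_hi, w.start, q, high_in))
    return found


def detect_stripes(m: ContactMatrix, params, pair_filter=None) -> list[CandidateStripe]:
    """Run the full candidate search on a normalized contact matrix.

    5' stripes come from vertical runs below the diagonal; 3' stripes are
    found by running the identical procedure on the genome-axis-mirrored
    matrix (``values[::-1, ::-1]``) and mapping coordinates back.  All
    candidates found across windows, contrast levels, and brightness
    levels are pooled; ``pair_filter`` (a predicate on a candidate), when
    given, removes low-quality pairs before duplicates are merged, so a
    poorly localized pairing cannot out-compete a well-anchored duplicate
    of the same stripe.
    """
    n = m.n_bins
    cands: list[CandidateStripe] = []
    for flip in (False, True):
        values = m.values[::-1, ::-1] if flip else m.values
        for a_lo, a_hi, d_lo, d_hi, wstart, q, high_in in _search_one_orientation(
            values, params, flip
        ):
            if flip:
                a_lo, a_hi = n - a_hi, n - a_lo
                d_lo, d_hi = n - d_hi, n - d_lo
                orientation = "3p"
            else:
                orientation = "5p"
            cands.append(
                CandidateStripe(
                    chromosome=m.chromosome,
                    orientation=orientation,
                    anchor=(a_lo, a_hi),
                    domain=(d_lo, d_hi),
                    resolution=m.resolution,
                    bin_start=m.bin_start,
                    provenance={"window": wstart, "quantile": q, "high_in": high_in},
                )
            )
    if pair_filter is not None:
        # deduplicate identical geometries first so each is tested once
        seen: dict[tuple, CandidateStripe] = {}
        for c in cands:
            seen.setdefault((c.orientation, c.anchor, c.domain), c)
        cands = [c for c in seen.values() if pair_filter(c)]
    return merge_candidates(cands)
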
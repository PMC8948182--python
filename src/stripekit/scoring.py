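"""Stripe scoring: distance-matched empirical P-values and stripiness.

Two statistics qualify a candidate stripe:

* **Median P-value** — per stripe row, the smoothed mean intensity of the
  row (``C``) is contrasted against its left and right flanking
  neighborhoods (``L``, ``R``); each difference is ranked against an
  empirical null of the same smoothed difference sampled at random
  positions of identical diagonal distance.  The less significant of the
  two sides is kept per row and the median over rows summarizes the
  stripe.  Low values mean the stripe stands out sharply from its
  background at its genomic distance.

* **Stripiness** — computed on the observed/expected matrix, a modified
  Sobel gradient score ``S = M * sum_i dG_i / L`` where per row
  ``dG_i = min(Gx_left, Gx_right) - Gy`` rewards cross-stripe contrast in
  the x-direction and penalizes intensity discontinuity along the stripe
  (y-direction); ``M`` is the median of row means.  Negative stripiness
  marks low-quality calls whose within-stripe discontinuity outweighs
  their contrast (e.g. loops).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_io import ContactMatrix, expected_profile, observed_over_expected
from .stripe_search import CandidateStripe

__all__ = [
    "NullDistributions",
    "ScoredStripe",
    "build_null_distributions",
    "row_pvalue",
    "median_pvalue",
    "stripiness",
    "score_stripes",
    "merge_stripe_sets",
    "classify_condition_specific",
    "stripes_to_table",
    "write_stripe_tsv",
    "write_bedpe",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "chrom",
    "anchor_start",
    "anchor_end",
    "chrom2",
    "domain_start",
    "domain_end",
    "orientation",
    "width_bp",
    "length_bp",
    "mean_oe",
    "sum_oe",
    "quantile_M",
    "high_in",
    "pvalue_median",
    "stripiness",
]


def smoothing_bins(resolution: int, smooth_bp: int = 50_000) -> int:
    """Number of bins spanning the smoothing window (50 kb by default)."""
    return max(1, round(smooth_bp / resolution))


class _Integral:
    """2-D integral image for O(1) rectangle means."""

    def __init__(self, values: np.ndarray):
        n = values.shape[0]
        self.s = np.zeros((n + 1, n + 1))
        np.cumsum(np.cumsum(values, axis=0), axis=1, out=self.s[1:, 1:])
        self.n = n

    def mean(self, r0, r1, c0, c1):
        """Mean over rows [r0,r1) x cols [c0,c1); NaN if empty after clipping."""
        r0, r1 = np.clip(r0, 0, self.n), np.clip(r1, 0, self.n)
        c0, c1 = np.clip(c0, 0, self.n), np.clip(c1, 0, self.n)
        area = (r1 - r0) * (c1 - c0)
        s = self.s
        tot = s[r1, c1] - s[r0, c1] - s[r1, c0] + s[r0, c0]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(area > 0, tot / np.where(area > 0, area, 1), np.nan)


@dataclass
class NullDistributions:
    """Empirical null samples of smoothed center-minus-flank differences.

    For each diagonal distance ``d`` and each side, ``samples[d]`` holds
    ``n`` differences computed with the same window geometry as real
    stripe rows of width ``stripe_width``.
    """

    stripe_width: int
    smooth_n: int
    n: int
    seed: int
    samples: dict = field(default_factory=dict)  # d -> (left[n], right[n])

    def covers(self, d: int) -> bool:
        return d in self.samples


def _row_windows(integral: _Integral, anchor_lo: int, width: int, rows, smooth_n: int):
    """C, L, R smoothed means for testing rows (vectorized over rows)."""
    rows = np.asarray(rows)
    r0 = rows - smooth_n // 2
    r1 = r0 + smooth_n
    c = integral.mean(r0, r1, anchor_lo, anchor_lo + width)
    left = integral.mean(r0, r1, anchor_lo - smooth_n, anchor_lo)
    right = integral.mean(r0, r1, anchor_lo + width, anchor_lo + width + smooth_n)
    return c, left, right


def build_null_distributions(
    m: ContactMatrix,
    stripe_width: int,
    n: int = 1000,
    max_distance: int = 400,
    smooth_bp: int = 50_000,
    seed: int = 0,
) -> NullDistributions:
    """Sample empirical nulls of C-L and C-R at every diagonal distance.

    At each distance ``d`` in 0..max_distance, ``n`` anchor positions are
    drawn uniformly (with replacement) over the bins where the full window
    geometry fits, and the same smoothed center/flank differences used for
    real rows are recorded, separately for the left and right side.
    Distances where no position is feasible are left unscorable.
    """
    if n < 2:
        raise ValueError("null sample size must be >= 2")
    nb = m.n_bins
    smooth_n = smoothing_bins(m.resolution, smooth_bp)
    integral = _Integral(m.values)
    rng = np.random.default_rng(seed)
    nulls = NullDistributions(stripe_width=stripe_width, smooth_n=smooth_n, n=n, seed=seed)
    for d in range(0, max_distance + 1):
        lo = max(smooth_n, smooth_n // 2 - d)
        hi = min(nb - stripe_width - smooth_n, nb - d - smooth_n + smooth_n // 2)
        if hi <= lo:
            continue
        anchors = rng.integers(lo, hi, size=n)
        r0 = anchors + d - smooth_n // 2
        r1 = r0 + smooth_n
        c = integral.mean(r0, r1, anchors, anchors + stripe_width)
        left = integral.mean(r0, r1, anchors - smooth_n, anchors)
        right = integral.mean(r0, r1, anchors + stripe_width, anchors + stripe_width + smooth_n)
        nulls.samples[d] = (c - left, c - right)
    return nulls


def row_pvalue(
    m_or_integral,
    nulls: NullDistributions,
    anchor_lo: int,
    width: int,
    row: int,
    distance: int,
) -> float:
    """Empirical P-value of one stripe row at the given diagonal distance.

    Uses the plus-one rule ``p = (1 + #{null >= observed}) / (1 + n)`` per
    side and returns the less significant side.  Rows at unscorable
    distances return 1.0 (conservative); rows whose flanks are entirely
    off-matrix return NaN and are skipped in the median.
    """
    integral = m_or_integral if isinstance(m_or_integral, _Integral) else _Integral(m_or_integral.values)
    if not nulls.covers(distance):
        logger.warning("distance %d not covered by null distributions; P=1", distance)
        return 1.0
    c, left, right = _row_windows(integral, anchor_lo, width, [row], nulls.smooth_n)
    c, left, right = float(c[0]), float(left[0]), float(right[0])
    if np.isnan(c) or (np.isnan(left) and np.isnan(right)):
        return float("nan")
    nl, nr = nulls.samples[distance]
    ps = []
    if not np.isnan(left):
        ps.append((1 + int(np.sum(nl >= c - left))) / (1 + nulls.n))
    if not np.isnan(right):
        ps.append((1 + int(np.sum(nr >= c - right))) / (1 + nulls.n))
    return max(ps)


def _stripe_rows(s: CandidateStripe):
    """(row, distance) pairs for every row of a stripe.

    Distance is measured from the row to the anchor-side reference pixel:
    the first anchor column for 5' stripes, the last for 3' stripes.
    """
    d_lo, d_hi = s.domain
    rows = np.arange(d_lo, d_hi)
    if s.orientation == "5p":
        dist = rows - s.anchor[0]
    else:
        dist = (s.anchor[1] - 1) - rows
    ok = dist >= 0
    return rows[ok], dist[ok]


def median_pvalue(s: CandidateStripe, m: ContactMatrix, nulls: NullDistributions) -> tuple:
    """Median over row P-values; returns (median, per-row array)."""
    integral = _Integral(m.values)
    rows, dists = _stripe_rows(s)
    pvals = np.array(
        [row_pvalue(integral, nulls, s.anchor[0], s.width_bins, int(r), int(d)) for r, d in zip(rows, dists)]
    )
    valid = pvals[~np.isnan(pvals)]
    if valid.size == 0:
        return 1.0, pvals
    return float(np.median(valid)), pvals


def stripiness(s: CandidateStripe, oe: ContactMatrix, smooth_bp: int = 50_000) -> float:
    """Gradient continuity score on the O/E matrix.

    Per row, C is the mean O/E over the stripe width and L/R the means of
    the 50 kb flanking column blocks; modified Sobel kernels over rows
    (i-1, i, i+1) with replicate padding give the x- and y-gradients, and
    ``S = M * sum(min(GxL, GxR) - Gy) / L`` with M the median of C.
    """
    if oe.norm_tag != "oe":
        raise ValueError("stripiness requires an O/E matrix")
    nb = oe.n_bins
    flank_n = smoothing_bins(oe.resolution, smooth_bp)
    x1, x2 = s.anchor
    rows, _ = _stripe_rows(s)
    rows = rows[(rows >= 0) & (rows < nb)]
    n_rows = rows.size
    if n_rows == 0:
        return 0.0
    v = oe.values
    C = v[rows, x1:x2].mean(axis=1)
    lf_lo, rf_hi = max(x1 - flank_n, 0), min(x2 + flank_n, nb)
    L = v[rows, lf_lo:x1].mean(axis=1) if lf_lo < x1 else np.zeros(n_rows)
    R = v[rows, x2:rf_hi].mean(axis=1) if x2 < rf_hi else np.zeros(n_rows)
    if not np.any(C):
        return 0.0
    # replicate padding at both ends for the (i-1, i+1) neighbors
    Cp, Lp, Rp = (np.pad(a, 1, mode="edge") for a in (C, L, R))
    up, mid, dn = slice(0, -2), slice(1, -1), slice(2, None)
    gx_left = (Cp[up] - Lp[up]) + 2 * (Cp[mid] - Lp[mid]) + (Cp[dn] - Lp[dn])
    gx_right = (Cp[up] - Rp[up]) + 2 * (Cp[mid] - Rp[mid]) + (Cp[dn] - Rp[dn])
    gy = (Lp[up] + 2 * Cp[up] + Rp[up]) - (Lp[dn] + 2 * Cp[dn] + Rp[dn])
    dG = np.minimum(gx_left, gx_right) - gy
    return float(np.median(C) * dG.sum() / n_rows)


class PValueScorer:
    """Caches the integral image and per-width null distributions so many
    candidates can be scored against one matrix cheaply."""

    def __init__(self, m: ContactMatrix, params):
        self.m = m
        self.params = params
        self.integral = _Integral(m.values)
        self._nulls: dict[int, NullDistributions] = {}

    def nulls_for(self, width: int) -> NullDistributions:
        if width not in self._nulls:
            self._nulls[width] = build_null_distributions(
                self.m,
                stripe_width=width,
                n=self.params.n_null,
                max_distance=self.params.null_max_distance,
                smooth_bp=self.params.smooth_bp,
                seed=self.params.seed,
            )
        return self._nulls[width]

    def row_pvalues(self, s: CandidateStripe) -> np.ndarray:
        nulls = self.nulls_for(s.width_bins)
        rows, dists = _stripe_rows(s)
        return np.array(
            [
                row_pvalue(self.integral, nulls, s.anchor[0], s.width_bins, int(r), int(d))
                for r, d in zip(rows, dists)
            ]
        )

    def median_pvalue(self, s: CandidateStripe) -> float:
        pvals = self.row_pvalues(s)
        valid = pvals[~np.isnan(pvals)]
        return float(np.median(valid)) if valid.size else 1.0


@dataclass
class ScoredStripe:
    """A candidate stripe with its quality statistics."""

    stripe: CandidateStripe
    median_pvalue: float
    stripiness: float
    mean_oe: float
    sum_oe: float
    row_pvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def score_stripes(
    cands: list[CandidateStripe],
    m: ContactMatrix,
    params,
    drop_insignificant: bool = True,
) -> list[ScoredStripe]:
    """Attach median P-value, stripiness and O/E summaries to candidates.

    ``m`` is the matrix the detection stack saw (raw or sqrt-VC); the O/E
    matrix for stripiness is derived from it.  In detection mode
    (``drop_insignificant``), stripes with median P >= ``params.p_cutoff``
    are removed.  Candidates with coordinates outside the matrix are
    skipped with a log entry.
    """
    profile = expected_profile(m)
    oe = observed_over_expected(m, profile)
    scorer = PValueScorer(m, params)
    out = []
    for s in cands:
        if s.anchor[0] < 0 or s.domain[1] > m.n_bins or s.width_bins < 1 or s.length_bins < 1:
            logger.warning("skipping stripe with out-of-range coordinates: %s", s)
            continue
        pvals = scorer.row_pvalues(s)
        valid = pvals[~np.isnan(pvals)]
        med_p = float(np.median(valid)) if valid.size else 1.0
        rows, _ = _stripe_rows(s)
        body = oe.values[rows[0] : rows[-1] + 1, s.anchor[0] : s.anchor[1]]
        out.append(
            ScoredStripe(
                stripe=s,
                median_pvalue=med_p,
                stripiness=stripiness(s, oe, params.smooth_bp),
                mean_oe=float(body.mean()) if body.size else 0.0,
                sum_oe=float(body.sum()),
                row_pvalues=pvals,
            )
        )
    if drop_insignificant:
        out = [s for s in out if s.median_pvalue < params.p_cutoff]
    return out


def _overlap_bp(a: CandidateStripe, b: CandidateStripe) -> int:
    a1, a2 = a.anchor_bp
    b1, b2 = b.anchor_bp
    return max(0, min(a2, b2) - max(a1, b1))


def merge_stripe_sets(a: list[ScoredStripe], b: list[ScoredStripe]) -> list[CandidateStripe]:
    """Union of two scored stripe sets; anchor-overlapping same-orientation
    stripes collapse to the member with the larger stripiness."""
    pool = sorted(
        list(a) + list(b),
        key=lambda s: (s.stripe.chromosome, s.stripe.orientation, s.stripe.anchor_bp),
    )
    out: list[CandidateStripe] = []
    cluster: list[ScoredStripe] = []

    def flush():
        if cluster:
            out.append(max(cluster, key=lambda s: s.stripiness).stripe)

    prev_key, hi = None, -1
    for s in pool:
        key = (s.stripe.chromosome, s.stripe.orientation)
        if cluster and key == prev_key and s.stripe.anchor_bp[0] < hi:
            cluster.append(s)
            hi = max(hi, s.stripe.anchor_bp[1])
        else:
            flush()
            cluster = [s]
            prev_key, hi = key, s.stripe.anchor_bp[1]
    flush()
    out.sort(key=lambda c: (c.chromosome, c.anchor_bp[0], c.orientation))
    return out


def classify_condition_specific(scored_a: list[ScoredStripe], scored_b: list[ScoredStripe]) -> list[str]:
    """Label merged stripes as 'A', 'B' (condition-specific) or 'shared'.

    A stripe is condition-specific when its stripiness exceeds 2 in one
    condition and is negative in the other.
    """
    if len(scored_a) != len(scored_b):
        raise ValueError("score lists must align on the merged stripe list")
    labels = []
    for sa, sb in zip(scored_a, scored_b):
        if sa.stripiness > 2 and sb.stripiness < 0:
            labels.append("A")
        elif sb.stripiness > 2 and sa.stripiness < 0:
            labels.append("B")
        else:
            labels.append("shared")
    return labels


def stripes_to_table(scored: list[ScoredStripe]) -> pd.DataFrame:
    """Scored stripes as a tidy table (coordinates in 0-based half-open bp)."""
    recs = []
    for s in scored:
        c = s.stripe
        a1, a2 = c.anchor_bp
        d1, d2 = c.domain_bp
        recs.append(
            dict(
                chrom=c.chromosome,
                anchor_start=a1,
                anchor_end=a2,
                chrom2=c.chromosome,
                domain_start=d1,
                domain_end=d2,
                orientation=c.orientation,
                width_bp=a2 - a1,
                length_bp=d2 - d1,
                mean_oe=s.mean_oe,
                sum_oe=s.sum_oe,
                quantile_M=c.provenance.get("quantile", float("nan")),
                high_in=c.provenance.get("high_in", float("nan")),
                pvalue_median=s.median_pvalue,
                stripiness=s.stripiness,
            )
        )
    return pd.DataFrame.from_records(recs, columns=TABLE_COLUMNS)


def write_stripe_tsv(scored: list[ScoredStripe], path) -> None:
    stripes_to_table(scored).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedpe(scored: list[ScoredStripe], path) -> None:
    """BEDPE export: anchor interval vs domain interval, stripiness as score."""
    df = stripes_to_table(scored)
    bedpe = df[["chrom", "anchor_start", "anchor_end", "chrom2", "domain_start", "domain_end"]].copy()
    bedpe["name"] = [
        f"stripe_{r.chrom}_{r.anchor_start}_{r.orientation}" for r in df.itertuples()
    ]
    bedpe["score"] = df["stripiness"]
    bedpe.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
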
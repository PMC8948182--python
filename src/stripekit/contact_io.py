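"""Contact-matrix input and normalization.

Reads genomically binned contact matrices from cooler-layout HDF5 files
(single-resolution ``.cool`` or multi-resolution ``.mcool``), applies
square-root vanilla-coverage balancing, and derives the distance-decay
expected profile and observed/expected (O/E) matrix used by the stripe
scores.  Only cis (intra-chromosomal) matrices are handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "ContactMatrix",
    "BinIndexMap",
    "ChromosomeNotFoundError",
    "ResolutionNotFoundError",
    "EmptyMatrixError",
    "read_contact_matrix",
    "sqrt_vc_normalize",
    "expected_profile",
    "observed_over_expected",
    "drop_empty_bins",
]


class ChromosomeNotFoundError(KeyError):
    """Requested chromosome is absent from the file."""


class ResolutionNotFoundError(KeyError):
    """Requested resolution is not stored in a multi-resolution file."""


class EmptyMatrixError(ValueError):
    """Operation undefined on an all-zero matrix."""


@dataclass
class ContactMatrix:
    """A dense symmetric cis contact matrix for one chromosome.

    Parameters
    ----------
    chromosome : str
        Chromosome name as stored in the source file.
    resolution : int
        Bin size in bp.
    values : numpy.ndarray
        ``(n, n)`` symmetric, non-negative, finite matrix of contact
        frequencies (raw counts or normalized values).
    bin_start : int
        Genomic coordinate (bp) of the left edge of bin 0.  Nonzero after
        empty-bin removal has compacted the leading bins away.
    norm_tag : str
        One of ``raw``, ``sqrt_vc``, ``oe``.
    """

    chromosome: str
    resolution: int
    values: np.ndarray
    bin_start: int = 0
    norm_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contact matrix must be finite")
        if np.any(self.values < 0):
            raise ValueError("contact matrix must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_to_bp(self, bin_idx: int) -> int:
        """Genomic coordinate (bp, 0-based) of the left edge of a bin."""
        return self.bin_start + bin_idx * self.resolution


@dataclass
class BinIndexMap:
    """Invertible map from compacted bin indices to original bin indices.

    ``orig_index[k]`` is the original (pre-compaction) index of compacted
    bin ``k``; indices are strictly increasing.
    """

    orig_index: np.ndarray
    _inverse: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.orig_index = np.asarray(self.orig_index, dtype=np.int64)
        if self.orig_index.size and np.any(np.diff(self.orig_index) <= 0):
            raise ValueError("bin map must be strictly increasing")
        self._inverse = {int(o): k for k, o in enumerate(self.orig_index)}

    def to_original(self, compact_idx: int) -> int:
        return int(self.orig_index[compact_idx])

    def to_compact(self, orig_idx: int) -> int:
        return self._inverse[int(orig_idx)]

    def __len__(self) -> int:
        return len(self.orig_index)


def _open_resolution_group(f: h5py.File, resolution: int) -> h5py.Group:
    if "resolutions" in f:
        stored = sorted(int(r) for r in f["resolutions"])
        if str(resolution) not in f["resolutions"]:
            raise ResolutionNotFoundError(
                f"resolution {resolution} not stored; available: {stored}"
            )
        return f[f"resolutions/{resolution}"]
    if "bin-size" in f.attrs:
        grp_res = int(f.attrs["bin-size"])
    else:  # infer from the first bin
        grp_res = int(f["bins/end"][0] - f["bins/start"][0])
    if grp_res != resolution:
        raise ResolutionNotFoundError(
            f"resolution {resolution} not stored; available: [{grp_res}]"
        )
    return f["/"]


def read_contact_matrix(path, chromosome: str, resolution: int) -> ContactMatrix:
    """Read the cis matrix of one chromosome from a .cool/.mcool file.

    Returns raw counts as a dense symmetric matrix (``norm_tag='raw'``).

    Raises
    ------
    ChromosomeNotFoundError
        If the chromosome is absent (message lists available names).
    ResolutionNotFoundError
        If an .mcool does not store the requested resolution.
    """
    with h5py.File(path, "r") as f:
        grp = _open_resolution_group(f, resolution)
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in grp["chroms/name"][:]]
        if chromosome not in names:
            raise ChromosomeNotFoundError(
                f"chromosome {chromosome!r} not found; available: {names}"
            )
        cid = names.index(chromosome)
        chrom_ids = grp["bins/chrom"][:]
        bin_lo, bin_hi = np.searchsorted(chrom_ids, [cid, cid + 1])
        n = int(bin_hi - bin_lo)
        bin_start = int(grp["bins/start"][bin_lo])
        offsets = grp["indexes/bin1_offset"][:]
        px_lo, px_hi = int(offsets[bin_lo]), int(offsets[bin_hi])
        b1 = grp["pixels/bin1_id"][px_lo:px_hi]
        b2 = grp["pixels/bin2_id"][px_lo:px_hi]
        cnt = grp["pixels/count"][px_lo:px_hi].astype(float)
        cis = b2 < bin_hi  # bin1 is within range by construction
        i = (b1[cis] - bin_lo).astype(np.int64)
        j = (b2[cis] - bin_lo).astype(np.int64)
        v = cnt[cis]
        mat = np.zeros((n, n), dtype=float)
        mat[i, j] = v
        # symmetric fill of the stored upper triangle
        mat[j, i] = v
    return ContactMatrix(
        chromosome=chromosome, resolution=resolution, values=mat, bin_start=bin_start
    )


def sqrt_vc_normalize(m: ContactMatrix) -> ContactMatrix:
    """Square-root vanilla-coverage balancing.

    Each entry is divided by ``sqrt(s_i * s_j)`` where ``s_k`` is the total
    coverage (row sum) of bin ``k``.  Bins with zero coverage are left at
    zero.  Requires a raw matrix.
    """
    if m.norm_tag != "raw":
        raise ValueError(f"sqrt_vc_normalize expects raw counts, got {m.norm_tag!r}")
    s = m.values.sum(axis=1)
    if not np.any(s > 0):
        raise EmptyMatrixError("empty matrix")
    root = np.sqrt(s, where=s > 0, out=np.zeros_like(s))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(root > 0, 1.0 / root, 0.0)
    # outer product first: float multiply is commutative, so the scaling
    # matrix (and hence the output) is bit-exactly symmetric
    out = m.values * np.outer(inv, inv)
    return replace(m, values=out, norm_tag="sqrt_vc")


def expected_profile(m: ContactMatrix) -> np.ndarray:
    """Mean contact frequency at each diagonal offset ``d = |i-j|``.

    Zeros are included in the mean; the returned array has length
    ``n_bins`` (offsets 0..n-1).
    """
    v = m.values
    n = v.shape[0]
    return np.array([v.diagonal(d).mean() for d in range(n)])


def observed_over_expected(m: ContactMatrix, profile: np.ndarray) -> ContactMatrix:
    """Divide each pixel by the expected value at its diagonal offset.

    Offsets with zero expectation map to zero (0/0 -> 0).
    """
    profile = np.asarray(profile, dtype=float)
    n = m.n_bins
    if profile.shape[0] != n:
        raise ValueError("profile length must equal the number of bins")
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = profile[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(exp > 0, m.values / np.where(exp > 0, exp, 1.0), 0.0)
    return replace(m, values=out, norm_tag="oe")


def drop_empty_bins(m: ContactMatrix) -> tuple[ContactMatrix, BinIndexMap]:
    """Remove all-zero rows/columns, returning the compacted matrix and map."""
    keep = np.flatnonzero(m.values.any(axis=1))
    if keep.size == m.n_bins:
        return m, BinIndexMap(np.arange(m.n_bins))
    out = m.values[np.ix_(keep, keep)]
    return replace(m, values=out), BinIndexMap(keep)
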
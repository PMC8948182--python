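"""End-to-end orchestration: cooler file -> scored stripe table."""

from __future__ import annotations

import logging

from .config import DetectionParams
from .contact_io import ContactMatrix, read_contact_matrix, sqrt_vc_normalize
from .scoring import PValueScorer, ScoredStripe, score_stripes
from .stripe_search import detect_stripes

__all__ = ["normalize_for_detection", "call_stripes", "process_cooler"]

logger = logging.getLogger(__name__)


def normalize_for_detection(m: ContactMatrix, norm: str) -> ContactMatrix:
    if norm == "raw":
        return m
    if norm == "sqrt_vc":
        return sqrt_vc_normalize(m)
    raise ValueError(f"unknown norm {norm!r}")


def call_stripes(m_raw: ContactMatrix, params: DetectionParams) -> list[ScoredStripe]:
    """Detect and score stripes on one raw cis matrix.

    Candidate pairs are filtered by median P-value before duplicates from
    overlapping windows and parameter sweeps are merged, then the merged
    survivors receive their full score set.
    """
    m = normalize_for_detection(m_raw, params.norm)
    scorer = PValueScorer(m, params)
    cands = detect_stripes(
        m, params, pair_filter=lambda c: scorer.median_pvalue(c) < params.p_cutoff
    )
    scored = score_stripes(cands, m, params, drop_insignificant=True)
    logger.info("%s: %d candidates, %d pass P < %g", m.chromosome, len(cands), len(scored), params.p_cutoff)
    return scored


def process_cooler(
    path, resolution: int, chromosomes: list[str], params: DetectionParams
) -> list[ScoredStripe]:
    """Run detection + scoring for each chromosome of a cooler file.

    Chromosomes are processed independently (the unit of parallelism);
    results are concatenated in the given chromosome order and do not
    depend on how the work is scheduled.
    """
    out: list[ScoredStripe] = []
    for chrom in chromosomes:
        raw = read_contact_matrix(path, chrom, resolution)
        out.extend(call_stripes(raw, params))
    return out
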
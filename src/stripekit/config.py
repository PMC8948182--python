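"""Detection and scoring parameters."""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_QUANTILES = (0.95, 0.96, 0.97, 0.98, 0.99)
DEFAULT_HIGH_IN_SWEEP = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class DetectionParams:
    """Tunable knobs of the detection + scoring pipeline.

    ``quantiles`` set the maximum-pixel-value contrast levels as quantiles
    of the positive contact frequencies of each chromosome; percentiles
    should be set differently for different data depending on sequencing
    depth.  ``max_width`` is in bins: 8 is the recommended maximum stripe
    width at 10 kb resolution, 16 at 5 kb.  ``norm`` selects the matrix the
    image stack and the P-value statistics see (``raw`` or ``sqrt_vc``);
    stripiness always uses the O/E matrix derived from that choice.
    """

    quantiles: tuple = DEFAULT_QUANTILES
    high_in_sweep: tuple = DEFAULT_HIGH_IN_SWEEP
    blur_kernel: int = 3
    canny_sigma: float = 2.0
    min_length: int = 10
    max_gap: int = 5
    max_width: int = 8
    window: int = 400
    step: int = 200
    p_cutoff: float = 0.1
    norm: str = "sqrt_vc"
    n_null: int = 1000
    null_max_distance: int = 400
    smooth_bp: int = 50_000
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if any(not (0.0 < q < 1.0) for q in self.quantiles):
            raise ValueError("quantiles must lie in (0, 1)")
        if self.max_width < 1:
            raise ValueError("max_width must be >= 1")
        if not (0.0 < self.p_cutoff <= 1.0):
            raise ValueError("p_cutoff must lie in (0, 1]")
        if self.norm not in ("raw", "sqrt_vc"):
            raise ValueError("norm must be 'raw' or 'sqrt_vc'")
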
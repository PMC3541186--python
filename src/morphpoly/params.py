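"""Shared parameter objects for the polymorphism pipeline.

The defaults encode the filtering contract of the original EST study design:
a Phred-20 mask, a minimum per-population depth of 4, a 5% minor-allele
frequency floor (at most ~10 breeding individuals, hence at most 20 sampled
alleles), and a sliding-window quality trim (window 30, step 5, minimum
retained length 100 bp).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CallThresholds:
    """Read-cleaning and site-calling thresholds.

    Parameters
    ----------
    q_min:
        Phred quality below which a base is masked to ``N`` (strict: Q20
        itself is kept).
    d_min:
        Minimum read depth per population for a site to be callable.
    f_min:
        Minimum minor-allele frequency (read-count frequency k/D).
    trim_window, trim_step:
        Sliding-window parameters for terminal quality trimming.
    min_read_length:
        Reads shorter than this after trimming are rejected.
    """

    q_min: int = 20
    d_min: int = 4
    f_min: float = 0.05
    trim_window: int = 30
    trim_step: int = 5
    min_read_length: int = 100

    def __post_init__(self) -> None:
        if self.d_min < 1:
            raise ValueError("d_min must be >= 1")
        if not (0.0 < self.f_min <= 0.5):
            raise ValueError("f_min must lie in (0, 0.5]")
        if self.trim_step > self.trim_window:
            raise ValueError("trim_step must not exceed trim_window")
        if self.trim_window < 1 or self.trim_step < 1:
            raise ValueError("trim_window and trim_step must be >= 1")
        if self.min_read_length < 0:
            raise ValueError("min_read_length must be non-negative")


@dataclass(frozen=True)
class ErrorModelParams:
    """Binomial sequencing/RT error model used to filter candidate SNPs.

    A minor allele seen k times at depth D is only trusted when the
    probability that *some* position of a contig of ``contig_len_for_test``
    bases shows >= k errors is at most ``alpha``, under independent per-base
    errors at rate ``p_err``.

    ``use_tail`` selects the upper-tail probability P(>= k errors) for the
    per-site quantity; setting it False uses the point mass P(= k errors)
    instead (the two are nearly identical at these parameter values).
    """

    p_err: float = 1e-4
    contig_len_for_test: int = 1000
    alpha: float = 0.01
    use_tail: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_err < 1.0):
            raise ValueError("p_err must lie in (0, 1)")
        if self.contig_len_for_test < 1:
            raise ValueError("contig_len_for_test must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
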
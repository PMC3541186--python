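"""Standard validation protocols run on synthetic data.

Two canned study conditions used by the validation suite and the
reproduction script:

* a *clean recovery* run — error-free reads at generous depth with an
  undiverged outgroup, where the design guarantees every planted fixed
  difference is observable, so detection and orientation must be perfect;
* an *error-only* run — no planted variants at the study's error rate
  (1e-4) and depth (6.8), measuring the per-contig false polymorphic-site
  rate that the binomial filter is built to keep at or below alpha.

Contig count/length are desk-scale (200 x 300 bp and 500 x 300 bp); see
docs/methods.md for the sizing rationale.
"""

from __future__ import annotations

from .simulate import SimulationConfig

__all__ = ["clean_recovery_config", "error_only_config",
           "false_positive_contig_rate"]


def clean_recovery_config(seed: int, n_contigs: int = 200) -> SimulationConfig:
    """Conditions under which every planted event must be recovered."""
    return SimulationConfig(
        n_contigs=n_contigs, contig_length=300, depth_mean=20.0,
        error_rate=0.0, q_low_fraction=0.0,
        fixed_diff_rate=2e-3, nonsyn_fraction=0.5,
        polymorphic_site_rate=5e-4, minor_allele_freq=0.5,
        outgroup_protein_divergence=0.0, seed=seed,
    )


def error_only_config(seed: int, n_contigs: int = 500) -> SimulationConfig:
    """Study-condition error process with nothing planted."""
    return SimulationConfig(
        n_contigs=n_contigs, contig_length=300, depth_mean=6.8,
        error_rate=1e-4, q_low_fraction=0.05,
        fixed_diff_rate=0.0, polymorphic_site_rate=0.0, seed=seed,
    )


def false_positive_contig_rate(classifications) -> float:
    """Fraction of contigs with >= 1 polymorphic site call in either morph."""
    n_bad = sum(
        1 for sites in classifications.values()
        if any(len(s.alleles_pop1) >= 2 or len(s.alleles_pop2) >= 2
               for s in sites)
    )
    return n_bad / max(len(classifications), 1)
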
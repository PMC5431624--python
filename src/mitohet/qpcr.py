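"""Relative copy-number estimation from qPCR threshold cycles.

The model: at the fluorescence detection threshold the amplified mass of every
amplicon is equal, and amplification is perfect doubling, so
``Ln * Nn * 2**ctn = Lm * Nm * 2**ctm`` where L is amplicon length (bp), N is
starting copies per cell, and ct the threshold cycle. With the single-copy
nuclear reference gene at Nn = 2 copies per (dikaryotic, two-nucleus) cell,
the mitochondrial target's per-cell copy number is

    Nm = (2 * Ln * 2**ctn) / (Lm * 2**ctm).

Replicates are paired by index (replicate i of the target against replicate i
of the reference); when the replicate counts differ the mean Ct values are
used instead and no SD is reported.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .simulate import NUCLEAR_COPIES, CtPanel

__all__ = ["CopyNumberResult", "RatioResult", "relative_copy_number",
           "summarize_panel", "major_minor_ratio"]


def relative_copy_number(ctn: float, ctm: float, ln: float, lm: float) -> float:
    """Per-cell copy number of a mitochondrial target vs the nuclear reference.

    Parameters are the reference Ct ``ctn``, target Ct ``ctm``, reference
    amplicon length ``ln`` (bp) and target amplicon length ``lm`` (bp). The
    factor 2 is the diploid nuclear reference copy number.
    """
    if ln <= 0 or lm <= 0:
        raise ValueError("amplicon lengths must be positive")
    if ctn <= 0 or ctm <= 0:
        raise ValueError("Ct values must be positive")
    return (NUCLEAR_COPIES * ln * 2.0**ctn) / (lm * 2.0**ctm)


@dataclass(frozen=True)
class CopyNumberResult:
    """Replicate-aggregated copy number of one gene (per cell)."""

    gene: str
    copies: float
    sd: float | None  # None when replicate counts forced the mean-Ct fallback
    n_reps: int

    def __post_init__(self) -> None:
        if self.copies <= 0:
            raise ValueError("copy number must be > 0")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")


def summarize_panel(panel: CtPanel) -> list[CopyNumberResult]:
    """Copy numbers (mean +/- SD across index-paired replicates) for a panel.

    For each target with the same replicate count as the reference, a copy
    number is computed per replicate pair and summarized as mean +/- sample
    SD; with a single replicate the SD is 0. Mismatched replicate counts fall
    back to the mean Ct values with the SD omitted.
    """
    ref = panel.reference
    ref_cts = tuple(ref["cts"])
    results = []
    for _, row in panel.targets().iterrows():
        cts = tuple(row["cts"])
        if len(cts) == len(ref_cts):
            values = [
                relative_copy_number(ctn, ctm, ref["length_bp"], row["length_bp"])
                for ctn, ctm in zip(ref_cts, cts)
            ]
            mean = statistics.fmean(values)
            sd = statistics.stdev(values) if len(values) > 1 else 0.0
        else:
            mean = relative_copy_number(
                statistics.fmean(ref_cts), statistics.fmean(cts),
                ref["length_bp"], row["length_bp"],
            )
            sd = None
        results.append(CopyNumberResult(row["gene"], mean, sd, len(cts)))
    return results


@dataclass(frozen=True)
class RatioResult:
    """Major/minor copy-number ratio between two mitochondrial variants."""

    ratio: float
    major_gene: str
    minor_gene: str


def major_minor_ratio(result_a: CopyNumberResult, result_b: CopyNumberResult) -> RatioResult:
    """Fold difference between the abundant and the rare variant.

    Computed from the mean copy numbers (not as a mean of per-replicate
    ratios); an exact tie is labeled with the first argument as major.
    """
    if result_a.copies <= 0 or result_b.copies <= 0:
        raise ValueError("copy numbers must be positive")
    if result_a.copies >= result_b.copies:
        major, minor = result_a, result_b
    else:
        major, minor = result_b, result_a
    return RatioResult(major.copies / minor.copies, major.gene, minor.gene)
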
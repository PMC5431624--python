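"""Synthetic data generation for the heteroplasmy / recombination pipeline.

Everything downstream (the double-peak caller, the EM phaser, the copy-number
estimator, and the clonality statistics) can be exercised on data produced
here: multilocus haploid genotype matrices under clonal, panmictic, or mixed
reproduction; two-haplotype heteroplasmic mixtures with a known mixing
fraction; chromatogram-like four-channel peak-height traces; and qPCR Ct
panels generated from the same threshold model the estimator inverts.

All generators are driven by a single integer seed, recorded in the output's
provenance metadata so a run can be reproduced exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, het_entry

__all__ = [
    "ConfigError",
    "LocusSpec",
    "SimConfig",
    "TraceTruth",
    "TraceProfile",
    "CtPanel",
    "NUCLEAR_COPIES",
    "simulate_genotype_matrix",
    "inject_heteroplasmy",
    "simulate_trace",
    "simulate_ct",
    "amplicon_detected",
]

CHANNELS = "ACGT"

#: copies of the single-copy nuclear reference gene per (dikaryotic) cell
NUCLEAR_COPIES = 2.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class LocusSpec:
    """One locus: its name, allele labels, and allele frequencies."""

    name: str
    alleles: tuple[str, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.freqs):
            raise ConfigError(f"locus {self.name}: {len(self.alleles)} alleles "
                              f"but {len(self.freqs)} frequencies")
        if len(set(self.alleles)) != len(self.alleles):
            raise ConfigError(f"locus {self.name}: duplicate allele labels")
        if any(f < 0 for f in self.freqs):
            raise ConfigError(f"locus {self.name}: negative allele frequency")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ConfigError(
                f"locus {self.name}: allele frequencies sum to {sum(self.freqs)}, not 1"
            )


@dataclass
class SimConfig:
    """Study-design parameters for :func:`simulate_genotype_matrix`.

    ``mode`` selects the reproductive system being emulated: ``"clonal"``
    replicates a small founder set, ``"panmictic"`` draws every locus
    independently from its allele frequencies (linkage equilibrium), and
    ``"mixed"`` makes a ``clonal_fraction`` of isolates clonal and the rest
    panmictic.
    """

    n_isolates: int
    loci: Sequence[LocusSpec]
    n_populations: int = 1
    mode: str = "panmictic"
    clonal_fraction: float = 1.0
    n_founders: int = 2
    founders: Sequence[Sequence[str]] | None = None
    het_rate: float = 0.0
    mixing_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isolates < 1:
            raise ConfigError("n_isolates must be >= 1")
        if self.n_populations < 1:
            raise ConfigError("n_populations must be >= 1")
        if not self.loci:
            raise ConfigError("at least one locus is required")
        if self.mode not in ("clonal", "panmictic", "mixed"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for bounded, name in ((self.clonal_fraction, "clonal_fraction"),
                              (self.het_rate, "het_rate")):
            if not 0.0 <= bounded <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {bounded}")
        if not 0.0 < self.mixing_fraction <= 1.0:
            raise ConfigError("mixing_fraction must lie in (0, 1]")
        if self.founders is not None:
            for founder in self.founders:
                if len(founder) != len(self.loci):
                    raise ConfigError("each founder must name one allele per locus")
                for allele, locus in zip(founder, self.loci):
                    if allele not in locus.alleles:
                        raise ConfigError(
                            f"founder allele {allele!r} unknown at locus {locus.name}"
                        )


def _draw_genotype(rng: np.random.Generator, loci: Sequence[LocusSpec]) -> tuple[str, ...]:
    return tuple(rng.choice(spec.alleles, p=spec.freqs) for spec in loci)


def simulate_genotype_matrix(config: SimConfig) -> GenotypeMatrix:
    """Simulate a homoplasmic multilocus genotype matrix.

    Clonal isolates copy founders round-robin, so explicit ``founders`` in
    equal proportions are reproduced exactly; panmictic isolates draw each
    locus independently from its allele frequencies.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_isolates
    loci = list(config.loci)

    if config.founders is not None:
        founders = [tuple(f) for f in config.founders]
    else:
        founders = [_draw_genotype(rng, loci) for _ in range(config.n_founders)]

    if config.mode == "clonal":
        n_clonal = n
    elif config.mode == "panmictic":
        n_clonal = 0
    else:
        n_clonal = round(config.clonal_fraction * n)

    rows = []
    for i in range(n):
        if i < n_clonal:
            rows.append(founders[i % len(founders)])
        else:
            rows.append(_draw_genotype(rng, loci))

    width = max(4, len(str(n)))
    ids = [f"iso{i + 1:0{width}d}" for i in range(n)]
    pops = [f"pop{(i % config.n_populations) + 1}" for i in range(n)]
    data = pd.DataFrame(rows, index=ids, columns=[spec.name for spec in loci], dtype=object)
    provenance = {
        "seed": config.seed,
        "mode": config.mode,
        "clonal_fraction": config.clonal_fraction,
        "founders": [list(f) for f in founders] if n_clonal else None,
    }
    return GenotypeMatrix(data, pd.Series(pops, index=ids), provenance)


def inject_heteroplasmy(
    matrix: GenotypeMatrix,
    het_rate: float,
    mixing_fraction: float,
    seed: int,
) -> GenotypeMatrix:
    """Turn a fraction of isolates heteroplasmic at one locus each.

    Each selected isolate receives an unordered allele pair at a single locus,
    the second allele drawn from its population's allele pool (falling back to
    the global pool if the population is monomorphic there). The injected
    truth — isolate -> (locus, (original, added)) — is recorded in the output
    provenance under ``"het_truth"`` for recovery tests. Non-selected cells
    are left bitwise unchanged.
    """
    if not 0.0 <= het_rate <= 1.0:
        raise ValueError(f"het_rate must lie in [0, 1], got {het_rate}")
    if not 0.0 < mixing_fraction <= 1.0:
        raise ValueError(f"mixing_fraction must lie in (0, 1], got {mixing_fraction}")
    if matrix.has_heterozygotes():
        raise ValueError("input matrix must be homoplasmic")

    rng = np.random.default_rng(seed)
    out = matrix.copy()
    selected = [iso for iso in out.isolates if rng.random() < het_rate]
    truth: dict[str, tuple[str, tuple[str, str]]] = {}
    for iso in selected:
        pop = out.populations[iso]
        candidates = []
        for locus in out.loci:
            own = out.data.at[iso, locus]
            if own is None:
                continue
            pool = [a for a in out.alleles_at(locus, population=pop) if a != own]
            if not pool:
                pool = [a for a in out.alleles_at(locus) if a != own]
            if pool:
                candidates.append((locus, own, pool))
        if not candidates:
            continue  # nothing polymorphic anywhere: isolate stays homoplasmic
        locus, own, pool = candidates[rng.integers(len(candidates))]
        other = pool[rng.integers(len(pool))]
        out.data.at[iso, locus] = het_entry(own, other)
        truth[iso] = (locus, (own, other))

    out.provenance["het_truth"] = truth
    out.provenance["het_rate"] = het_rate
    out.provenance["mixing_fraction"] = mixing_fraction
    out.provenance["het_seed"] = seed
    return out


# ---------------------------------------------------------------------------
# chromatogram-like traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceTruth:
    """Ground truth behind a simulated trace, kept for round-trip tests."""

    major_seq: str
    minor_seq: str
    mixing_fraction: float

    @property
    def diff_sites(self) -> tuple[int, ...]:
        """1-based positions where the two haplotypes differ."""
        return tuple(
            i + 1 for i, (a, b) in enumerate(zip(self.major_seq, self.minor_seq)) if a != b
        )


@dataclass
class TraceProfile:
    """Per-site four-channel (A, C, G, T) peak heights for one amplicon read."""

    heights: np.ndarray  # shape (n_sites, 4), non-negative fluorescence units
    truth: TraceTruth | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.shape[1] != 4:
            raise ValueError("heights must have shape (n_sites, 4)")
        if (self.heights < 0).any():
            raise ValueError("peak heights must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.heights.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """1-based site indices (chromatogram convention)."""
        return np.arange(1, self.n_sites + 1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.heights, columns=list(CHANNELS))
        frame.insert(0, "pos", self.positions)
        return frame


def simulate_trace(
    major_seq: str,
    minor_seq: str,
    mixing_fraction: float,
    signal: float = 100.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> TraceProfile:
    """Simulate a Sanger-style trace of a two-haplotype mixture.

    At every site the channel of the major base has mean ``signal``; where the
    haplotypes differ, the minor base channel has mean
    ``signal * mixing_fraction``. Additive noise is half-normal (a Gaussian of
    scale ``noise_sd`` truncated at zero), so heights stay non-negative.
    """
    if len(major_seq) != len(minor_seq):
        raise ValueError(
            f"sequences differ in length ({len(major_seq)} vs {len(minor_seq)})"
        )
    if not 0.0 < mixing_fraction <= 1.0:
        raise ValueError("mixing_fraction must lie in (0, 1]")
    for seq, name in ((major_seq, "major_seq"), (minor_seq, "minor_seq")):
        bad = set(seq) - set(CHANNELS)
        if bad:
            raise ValueError(f"{name} contains non-ACGT symbols: {sorted(bad)}")

    n = len(major_seq)
    mean = np.zeros((n, 4))
    for i, (a, b) in enumerate(zip(major_seq, minor_seq)):
        mean[i, CHANNELS.index(a)] += signal
        if b != a:
            mean[i, CHANNELS.index(b)] += signal * mixing_fraction
    rng = np.random.default_rng(seed)
    noise = np.abs(rng.normal(0.0, noise_sd, size=(n, 4))) if noise_sd > 0 else 0.0
    truth = TraceTruth(major_seq, minor_seq, mixing_fraction)
    return TraceProfile(mean + noise, truth=truth,
                        provenance={"seed": seed, "signal": signal, "noise_sd": noise_sd})


# ---------------------------------------------------------------------------
# qPCR panels
# ---------------------------------------------------------------------------

@dataclass
class CtPanel:
    """Replicate Ct values plus amplicon lengths for a qPCR run.

    ``table`` has one row per gene with columns ``gene``, ``length_bp``,
    ``is_reference`` (exactly one True: the two-copy nuclear reference), and
    ``cts`` (tuple of replicate Ct values, in cycles).
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene", "length_bp", "is_reference", "cts"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"CtPanel table missing columns: {sorted(missing)}")
        if int(self.table["is_reference"].sum()) != 1:
            raise ValueError("CtPanel needs exactly one nuclear reference row")
        for _, row in self.table.iterrows():
            if row["length_bp"] <= 0:
                raise ValueError(f"gene {row['gene']}: amplicon length must be > 0")
            cts = tuple(row["cts"])
            if len(cts) < 1:
                raise ValueError(f"gene {row['gene']}: at least one Ct replicate required")
            if any(ct <= 0 for ct in cts):
                raise ValueError(f"gene {row['gene']}: Ct values must be > 0")

    @property
    def reference(self) -> pd.Series:
        return self.table[self.table["is_reference"]].iloc[0]

    def targets(self) -> pd.DataFrame:
        return self.table[~self.table["is_reference"]]


def simulate_ct(
    true_copies: Mapping[str, float],
    lengths: Mapping[str, float],
    ref_ct: float = 17.80,
    replicate_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    ref_gene: str = "beta-tubulin",
    ref_length: float = 140.0,
) -> CtPanel:
    """Generate a Ct panel from true per-cell copy numbers.

    Inverts the threshold model ``Ln * Nn * 2**ctn = Lm * Nm * 2**ctm`` with
    the nuclear reference fixed at ``Nn = 2`` copies per cell: the noiseless
    target Ct is ``ctm = ctn + log2(2 * Ln / (Lm * Nm))``. Replicates add
    Gaussian jitter of scale ``replicate_sd`` (applied to the reference too),
    so at ``replicate_sd = 0`` the panel round-trips exactly through
    :func:`mitohet.qpcr.summarize_panel`.
    """
    if set(true_copies) != set(lengths):
        raise ValueError("true_copies and lengths must cover the same genes")
    if ref_gene in true_copies:
        raise ValueError("the nuclear reference must not appear among targets")
    for gene, copies in true_copies.items():
        if copies <= 0:
            raise ValueError(f"gene {gene}: copies per cell must be > 0")
        if lengths[gene] <= 0:
            raise ValueError(f"gene {gene}: amplicon length must be > 0")
    if ref_ct <= 0 or ref_length <= 0:
        raise ValueError("reference Ct and length must be > 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    rng = np.random.default_rng(seed)

    def _reps(ct_true: float) -> tuple[float, ...]:
        if replicate_sd > 0:
            return tuple(ct_true + rng.normal(0.0, replicate_sd, size=n_reps))
        return tuple(float(ct_true) for _ in range(n_reps))

    rows = [{"gene": ref_gene, "length_bp": float(ref_length), "is_reference": True,
             "cts": _reps(ref_ct)}]
    for gene in true_copies:
        ct_true = ref_ct + math.log2(
            NUCLEAR_COPIES * ref_length / (lengths[gene] * true_copies[gene])
        )
        rows.append({"gene": gene, "length_bp": float(lengths[gene]),
                     "is_reference": False, "cts": _reps(ct_true)})
    return CtPanel(pd.DataFrame(rows),
                   provenance={"seed": seed, "replicate_sd": replicate_sd,
                               "true_copies": dict(true_copies)})


def amplicon_detected(
    copies_per_cell: float,
    template_cells: float,
    cycles: float,
    threshold: float,
) -> bool:
    """Idealized end-point PCR detection under perfect doubling.

    True iff ``copies_per_cell * template_cells * 2**cycles >= threshold``
    molecules. This is the model behind genotyping the same samples at 25
    cycles (detecting only the abundant mitochondrial variant) versus 45
    cycles (also detecting the rare one).
    """
    if copies_per_cell <= 0 or template_cells <= 0 or cycles <= 0:
        raise ValueError("copies, cells, and cycles must be positive")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return copies_per_cell * template_cells * 2.0**cycles >= threshold
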
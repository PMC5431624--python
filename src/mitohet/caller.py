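"""Base calling and double-peak (heteroplasmy) detection from trace profiles.

A site is called heterozygous when its chromatogram shows two peaks that both
stand clearly above the local background: each of the two largest channel
heights must exceed ``k`` times the noise floor estimated from neighbouring
sites, and the minor peak must reach at least a fraction ``r`` of the major
one. Both thresholds are configurable; the defaults (k=3, r=0.2, window w=5)
operationalize "significantly higher than the basic noise level" for clean
Sanger-quality traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from .simulate import CHANNELS, TraceProfile

__all__ = [
    "CallerParams",
    "SiteCall",
    "AMBIGUITY_OF_PAIR",
    "PAIR_OF_AMBIGUITY",
    "noise_floor",
    "call_site",
    "call_trace",
    "het_sites",
    "calls_to_sequence",
    "confirm_heteroplasmy",
    "ConfirmedHet",
    "singleton_audit",
]

#: two-base IUPAC ambiguity code for each unordered base pair, e.g. {A,G} -> R
AMBIGUITY_OF_PAIR: dict[frozenset, str] = {
    frozenset(bases): code
    for code, bases in ambiguous_dna_values.items()
    if len(bases) == 2
}
PAIR_OF_AMBIGUITY: dict[str, tuple[str, str]] = {
    code: tuple(sorted(bases))
    for code, bases in ambiguous_dna_values.items()
    if len(bases) == 2
}


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the double-peak rule.

    noise_multiplier
        k: a peak counts as real only if higher than k x the noise floor.
    minor_ratio
        r: minimum minor/major height ratio for a heterozygous call.
    noise_window
        w: number of neighbouring sites on each side used for the floor.
    """

    noise_multiplier: float = 3.0
    minor_ratio: float = 0.2
    noise_window: int = 5

    def __post_init__(self) -> None:
        if self.noise_multiplier <= 1:
            raise ValueError("noise_multiplier must be > 1")
        if not 0 < self.minor_ratio <= 1:
            raise ValueError("minor_ratio must lie in (0, 1]")
        if self.noise_window < 1:
            raise ValueError("noise_window must be >= 1")


@dataclass(frozen=True)
class SiteCall:
    """Base call at one site, with the evidence behind it."""

    position: int  # 1-based
    call: str      # single base, two-base IUPAC code, or "N"
    peak_major: float
    peak_minor: float
    noise_floor: float
    is_het: bool

    def __post_init__(self) -> None:
        if self.peak_minor > self.peak_major or self.peak_minor < 0:
            raise ValueError("peaks must satisfy major >= minor >= 0")
        if self.is_het and self.call not in AMBIGUITY_OF_PAIR.values():
            raise ValueError(f"het call must be a two-base ambiguity code, got {self.call!r}")


def noise_floor(profile: TraceProfile, position: int, params: CallerParams = CallerParams()) -> float:
    """Background level around ``position`` (1-based, itself excluded).

    Median of the non-maximal channel heights over the w-site window on each
    side; windows straddling the ends are truncated. A single-site profile has
    no neighbours and gets a floor of 0.
    """
    if profile.n_sites < 1:
        raise ValueError("profile must contain at least one site")
    if not 1 <= position <= profile.n_sites:
        raise ValueError(f"position {position} outside profile of {profile.n_sites} sites")
    w = params.noise_window
    lo = max(0, position - 1 - w)
    hi = min(profile.n_sites, position + w)
    rows = [i for i in range(lo, hi) if i != position - 1]
    if not rows:
        return 0.0
    window = profile.heights[rows]  # (m, 4)
    # drop one maximal channel per site, keep the other three as background
    order = np.argsort(window, axis=1)
    background = np.take_along_axis(window, order[:, :3], axis=1)
    return float(np.median(background))


def _ranked_channels(heights: np.ndarray) -> list[int]:
    """Channel indices by descending height; ties broken alphabetically."""
    return sorted(range(4), key=lambda i: (-heights[i], CHANNELS[i]))


def call_site(profile: TraceProfile, position: int, params: CallerParams = CallerParams()) -> SiteCall:
    """Call one site: a single base, a two-base ambiguity code, or ``N``.

    Heterozygous iff the two largest peaks both exceed k x the noise floor and
    the minor/major ratio is at least r. If even the largest peak fails the
    noise test the call is ``N``. Two equal maximal peaks above noise yield a
    heterozygous call with the bases in alphabetical order.
    """
    heights = profile.heights[position - 1]
    floor = noise_floor(profile, position, params)
    first, second = _ranked_channels(heights)[:2]
    h1, h2 = float(heights[first]), float(heights[second])
    cutoff = params.noise_multiplier * floor
    if h1 <= cutoff:
        return SiteCall(position, "N", h1, h2, floor, False)
    if h2 > cutoff and h2 / h1 >= params.minor_ratio:
        pair = frozenset({CHANNELS[first], CHANNELS[second]})
        return SiteCall(position, AMBIGUITY_OF_PAIR[pair], h1, h2, floor, True)
    return SiteCall(position, CHANNELS[first], h1, h2, floor, False)


def call_trace(profile: TraceProfile, params: CallerParams = CallerParams()) -> list[SiteCall]:
    """Call every site of a trace. Deterministic in the profile and params."""
    if profile.n_sites < 1:
        raise ValueError("profile must contain at least one site")
    return [call_site(profile, pos, params) for pos in range(1, profile.n_sites + 1)]


def het_sites(calls: list[SiteCall]) -> list[int]:
    """1-based positions called heterozygous."""
    return [c.position for c in calls if c.is_het]


def calls_to_sequence(calls: list[SiteCall]) -> str:
    """IUPAC-coded consensus string, ready for the phasing stage."""
    return "".join(c.call for c in calls)


@dataclass(frozen=True)
class ConfirmedHet:
    """Replicate-confirmation outcome for putative heteroplasmic sites."""

    confirmed: frozenset  # positions het in both replicates with the same code
    unconfirmed: frozenset  # het in only one replicate, or codes disagree


def confirm_heteroplasmy(calls_a: list[SiteCall], calls_b: list[SiteCall]) -> ConfirmedHet:
    """Cross-check het calls between two independent reads of the same sample.

    A site counts as confirmed heteroplasmy only when both replicates call it
    heterozygous with the same ambiguity code; anything seen in just one
    replicate (or with conflicting codes) is reported as unconfirmed.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError(
            f"replicate call lengths differ ({len(calls_a)} vs {len(calls_b)})"
        )
    a = {c.position: c.call for c in calls_a if c.is_het}
    b = {c.position: c.call for c in calls_b if c.is_het}
    confirmed = {pos for pos in a.keys() & b.keys() if a[pos] == b[pos]}
    unconfirmed = (a.keys() | b.keys()) - confirmed
    return ConfirmedHet(frozenset(confirmed), frozenset(unconfirmed))


def singleton_audit(alignment) -> list[int]:
    """Flag sites whose rare base appears in exactly one isolate.

    Such singleton polymorphisms are the ones most likely to be sequencing
    artifacts and are returned (1-based) for chromatograph re-inspection.
    ``alignment`` is a mapping or sequence of equal-length called sequences;
    symbols outside ACGT (gaps, N, ambiguity codes) are ignored in the counts.
    """
    seqs = list(alignment.values()) if hasattr(alignment, "values") else list(alignment)
    if not seqs:
        return []
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment is ragged: sequences differ in length")
    flagged = []
    for i in range(length):
        counts: dict[str, int] = {}
        for s in seqs:
            base = s[i]
            if base in CHANNELS:
                counts[base] = counts.get(base, 0) + 1
        if len(counts) >= 2 and any(n == 1 for n in counts.values()):
            flagged.append(i + 1)
    return flagged
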
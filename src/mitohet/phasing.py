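"""Haplotype-mixture resolution and classification of heteroplasmic genotypes.

A heteroplasmic isolate carries two mitochondrial haplotypes whose Sanger
superposition is the observed IUPAC-coded sequence. With plenty of homoplasmic
isolates around, the mixture can be resolved by treating each heteroplasmic
isolate as an unordered haplotype pair and estimating population haplotype
frequencies by expectation-maximization (the classic haplotype-frequency EM
for unphased data). Each resolved genotype is then classified by whether its
two constituent haplotypes are also seen in homoplasmic isolates:

* ``local`` — both haplotypes occur homoplasmically in the isolate's own
  population (after removing the heterozygote's own copies);
* ``global`` — both occur homoplasmically somewhere in the whole sample;
* ``unexplained`` — at least one haplotype is never seen outside mixtures.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .caller import AMBIGUITY_OF_PAIR, PAIR_OF_AMBIGUITY
from .genotypes import is_het_entry, split_het_entry

__all__ = [
    "HaplotypeCatalog",
    "MixtureClass",
    "EMResult",
    "superpose",
    "consistent_pairs",
    "em_phase",
    "homoplasmic_counts",
    "classify_mixture",
    "classify_all",
]

BASES = "ACGT"


def _label_key(label: str) -> tuple:
    """Natural sort key so numeric haplotype labels order as numbers."""
    return (len(label), label) if label.isdigit() else (float("inf"), label)


def sort_pair(pair) -> tuple[str, str]:
    """Canonical unordered-pair ordering for haplotype labels."""
    a, b = sorted(pair, key=_label_key)
    return (a, b)


@dataclass
class HaplotypeCatalog:
    """Labeled haplotypes with per-population copy counts.

    Counts follow the two-copies-per-isolate convention: a homoplasmic isolate
    contributes 2 copies of its haplotype, a resolved heterozygote 1 copy of
    each constituent, so per-population counts sum to twice the sample size.
    ``het_genotypes`` lists each population's resolved heterozygous genotypes
    as unordered label pairs (one entry per heteroplasmic isolate).
    """

    counts: dict[str, Counter]
    sequences: Mapping[str, str] | None = None
    het_genotypes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    population_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.counts = {pop: Counter(c) for pop, c in self.counts.items()}
        self.het_genotypes = {
            pop: [sort_pair(pair) for pair in pairs]
            for pop, pairs in self.het_genotypes.items()
        }

    @property
    def labels(self) -> list[str]:
        out: set[str] = set()
        for counter in self.counts.values():
            out.update(counter)
        return sorted(out, key=_label_key)

    def total_counts(self) -> Counter:
        total: Counter = Counter()
        for counter in self.counts.values():
            total.update(counter)
        return total

    def consistency_report(self) -> list[str]:
        """Populations whose counts do not sum to 2 x the sample size."""
        problems = []
        if self.population_sizes:
            for pop, size in self.population_sizes.items():
                got = sum(self.counts.get(pop, Counter()).values())
                if got != 2 * size:
                    problems.append(
                        f"population {pop}: copy counts sum to {got}, expected {2 * size}"
                    )
        return problems


# ---------------------------------------------------------------------------
# superposition arithmetic on IUPAC sequences
# ---------------------------------------------------------------------------

def superpose(seq_a: str, seq_b: str) -> str | None:
    """Site-wise superposition of two plain haplotype sequences.

    Equal bases stay; differing bases become the two-base ambiguity code (what
    a chromatogram of the mixture would show). Returns None if either input
    itself contains non-ACGT symbols.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    out = []
    for a, b in zip(seq_a, seq_b):
        if a not in BASES or b not in BASES:
            return None
        out.append(a if a == b else AMBIGUITY_OF_PAIR[frozenset({a, b})])
    return "".join(out)


def _matches(hap: str, het_seq: str) -> bool:
    """True if ``hap`` could be one constituent of the observed mixture."""
    for h, obs in zip(hap, het_seq):
        if obs in BASES:
            if h != obs:
                return False
        elif obs in PAIR_OF_AMBIGUITY:
            if h not in PAIR_OF_AMBIGUITY[obs]:
                return False
        else:
            return False
    return True


def _partner_of(hap: str, het_seq: str) -> str:
    """The unique second haplotype completing ``hap`` into ``het_seq``."""
    out = []
    for h, obs in zip(hap, het_seq):
        if obs in BASES:
            out.append(obs)
        else:
            a, b = PAIR_OF_AMBIGUITY[obs]
            out.append(b if h == a else a)
    return "".join(out)


def consistent_pairs(het_sequence: str, catalog: HaplotypeCatalog) -> list[tuple[str, str]]:
    """All catalog haplotype pairs whose superposition equals ``het_sequence``.

    If no catalog pair fits, each single catalog haplotype that matches the
    mixture is completed with the (novel) partner sequence it implies; the
    novel member is reported by its raw sequence instead of a catalog label.
    Returns an empty list when nothing in the catalog matches at all.
    """
    if catalog.sequences is None:
        raise ValueError("catalog carries no haplotype sequences")
    amb = [ch for ch in het_sequence if ch not in BASES]
    if not amb:
        raise ValueError("het_sequence has no ambiguity code; nothing to resolve")
    if any(ch not in PAIR_OF_AMBIGUITY for ch in amb):
        bad = sorted(set(amb) - set(PAIR_OF_AMBIGUITY))
        raise ValueError(f"unsupported symbols in het sequence: {bad}")

    labels = sorted(catalog.sequences)
    pairs = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            sup = superpose(catalog.sequences[la], catalog.sequences[lb])
            if sup == het_sequence:
                pairs.append(tuple(sorted((la, lb))))
    if pairs:
        return pairs
    seq_to_label = {seq: label for label, seq in catalog.sequences.items()}
    for label in labels:
        hap = catalog.sequences[label]
        if len(hap) == len(het_sequence) and _matches(hap, het_sequence):
            partner = _partner_of(hap, het_sequence)
            if partner in seq_to_label:
                pairs.append(tuple(sorted((label, seq_to_label[partner]))))
            else:
                pairs.append((label, partner))  # catalog member first, novel second
    return sorted(set(pairs))


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    """Outcome of :func:`em_phase`."""

    frequencies: dict
    resolutions: dict  # isolate -> (unordered haplotype pair, posterior)
    loglik: list[float]
    converged: bool
    n_iter: int


def _genotype_to_vector(genotype) -> tuple:
    """Normalize a genotype to a tuple of entries (allele or unordered pair)."""
    if isinstance(genotype, str):
        entries: list = []
        for ch in genotype:
            if ch in PAIR_OF_AMBIGUITY:
                entries.append(PAIR_OF_AMBIGUITY[ch])
            else:
                entries.append(ch)
        return tuple(entries)
    entries = []
    for entry in genotype:
        if is_het_entry(entry):
            entries.append(split_het_entry(entry))
        elif isinstance(entry, (tuple, frozenset, set)):
            pair = tuple(sorted(entry))
            if len(pair) != 2:
                raise ValueError(f"heterozygous entry must have two alleles, got {entry!r}")
            entries.append(pair)
        else:
            entries.append(entry)
    return tuple(entries)


def _expand_pairs(vector: tuple) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs whose superposition gives ``vector``."""
    het_positions = [i for i, e in enumerate(vector) if isinstance(e, tuple)]
    if not het_positions:
        hap = tuple(vector)
        return [(hap, hap)]
    pairs = []
    k = len(het_positions)
    for mask in range(2 ** (k - 1)):  # fix the first het site to kill mirror duplicates
        h1, h2 = list(vector), list(vector)
        for bit, pos in enumerate(het_positions):
            a, b = vector[pos]
            if bit == 0:
                pick = 0
            else:
                pick = (mask >> (bit - 1)) & 1
            h1[pos] = (a, b)[pick]
            h2[pos] = (a, b)[1 - pick]
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        pairs.append(pair)
    return sorted(set(pairs))


def em_phase(
    population_calls,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
) -> EMResult:
    """Estimate haplotype frequencies and resolve heteroplasmic isolates.

    ``population_calls`` maps isolate id -> genotype, where a genotype is
    either an IUPAC-coded sequence string or a sequence of per-locus entries
    (allele label, or an unordered pair for heteroplasmic loci). Homoplasmic
    isolates contribute two copies of their haplotype; each heteroplasmic one
    is treated as an unordered pair over all haplotype resolutions of its
    ambiguous sites. Plain Hardy-Weinberg-style EM: the E step weights each
    candidate pair by ``f_a * f_b`` (doubled for distinct haplotypes), the M
    step re-estimates frequencies from expected copy counts. Iteration stops
    when the largest frequency change drops below ``tol``; running out of
    ``max_iter`` raises a warning and sets ``converged=False``.

    The ``seed`` only matters for the (deterministic by default) tie-break of
    equally likely resolutions and is accepted for interface symmetry.
    """
    if hasattr(population_calls, "items"):
        items = list(population_calls.items())
    else:
        items = [(f"iso{i + 1}", g) for i, g in enumerate(population_calls)]
    if not items:
        raise ValueError("at least one genotype is required")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    as_string = isinstance(items[0][1], str)
    vectors = {iso: _genotype_to_vector(g) for iso, g in items}
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError("genotypes differ in length")

    pair_sets = {iso: _expand_pairs(v) for iso, v in vectors.items()}
    candidates = sorted({h for pairs in pair_sets.values() for p in pairs for h in p})
    n = len(items)
    freq = {h: 1.0 / len(candidates) for h in candidates}

    loglik: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = {h: 0.0 for h in candidates}
        ll = 0.0
        for iso in vectors:
            pairs = pair_sets[iso]
            weights = [(2.0 if a != b else 1.0) * freq[a] * freq[b] for a, b in pairs]
            norm = sum(weights)
            if norm <= 0.0:
                weights = [1.0] * len(pairs)
                norm = float(len(pairs))
            else:
                ll += math.log(norm)
            for (a, b), w in zip(pairs, weights):
                counts[a] += w / norm
                counts[b] += w / norm
        loglik.append(ll)
        new = {h: counts[h] / (2.0 * n) for h in candidates}
        delta = max(abs(new[h] - freq[h]) for h in candidates)
        freq = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations", RuntimeWarning)

    resolutions = {}
    for iso in vectors:
        pairs = pair_sets[iso]
        weights = [(2.0 if a != b else 1.0) * freq[a] * freq[b] for a, b in pairs]
        norm = sum(weights)
        if norm <= 0.0:
            weights = [1.0] * len(pairs)
            norm = float(len(pairs))
        best_i = max(range(len(pairs)), key=lambda i: (weights[i], pairs[i]))
        resolutions[iso] = (pairs[best_i], weights[best_i] / norm)

    def _out_hap(h: tuple):
        return "".join(h) if as_string else h

    return EMResult(
        frequencies={_out_hap(h): f for h, f in freq.items()},
        resolutions={
            iso: ((_out_hap(a), _out_hap(b)), post)
            for iso, ((a, b), post) in resolutions.items()
        },
        loglik=loglik,
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# mixture classification against homoplasmic references
# ---------------------------------------------------------------------------

class DataInconsistencyError(ValueError):
    """Copy-count bookkeeping went negative: counts and genotypes disagree."""


def homoplasmic_counts(
    catalog: HaplotypeCatalog,
    het_genotypes: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> dict[str, Counter]:
    """Per-population haplotype copy counts attributable to homoplasmic isolates.

    Subtracts one copy per occurrence of a haplotype inside a heterozygous
    genotype of that population from the catalog's (heterozygote-inclusive)
    counts. Raises :class:`DataInconsistencyError` if a subtraction would go
    negative, naming the population and haplotype.
    """
    hets = catalog.het_genotypes if het_genotypes is None else het_genotypes
    out: dict[str, Counter] = {pop: Counter(c) for pop, c in catalog.counts.items()}
    for pop, pairs in hets.items():
        counter = out.setdefault(pop, Counter())
        for pair in pairs:
            for hap in pair:
                counter[hap] -= 1
                if counter[hap] < 0:
                    raise DataInconsistencyError(
                        f"population {pop}: haplotype {hap} count went negative "
                        "while removing heterozygote copies"
                    )
    return out


@dataclass(frozen=True)
class MixtureClass:
    """Classification of one heteroplasmic genotype.

    ``label`` is ``"local"`` (both haplotypes homoplasmic in the isolate's own
    population), ``"global"`` (both homoplasmic somewhere in the full sample),
    or ``"unexplained"``. Local implies global by construction.
    """

    genotype: tuple[str, str]
    population: str
    label: str


def classify_mixture(
    genotype: Iterable[str],
    population: str,
    catalog: HaplotypeCatalog,
) -> MixtureClass:
    """Classify one heterozygous genotype as local / global / unexplained.

    The homoplasmic evidence is the catalog's copy counts after removing every
    heterozygote's own contributions (:func:`homoplasmic_counts`); a haplotype
    counts as present when at least one residual copy remains.
    """
    pair = sort_pair(genotype)
    if len(pair) != 2 or pair[0] == pair[1]:
        raise ValueError(f"genotype must hold two distinct haplotype labels, got {pair}")
    known = set(catalog.total_counts())
    unknown = [h for h in pair if h not in known]
    if unknown:
        raise KeyError(f"unknown haplotype label(s) {unknown} for catalog")
    residual = homoplasmic_counts(catalog)
    if population not in residual:
        raise KeyError(f"unknown population {population!r}")
    if all(residual[population][h] >= 1 for h in pair):
        label = "local"
    else:
        total: Counter = Counter()
        for counter in residual.values():
            total.update(counter)
        label = "global" if all(total[h] >= 1 for h in pair) else "unexplained"
    return MixtureClass(pair, population, label)


def classify_all(catalog: HaplotypeCatalog) -> list[MixtureClass]:
    """Classify every heterozygous genotype recorded in the catalog."""
    out = []
    for pop in sorted(catalog.het_genotypes):
        for pair in catalog.het_genotypes[pop]:
            out.append(classify_mixture(pair, pop, catalog))
    return out
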
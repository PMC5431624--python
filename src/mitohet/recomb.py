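"""Multilocus clonality and recombination inference.

Implements the classic haploid linkage-disequilibrium toolkit: the index of
association I_A and its locus-count-corrected form rbar_d, a within-locus
allele-shuffling permutation null, the generalized four-gamete (phylogenetic
compatibility) test for pairs of multi-allelic loci, clone correction, and a
sites-as-loci converter for intra-genic analyses.

Conventions
-----------
* I_A = V_O / V_E - 1 and rbar_d = (V_O - V_E) / (2 * sum_{j<k}
  sqrt(var_j * var_k)), where V_O is the variance over isolate pairs of the
  multilocus mismatch distance, var_j the per-locus mismatch-indicator
  variance, and V_E = sum_j var_j. Variances use the population denominator
  (divide by the number of pairs).
* Missing data are handled by pairwise deletion: a pair's distance counts
  only loci typed in both isolates, and a locus pair's compatibility uses
  only isolates typed at both loci.
* Heterozygous cells are excluded (treated as missing) by default; phase them
  first with :mod:`mitohet.phasing` if they should contribute.
* Permutation p-values use (1 + b) / (1 + n), never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, is_het_entry

__all__ = [
    "IaResult",
    "PermutationTest",
    "IncompatibilityTest",
    "RecombReport",
    "mismatch_distance",
    "ia_rbard",
    "permute_matrix",
    "ia_test",
    "pairwise_compatible",
    "compatibility_matrix",
    "pcp",
    "incompatibility_test",
    "clone_correct",
    "sites_to_loci",
    "recomb_report",
]

_MISSING = -1


def _encode(matrix: GenotypeMatrix) -> np.ndarray:
    """Integer-code the matrix; missing and heterozygous cells become -1."""
    if matrix.n_isolates < 2:
        raise ValueError("at least two isolates are required")
    if matrix.n_loci < 1:
        raise ValueError("at least one locus is required")
    codes = np.full((matrix.n_isolates, matrix.n_loci), _MISSING, dtype=np.int64)
    had_het = False
    for j, locus in enumerate(matrix.loci):
        col = matrix.data[locus].to_numpy(dtype=object)
        mapping: dict[str, int] = {}
        for i, value in enumerate(col):
            if value is None:
                continue
            if is_het_entry(value):
                had_het = True
                continue
            codes[i, j] = mapping.setdefault(value, len(mapping))
    if had_het:
        warnings.warn(
            "heterozygous entries excluded from recombination statistics; "
            "phase them first to include them", UserWarning,
        )
    return codes


def mismatch_distance(g1: Sequence, g2: Sequence) -> int | None:
    """Number of loci at which two genotype rows differ.

    Counted over loci non-missing (``None``) in both rows. Returns ``None``
    (with a warning) when the rows share no typed locus.
    """
    if len(g1) != len(g2):
        raise ValueError("genotype rows cover different loci")
    shared = [(a, b) for a, b in zip(g1, g2) if a is not None and b is not None]
    if not shared:
        warnings.warn("genotype pair shares no typed locus; distance undefined", UserWarning)
        return None
    return sum(1 for a, b in shared if a != b)


@dataclass(frozen=True)
class IaResult:
    """Index of association and rbar_d, with the variance components."""

    ia: float
    rbard: float
    v_o: float
    v_e: float
    defined: bool  # False when the data are monomorphic (V_E = 0)


def _ia_from_codes(codes: np.ndarray) -> IaResult:
    n, n_loci = codes.shape
    iu, ju = np.triu_indices(n, k=1)
    total = np.zeros(len(iu))
    variances = []
    for j in range(n_loci):
        col = codes[:, j]
        neq = (col[iu] != col[ju])
        valid = (col[iu] != _MISSING) & (col[ju] != _MISSING)
        mismatch = neq & valid
        total += mismatch
        n_valid = int(valid.sum())
        if n_valid == 0:
            variances.append(0.0)
        else:
            p = mismatch.sum() / n_valid
            variances.append(p * (1.0 - p))
    v_o = float(np.var(total))  # population denominator
    v_e = float(sum(variances))
    if v_e == 0.0:
        return IaResult(float("nan"), float("nan"), v_o, v_e, False)
    ia = v_o / v_e - 1.0
    cross = sum(
        np.sqrt(variances[j] * variances[k])
        for j, k in combinations(range(n_loci), 2)
    )
    rbard = (v_o - v_e) / (2.0 * cross) if cross > 0 else float("nan")
    return IaResult(ia, rbard, v_o, v_e, True)


def ia_rbard(matrix: GenotypeMatrix) -> IaResult:
    """I_A and rbar_d for a genotype matrix.

    Monomorphic data (V_E = 0) yield an undefined-flagged result; a single
    locus gives I_A = 0 (V_O = V_E identically) with rbar_d undefined.
    """
    return _ia_from_codes(_encode(matrix))


def permute_matrix(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """One artificially recombined dataset: shuffle alleles within each locus.

    Alleles are permuted independently per locus across isolates, so each
    locus keeps its exact allele proportions while all between-locus
    associations are destroyed. Missing cells stay missing in place.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for locus in out.loci:
        col = out.data[locus].to_numpy(dtype=object).copy()
        typed = np.array([v is not None for v in col])
        idx = np.flatnonzero(typed)
        col[idx] = col[rng.permutation(idx)]
        out.data[locus] = col
    out.provenance = dict(out.provenance, permuted_seed=seed)
    return out


def _permuted_codes(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    for j in range(codes.shape[1]):
        idx = np.flatnonzero(out[:, j] != _MISSING)
        out[idx, j] = out[rng.permutation(idx), j]
    return out


@dataclass(frozen=True)
class PermutationTest:
    """Observed I_A against the allele-shuffling null."""

    observed: IaResult
    p_value: float
    null_mean: float
    n_perm: int
    seed: int


def ia_test(matrix: GenotypeMatrix, n_perm: int = 500, seed: int = 0) -> PermutationTest:
    """One-sided permutation test of the index of association.

    Clonality inflates I_A, so p = (1 + #{permuted I_A >= observed}) /
    (1 + n_perm). Reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = _encode(matrix)
    observed = _ia_from_codes(codes)
    if not observed.defined:
        raise ValueError("I_A undefined on monomorphic data; nothing to test")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _ia_from_codes(_permuted_codes(codes, rng)).ia
    exceed = int(np.sum(null >= observed.ia))
    return PermutationTest(
        observed=observed,
        p_value=(1 + exceed) / (1 + n_perm),
        null_mean=float(np.nanmean(null)),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# phylogenetic compatibility (generalized four-gamete test)
# ---------------------------------------------------------------------------

def _combo_edges(codes_j: np.ndarray, codes_k: np.ndarray) -> set[tuple[int, int]]:
    both = (codes_j != _MISSING) & (codes_k != _MISSING)
    return set(zip(codes_j[both].tolist(), codes_k[both].tolist()))


def _compatible_from_edges(edges: set[tuple[int, int]]) -> bool:
    graph = nx.Graph()
    for a, b in edges:
        graph.add_edge(("j", a), ("k", b))
    if graph.number_of_nodes() == 0:
        return True
    # a forest (no cycle) means every observed allele combination fits one tree
    return graph.number_of_edges() == graph.number_of_nodes() - nx.number_connected_components(graph)


def pairwise_compatible(matrix: GenotypeMatrix, locus_j: str, locus_k: str) -> bool:
    """Phylogenetic compatibility of two (possibly multi-allelic) loci.

    Observed allele combinations are edges of a bipartite graph with the two
    loci's alleles as vertex sets; the loci are compatible iff that graph is
    acyclic. For two biallelic loci this is exactly the four-gamete test
    (compatible iff at most three of the four gametes occur), and in general
    it is equivalent to the marked-box rule: incompatible iff one can leave a
    marked cell of the allele-combination table and return to it by
    alternating row/column moves through marked cells.
    """
    codes = _encode(matrix)
    j = matrix.loci.index(locus_j)
    k = matrix.loci.index(locus_k)
    edges = _combo_edges(codes[:, j], codes[:, k])
    if not edges:
        raise ValueError(f"no isolate typed at both {locus_j} and {locus_k}")
    return _compatible_from_edges(edges)


def compatibility_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Boolean locus x locus compatibility table (diagonal True)."""
    codes = _encode(matrix)
    loci = matrix.loci
    out = pd.DataFrame(True, index=loci, columns=loci)
    for j, k in combinations(range(len(loci)), 2):
        edges = _combo_edges(codes[:, j], codes[:, k])
        compat = _compatible_from_edges(edges)
        out.iloc[j, k] = out.iloc[k, j] = compat
    return out


def pcp(matrix: GenotypeMatrix) -> float:
    """Proportion of unordered locus pairs that are phylogenetically compatible."""
    if matrix.n_loci < 2:
        raise ValueError("PcP needs at least two loci")
    compat = compatibility_matrix(matrix)
    n = matrix.n_loci
    vals = [compat.iloc[j, k] for j, k in combinations(range(n), 2)]
    return float(np.mean(vals))


def _incompat_count(codes: np.ndarray) -> int:
    n_loci = codes.shape[1]
    return sum(
        not _compatible_from_edges(_combo_edges(codes[:, j], codes[:, k]))
        for j, k in combinations(range(n_loci), 2)
    )


@dataclass(frozen=True)
class IncompatibilityTest:
    """Observed incompatible-pair count against artificially recombined data.

    ``p_value`` is the probability (plus-one corrected) that a randomly
    recombined dataset shows as few or fewer incompatible pairs as observed —
    small when the data carry markedly less homoplasy than free recombination
    would generate, i.e. when they look clonal. ``frac_null_ge`` reports the
    opposite tail for completeness.
    """

    observed_count: int
    n_pairs: int
    p_value: float
    frac_null_ge: float
    null_mean: float
    n_perm: int
    seed: int


def incompatibility_test(matrix: GenotypeMatrix, n_perm: int = 500, seed: int = 0) -> IncompatibilityTest:
    """Permutation test of the number of phylogenetically incompatible pairs."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if matrix.n_loci < 2:
        raise ValueError("at least two loci are required")
    codes = _encode(matrix)
    observed = _incompat_count(codes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        null[b] = _incompat_count(_permuted_codes(codes, rng))
    n_pairs = matrix.n_loci * (matrix.n_loci - 1) // 2
    return IncompatibilityTest(
        observed_count=observed,
        n_pairs=n_pairs,
        p_value=(1 + int(np.sum(null <= observed))) / (1 + n_perm),
        frac_null_ge=(1 + int(np.sum(null >= observed))) / (1 + n_perm),
        null_mean=float(null.mean()),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# clone correction and sites-as-loci
# ---------------------------------------------------------------------------

def clone_correct(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep one representative isolate per distinct multilocus genotype.

    The representative is the lexicographically smallest isolate id carrying
    the genotype (missing cells count as part of the genotype). Idempotent.
    """
    seen: dict[tuple, str] = {}
    for iso in sorted(matrix.isolates):
        key = tuple(matrix.data.loc[iso])
        seen.setdefault(key, iso)
    keep = sorted(seen.values(), key=matrix.isolates.index)
    out = GenotypeMatrix(
        matrix.data.loc[keep].copy(),
        matrix.populations.loc[keep].copy(),
        dict(matrix.provenance, clone_corrected=True),
    )
    return out


def sites_to_loci(
    alignment: Mapping[str, str],
    populations: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Turn an alignment into a genotype matrix with one locus per polymorphic site.

    Alleles are the bases themselves; monomorphic sites are dropped; ``N`` and
    ``-`` become missing. Two-base ambiguity codes are rejected — resolve
    heteroplasmic isolates with the phasing stage (or exclude them) first.
    Locus names are ``site<pos>`` with 1-based positions.
    """
    ids = sorted(alignment)
    if not ids:
        raise ValueError("alignment is empty")
    seqs = [alignment[i] for i in ids]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment is ragged: sequences differ in length")
    ambiguous = {"R", "Y", "S", "W", "K", "M"}
    columns = {}
    for pos in range(length):
        col = [s[pos] for s in seqs]
        bad = set(col) & ambiguous
        if bad:
            raise ValueError(
                f"ambiguity code(s) {sorted(bad)} at site {pos + 1}: "
                "phase heteroplasmic isolates before the sites-as-loci analysis"
            )
        cells = [b if b in "ACGT" else None for b in col]
        if len({c for c in cells if c is not None}) >= 2:
            columns[f"site{pos + 1}"] = cells
    data = pd.DataFrame(columns, index=ids, dtype=object)
    if populations is None:
        pops = pd.Series("all", index=ids)
    else:
        pops = pd.Series({i: populations[i] for i in ids})
    return GenotypeMatrix(data, pops, {"source": "sites_to_loci", "n_sites": length})


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

@dataclass
class RecombReport:
    """Everything the recombination analysis of one sample produces."""

    ia: float
    rbard: float
    p_ia: float
    p_incompat: float
    pcp: float
    compat_matrix: pd.DataFrame
    n_isolates: int
    n_loci: int
    n_perm: int
    seed: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "IA": self.ia,
            "rbarD": self.rbard,
            "p_IA": self.p_ia,
            "p_incompat": self.p_incompat,
            "PcP": self.pcp,
            "n_isolates": self.n_isolates,
            "n_loci": self.n_loci,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "compat_matrix": {
                locus: self.compat_matrix[locus].tolist() for locus in self.compat_matrix
            },
            "notes": self.notes,
        }

    def summary_row(self) -> str:
        """Human-readable one-liner with significance stars (p<0.05 *, p<0.01 **)."""
        def stars(p: float) -> str:
            return "**" if p < 0.01 else "*" if p < 0.05 else ""
        return (
            f"n={self.n_isolates}\tIA={self.ia:.3f}{stars(self.p_ia)}\t"
            f"rbarD={self.rbard:.3f}{stars(self.p_ia)}\tPcP={self.pcp:.3f}{stars(self.p_incompat)}"
        )


def recomb_report(
    matrix: GenotypeMatrix,
    n_perm: int = 500,
    seed: int = 0,
    clone_corrected: bool = False,
) -> RecombReport:
    """Run the full clonality/recombination battery on one sample."""
    notes = []
    if clone_corrected:
        matrix = clone_correct(matrix)
        notes.append(f"clone-corrected to {matrix.n_isolates} distinct genotypes")
    test = ia_test(matrix, n_perm=n_perm, seed=seed)
    if matrix.n_loci >= 2:
        proportion = pcp(matrix)
        incompat = incompatibility_test(matrix, n_perm=n_perm, seed=seed)
        p_incompat = incompat.p_value
        compat = compatibility_matrix(matrix)
    else:
        proportion, p_incompat = 1.0, 1.0
        compat = pd.DataFrame(True, index=matrix.loci, columns=matrix.loci)
        notes.append("single locus: compatibility trivially 1")
    return RecombReport(
        ia=test.observed.ia,
        rbard=test.observed.rbard,
        p_ia=test.p_value,
        p_incompat=p_incompat,
        pcp=proportion,
        compat_matrix=compat,
        n_isolates=matrix.n_isolates,
        n_loci=matrix.n_loci,
        n_perm=n_perm,
        seed=seed,
        notes=notes,
    )
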
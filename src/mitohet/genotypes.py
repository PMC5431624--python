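"""Multilocus haploid genotype matrix shared across the pipeline.

The container holds one allele label per (isolate, locus) cell. A cell may be
missing (``None``) or heteroplasmic, in which case it stores the unordered
allele pair as ``"a/b"`` with the two labels in lexicographic order. Population
labels ride along as a parallel series indexed by isolate id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

HET_SEP = "/"

__all__ = ["GenotypeMatrix", "HET_SEP", "het_entry", "is_het_entry", "split_het_entry"]


def het_entry(a: str, b: str) -> str:
    """Canonical string encoding of an unordered heterozygous allele pair."""
    if a == b:
        raise ValueError(f"heterozygous entry needs two distinct alleles, got {a!r} twice")
    a, b = sorted((a, b))
    return f"{a}{HET_SEP}{b}"


def is_het_entry(value: object) -> bool:
    return isinstance(value, str) and HET_SEP in value


def split_het_entry(value: str) -> tuple[str, str]:
    a, _, b = value.partition(HET_SEP)
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeMatrix:
    """Isolates x loci allele-label matrix with population tags.

    Parameters
    ----------
    data
        DataFrame indexed by isolate id with one object-dtype column per locus.
        ``None`` marks missing; ``"a/b"`` marks an unordered heterozygous pair.
    populations
        Series mapping isolate id -> population label, aligned with ``data``.
    provenance
        Free-form metadata (seed, simulation mode, injected-heteroplasmy truth).
    """

    data: pd.DataFrame
    populations: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.astype(object).where(self.data.notna(), None)
        if not self.data.index.is_unique:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate isolate ids: {dups}")
        self.populations = self.populations.reindex(self.data.index)
        # normalize heterozygous cells to sorted "a/b"
        for locus in self.data.columns:
            col = self.data[locus]
            for iso, value in col.items():
                if is_het_entry(value):
                    self.data.at[iso, locus] = het_entry(*value.split(HET_SEP))

    # -- basic introspection ------------------------------------------------
    @property
    def isolates(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_isolates(self) -> int:
        return len(self.data.index)

    @property
    def n_loci(self) -> int:
        return len(self.data.columns)

    def alleles_at(self, locus: str, population: str | None = None) -> list[str]:
        """Distinct homoplasmic allele labels observed at ``locus``."""
        col = self.data[locus]
        if population is not None:
            col = col[self.populations == population]
        seen: set[str] = set()
        for value in col:
            if value is None:
                continue
            if is_het_entry(value):
                seen.update(split_het_entry(value))
            else:
                seen.add(value)
        return sorted(seen)

    def het_entries(self) -> Iterator[tuple[str, str, tuple[str, str]]]:
        """Yield (isolate, locus, (a, b)) for every heterozygous cell."""
        for locus in self.data.columns:
            for iso, value in self.data[locus].items():
                if is_het_entry(value):
                    yield iso, locus, split_het_entry(value)

    def has_heterozygotes(self) -> bool:
        return any(True for _ in self.het_entries())

    # -- derived matrices ---------------------------------------------------
    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.data.copy(), self.populations.copy(), dict(self.provenance))

    def mask_heterozygotes(self) -> "GenotypeMatrix":
        """Return a copy with heterozygous cells set to missing."""
        out = self.copy()
        for iso, locus, _pair in self.het_entries():
            out.data.at[iso, locus] = None
        return out

    def subset_population(self, population: str) -> "GenotypeMatrix":
        keep = self.populations == population
        return GenotypeMatrix(
            self.data.loc[keep], self.populations.loc[keep], dict(self.provenance)
        )

    def row(self, isolate: str) -> pd.Series:
        return self.data.loc[isolate]
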
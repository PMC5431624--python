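"""Readers, writers, packaged reference tables, and run configuration.

All on-disk formats are plain text: TSV for genotype matrices, traces and Ct
panels; FASTA for haplotype catalogs. Site coordinates are 1-based
(chromatogram convention) everywhere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .genotypes import GenotypeMatrix, het_entry, is_het_entry
from .phasing import HaplotypeCatalog
from .simulate import CHANNELS, CtPanel, TraceProfile

__all__ = [
    "ParseError",
    "read_genotype_table",
    "write_genotype_table",
    "read_trace_table",
    "write_trace_table",
    "read_ct_table",
    "write_ct_table",
    "read_haplotype_fasta",
    "write_haplotype_fasta",
    "load_cox3_survey",
    "read_haplotype_survey",
    "load_qpcr_survey",
    "RunConfig",
    "provenance_header",
]


class ParseError(ValueError):
    """A file did not match the expected layout."""


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def read_genotype_table(path) -> GenotypeMatrix:
    """Read a genotype TSV: columns isolate_id, population, then one per locus.

    Heterozygous cells use ``a/b`` (normalized to lexicographic order), empty
    cells are missing. Round-trips byte-identically with
    :func:`write_genotype_table` for canonical files.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in ("isolate_id", "population"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if frame.columns[0] != "isolate_id" or frame.columns[1] != "population":
        raise ParseError(f"{path}: first two columns must be isolate_id, population")
    dup = frame["isolate_id"][frame["isolate_id"].duplicated()]
    if not dup.empty:
        lines = [str(i + 2) for i in dup.index]  # +2: header plus 1-based
        raise ParseError(
            f"{path}: duplicate isolate id(s) {sorted(set(dup))} at line(s) {lines}"
        )
    loci = [c for c in frame.columns[2:]]
    data = frame[loci].copy()
    data.index = frame["isolate_id"]
    data = data.where(data != "", None)
    for locus in loci:
        for iso, value in data[locus].items():
            if is_het_entry(value):
                parts = value.split("/")
                if len(parts) != 2 or not all(parts):
                    row = frame.index[frame["isolate_id"] == iso][0] + 2
                    raise ParseError(f"{path}: malformed heterozygote {value!r} at line {row}")
                data.at[iso, locus] = het_entry(*parts)
    pops = pd.Series(frame["population"].to_numpy(), index=data.index)
    return GenotypeMatrix(data, pops, {"source": str(path)})


def write_genotype_table(matrix: GenotypeMatrix, path, header_lines: list[str] | None = None) -> None:
    frame = matrix.data.copy()
    frame = frame.where(frame.notna(), "")
    frame.insert(0, "population", matrix.populations)
    frame.insert(0, "isolate_id", frame.index)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def read_trace_table(path) -> TraceProfile:
    """Read a trace TSV with columns pos, A, C, G, T (pos is 1-based)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    needed = ["pos", *CHANNELS]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    frame = frame.sort_values("pos")
    expected = np.arange(1, len(frame) + 1)
    if not np.array_equal(frame["pos"].to_numpy(), expected):
        raise ParseError(f"{path}: positions must run 1..{len(frame)} without gaps")
    return TraceProfile(frame[list(CHANNELS)].to_numpy(float), provenance={"source": str(path)})


def write_trace_table(profile: TraceProfile, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ct panels
# ---------------------------------------------------------------------------

def read_ct_table(path) -> CtPanel:
    """Read a Ct TSV: gene, length_bp, is_reference, then ct_1..ct_n columns."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene", "length_bp", "is_reference"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ct_cols = [c for c in frame.columns if c.startswith("ct_")]
    if not ct_cols:
        raise ParseError(f"{path}: no ct_<i> replicate columns found")
    rows = []
    for _, row in frame.iterrows():
        cts = tuple(float(row[c]) for c in ct_cols if pd.notna(row[c]))
        rows.append({
            "gene": row["gene"],
            "length_bp": float(row["length_bp"]),
            "is_reference": bool(int(row["is_reference"])),
            "cts": cts,
        })
    return CtPanel(pd.DataFrame(rows), provenance={"source": str(path)})


def write_ct_table(panel: CtPanel, path, header_lines: list[str] | None = None) -> None:
    n_max = max(len(row["cts"]) for _, row in panel.table.iterrows())
    records = []
    for _, row in panel.table.iterrows():
        rec = {"gene": row["gene"], "length_bp": row["length_bp"],
               "is_reference": int(row["is_reference"])}
        for i in range(n_max):
            rec[f"ct_{i + 1}"] = row["cts"][i] if i < len(row["cts"]) else ""
        records.append(rec)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(records).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# haplotype FASTA
# ---------------------------------------------------------------------------

def read_haplotype_fasta(path) -> dict[str, str]:
    """Read haplotypes (or IUPAC-coded consensus calls) from FASTA."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_haplotype_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=label, description="") for label, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def read_haplotype_survey(path) -> HaplotypeCatalog:
    """Read a per-population haplotype survey TSV into a catalog.

    Columns: ``population``, ``n_isolates`` (successfully typed sample size),
    ``haplotype_counts`` (``label:copies`` pairs, ``;``-separated, including
    heterozygote contributions), and optional ``het_genotypes``
    (``a/b`` pairs, ``,``-separated). Internal inconsistencies (counts not
    summing to twice the sample size) are reported by
    :meth:`HaplotypeCatalog.consistency_report`, never silently fixed.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    needed = {"population", "n_isolates", "haplotype_counts"}
    missing = needed - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    if frame.empty:
        raise ParseError(f"{path}: survey has no populations")
    counts: dict = {}
    sizes: dict[str, int] = {}
    hets: dict[str, list[tuple[str, str]]] = {}
    for line_no, row in frame.iterrows():
        pop = row["population"]
        try:
            sizes[pop] = int(row["n_isolates"])
            pop_counts = {}
            for item in row["haplotype_counts"].split(";"):
                label, _, value = item.strip().partition(":")
                pop_counts[label] = int(value)
            counts[pop] = pop_counts
            raw_hets = row.get("het_genotypes", "")
            if raw_hets:
                pairs = []
                for token in raw_hets.split(","):
                    a, _, b = token.strip().partition("/")
                    if not a or not b:
                        raise ValueError(f"malformed genotype {token!r}")
                    pairs.append(tuple(sorted((a, b))))
                hets[pop] = pairs
        except ValueError as exc:
            raise ParseError(f"{path}: line {line_no + 2}: {exc}") from exc
    return HaplotypeCatalog(counts=counts, het_genotypes=hets, population_sizes=sizes)


def load_cox3_survey() -> HaplotypeCatalog:
    """The packaged COX3 haplotype survey: 27 populations, 284 typed isolates,
    12 haplotypes, and the 12 resolved heteroplasmic genotypes."""
    with resources.as_file(
        resources.files("mitohet.data") / "cox3_haplotype_survey.tsv"
    ) as path:
        return read_haplotype_survey(path)


def load_qpcr_survey() -> pd.DataFrame:
    """The packaged qPCR reference panel: mean +/- SD Ct values and published
    per-cell copy numbers for six strains across five amplicons."""
    with resources.as_file(resources.files("mitohet.data") / "qpcr_ct_survey.tsv") as path:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Stage parameters shared by the CLI subcommands."""

    seed: int = 0
    caller: dict = field(default_factory=dict)      # CallerParams overrides
    em: dict = field(default_factory=dict)          # max_iter / tol
    n_perm: int = 500
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: raw.pop(k) for k in ("seed", "caller", "em", "n_perm") if k in raw}
        return cls(**known, extras=raw)


def provenance_header(seed: int | None, config: dict | None = None) -> list[str]:
    """Header lines stamped into every CLI output for reproducibility."""
    blob = yaml.safe_dump(config or {}, sort_keys=True).encode()
    digest = hashlib.sha256(blob).hexdigest()[:12]
    return [
        f"mitohet {__version__}",
        f"seed={seed if seed is not None else 'none'} config_sha={digest}",
    ]
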
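"""Sequence/table I/O and run configuration.

Formats handled here: FASTA (assembly in, clean/contaminant out),
the de-facto 12-column tabular alignment dialect (BLAST ``-outfmt 6``),
GFF3 for optional gene calls, and a flat ``key: value`` YAML config
mirroring :class:`RunConfig`.

Coordinates are 0-based half-open internally and 1-based inclusive in
GFF3.  Bases outside {A,C,G,T,N} are normalized to N on read rather than
rejected — real assemblies carry IUPAC ambiguity codes, and mapping them
to N makes downstream N handling uniform.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

import yaml
from Bio import SeqIO as _BioSeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .homology import AlignmentHit
    from .taxonomy import Lineage

__all__ = [
    "Contig",
    "GeneCall",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_alignment_table",
    "read_gff",
    "write_gff",
]

# Uppercase, then anything outside {A,C,G,T,N} becomes N.
_NON_ACGTN = re.compile(r"[^ACGTN]")


def _normalize(seq: str) -> str:
    return _NON_ACGTN.sub("N", seq.upper())


@dataclass(frozen=True)
class Contig:
    """One assembled sequence: the atomic unit the pipeline labels."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if any(ch.isspace() for ch in self.seq):
            raise ValueError(f"contig {self.id!r}: sequence contains whitespace")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneCall:
    """A gene interval on a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene on {self.contig_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene on {self.contig_id!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RunConfig:
    """Tunable parameters of a decontamination run.

    kmer_small / kmer_large
        Word sizes for the calibrated composition stage (default 5) and
        the taxonomy-free fallback stage (default 9).
    n_components
        PCA components retained; distances live in this space (default 3).
    target_specificity
        Calibration aims to keep at most ``1 - target_specificity`` of
        contaminant calibration bases inside the clean radius.
    user_cutoff
        Optional user-supplied distance radius; overrides calibration.
    min_contig_len
        Contigs shorter than this (bases) are excluded from PCA fitting
        and calibration but still projected and classified, flagged
        ``short`` in the report.
    min_identity / min_aln_len
        Qualifying-hit thresholds for the homology stage.
    rank_required_for_homology
        Rank the target taxonomy (and a best hit's agreement with it)
        must reach for the homology path.
    min_orf_len
        Minimum open-reading-frame length (bases) for the built-in gene
        caller.
    seed
        Seed for every stochastic choice; fixed seed implies bit-identical
        output.
    """

    kmer_small: int = 5
    kmer_large: int = 9
    n_components: int = 3
    target_specificity: float = 0.8
    user_cutoff: float | None = None
    min_contig_len: int = 2000
    min_identity: float = 0.95
    min_aln_len: int = 200
    rank_required_for_homology: str = "class"
    min_orf_len: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        from .taxonomy import rank_index

        if not (1 <= self.kmer_small < self.kmer_large <= 12):
            raise ValueError("require 1 <= kmer_small < kmer_large <= 12")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not (0.0 < self.target_specificity <= 1.0):
            raise ValueError("target_specificity must be in (0, 1]")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.user_cutoff is not None and self.user_cutoff < 0:
            raise ValueError("user_cutoff must be non-negative")
        if self.min_aln_len < 1:
            raise ValueError("min_aln_len must be >= 1")
        rank_index(self.rank_required_for_homology)  # validates the rank name

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key: value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def read_fasta(path: str | Path) -> list[Contig]:
    """Read an assembly FASTA into :class:`Contig` records, in file order.

    Record ids are the first whitespace-delimited header token.  Sequences
    are uppercased and non-ACGTN characters mapped to N.  An empty file or
    a duplicate id is a hard error.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, _normalize(str(rec.seq))))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 60) -> None:
    """Write contigs as FASTA, sequence lines wrapped at *width* columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, c.length, width):
                fh.write(c.seq[i : i + width] + "\n")


def read_alignment_table(
    path: str | Path, lineages: "dict[str, Lineage]"
) -> "list[AlignmentHit]":
    """Read 12-column tabular alignment hits (BLAST ``-outfmt 6`` dialect).

    Columns: query id, subject id, percent identity, alignment length,
    mismatches, gap opens, qstart, qend, sstart, send, e-value, bit score.
    Percent identity is converted to a fraction.  Each subject id must be
    present in *lineages* (the reference DB lineage table).  Malformed
    rows raise with the offending line number; an empty file yields [].
    """
    from .homology import AlignmentHit

    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            q, s = parts[0], parts[1]
            try:
                pident = float(parts[2])
                aln_len = int(parts[3])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from None
            if s not in lineages:
                raise ValueError(
                    f"{path}:{lineno}: subject {s!r} absent from the lineage table"
                )
            hits.append(
                AlignmentHit(
                    query_id=q,
                    subject_id=s,
                    subject_lineage=lineages[s],
                    identity=pident / 100.0,
                    aln_len=aln_len,
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def read_gff(path: str | Path) -> list[GeneCall]:
    """Read gene calls from GFF3 (1-based inclusive -> internal half-open)."""
    path = Path(path)
    genes: list[GeneCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 GFF columns")
            try:
                start = int(parts[3]) - 1
                end = int(parts[4])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from None
            genes.append(GeneCall(parts[0], start, end, parts[6]))
    return genes


def write_gff(genes: Iterable[GeneCall], path: str | Path) -> None:
    """Write gene calls as GFF3 (internal half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes, start=1):
            fh.write(
                f"{g.contig_id}\tprodege\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID=gene{i}\n"
            )
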
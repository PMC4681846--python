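"""Homology stage: gene calling, eukaryote screen, alignment classification.

The first stage of the engine assigns contigs taxonomically from
nucleotide alignments against a lineage-annotated reference database.
A contig whose best qualifying hit agrees with the declared target
taxonomy at (or deeper than) the required rank is CLEAN; one whose best
hit disagrees above that rank is CONTAMINANT; a contig with no qualifying
hit is UNDECIDED and falls through to the composition stage.

Classification is best-hit (not LCA): the single top-scoring hit decides,
under a total tie-break order (bitscore, identity, alignment length,
subject id), so labels never depend on input hit order.

Eukaryotic contamination is screened separately at the gene level: a
contig is flagged when a strict majority of its hit-bearing genes have
their best hit in a eukaryotic subject.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections import defaultdict
from pathlib import Path

from .seqio import Contig, GeneCall, RunConfig, read_fasta
from .taxonomy import (
    Lineage,
    agreement_rank,
    is_taxonomy_deep_enough,
    rank_index,
    read_lineage_table,
)

__all__ = [
    "AlignmentHit",
    "HomologyLabel",
    "ReferenceDB",
    "CLEAN",
    "CONTAMINANT",
    "UNDECIDED",
    "EUK_CONTAMINANT",
    "call_genes",
    "screen_eukaryotic",
    "classify_by_homology",
    "confident_target_bin_exists",
]

CLEAN = "CLEAN"
CONTAMINANT = "CONTAMINANT"
UNDECIDED = "UNDECIDED"
EUK_CONTAMINANT = "EUK_CONTAMINANT"

_EUK_DOMAINS = {"eukaryota", "eukarya", "eukaryotes"}


@dataclass(frozen=True)
class AlignmentHit:
    """One nucleotide alignment between a query contig and a reference."""

    query_id: str
    subject_id: str
    subject_lineage: Lineage
    identity: float
    aln_len: int
    bitscore: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be a fraction in [0, 1]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.bitscore < 0:
            raise ValueError("bitscore must be non-negative")


@dataclass(frozen=True)
class HomologyLabel:
    contig_id: str
    label: str
    decided_at_rank: str | None = None
    best_hit: AlignmentHit | None = None

    def __post_init__(self) -> None:
        if self.label not in (CLEAN, CONTAMINANT, UNDECIDED, EUK_CONTAMINANT):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == UNDECIDED and self.decided_at_rank is not None:
            raise ValueError("UNDECIDED implies no deciding rank")
        if self.label == CLEAN and self.best_hit is None:
            raise ValueError("CLEAN requires a best hit")


@dataclass
class ReferenceDB:
    """A nucleotide reference: sequences plus a per-sequence lineage table."""

    sequences: list[Contig]
    lineages: dict[str, Lineage]

    def __post_init__(self) -> None:
        missing = [c.id for c in self.sequences if c.id not in self.lineages]
        if missing:
            raise ValueError(
                f"reference sequences missing from the lineage table: {missing[:5]}"
            )

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceDB":
        """Load ``<dir>/refdb.fna`` + ``<dir>/lineages.tsv``."""
        directory = Path(directory)
        return cls(
            sequences=read_fasta(directory / "refdb.fna"),
            lineages=read_lineage_table(directory / "lineages.tsv"),
        )

    def write(self, directory: str | Path) -> None:
        from .seqio import write_fasta

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, directory / "refdb.fna")
        with open(directory / "lineages.tsv", "w") as fh:
            for c in self.sequences:
                fh.write(f"{c.id}\t{self.lineages[c.id]}\n")


# ---------------------------------------------------------------------------
# Gene calling (built-in fallback: maximal start-to-stop ORFs, both strands)
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")
_STOPS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _orfs_one_strand(seq: str, min_orf_len: int):
    """Maximal ORFs [start, end) on the forward frames of *seq*.

    An ORF runs from the first ATG after the previous in-frame stop
    through its stop codon inclusive.  Codons containing N cannot be
    recognised as start or stop and are treated as sense codons.
    """
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if start is not None and pos + 3 - start >= min_orf_len:
                    yield start, pos + 3
                start = None
            elif start is None and codon == "ATG":
                start = pos


def call_genes(contig: Contig, min_orf_len: int = 300) -> list[GeneCall]:
    """Built-in gene caller: maximal open reading frames on both strands.

    Finds start(ATG)-to-stop(TAA/TAG/TGA) frames of at least
    ``min_orf_len`` bases under the standard code.  An external gene
    caller may replace this anywhere a list of :class:`GeneCall` is
    consumed.  A contig may legitimately yield zero genes.
    """
    if min_orf_len < 60:
        raise ValueError("min_orf_len must be >= 60")
    genes = [
        GeneCall(contig.id, s, e, "+")
        for s, e in _orfs_one_strand(contig.seq, min_orf_len)
    ]
    rc = revcomp(contig.seq)
    n = contig.length
    genes += [
        GeneCall(contig.id, n - e, n - s, "-")
        for s, e in _orfs_one_strand(rc, min_orf_len)
    ]
    genes.sort(key=lambda g: (g.start, g.end, g.strand))
    return genes


def gene_query_id(gene: GeneCall) -> str:
    """Query id used when aligning a gene region: contig|start-end|strand."""
    return f"{gene.contig_id}|{gene.start}-{gene.end}|{gene.strand}"


_GENE_QID = re.compile(r"^(?P<contig>.+)\|(?P<start>\d+)-(?P<end>\d+)\|[+-]$")


def contig_of_gene_query(query_id: str) -> str:
    """Contig id embedded in a gene query id (plain contig ids pass through)."""
    m = _GENE_QID.match(query_id)
    return m.group("contig") if m else query_id


# ---------------------------------------------------------------------------
# Hit selection and classification
# ---------------------------------------------------------------------------


def _hit_sort_key(h: AlignmentHit):
    # Total order: best first.  Higher bitscore, then identity, then length,
    # then lexicographically smallest subject id — permutation-invariant.
    return (-h.bitscore, -h.identity, -h.aln_len, h.subject_id)


def filter_hits(hits: list[AlignmentHit], config: RunConfig) -> list[AlignmentHit]:
    """Keep hits meeting the identity and alignment-length thresholds."""
    return [
        h
        for h in hits
        if h.identity >= config.min_identity and h.aln_len >= config.min_aln_len
    ]


def best_hit_per_query(hits: list[AlignmentHit]) -> dict[str, AlignmentHit]:
    best: dict[str, AlignmentHit] = {}
    for h in sorted(hits, key=lambda h: (h.query_id,) + _hit_sort_key(h)):
        best.setdefault(h.query_id, h)
    return best


def _is_eukaryotic(lineage: Lineage) -> bool:
    return lineage.names[0].casefold() in _EUK_DOMAINS


def screen_eukaryotic(
    genes: list[GeneCall],
    hits_vs_euk: list[AlignmentHit],
    config: RunConfig,
) -> set[str]:
    """Flag contigs whose gene content is predominantly eukaryotic.

    Hits are gene-region queries (ids from :func:`gene_query_id`).  Each
    hit-bearing gene votes with its best hit; a contig is flagged iff a
    strict majority of its hit-bearing genes vote eukaryotic.  Contigs
    with zero qualifying gene hits are never flagged.
    """
    qualifying = filter_hits(hits_vs_euk, config)
    best = best_hit_per_query(qualifying)
    genes_by_contig: dict[str, list[GeneCall]] = defaultdict(list)
    for g in genes:
        genes_by_contig[g.contig_id].append(g)
    flagged: set[str] = set()
    for contig_id, gene_list in genes_by_contig.items():
        euk = tot = 0
        for g in gene_list:
            h = best.get(gene_query_id(g))
            if h is None:
                continue
            tot += 1
            euk += int(_is_eukaryotic(h.subject_lineage))
        if tot and euk * 2 > tot:
            flagged.add(contig_id)
    return flagged


def classify_by_homology(
    contigs: list[Contig],
    hits: list[AlignmentHit],
    target: Lineage,
    config: RunConfig,
) -> list[HomologyLabel]:
    """Label every contig CLEAN / CONTAMINANT / UNDECIDED from alignments.

    Hits are first filtered to ``identity >= min_identity`` and
    ``aln_len >= min_aln_len``; each contig's single best remaining hit
    decides.  CLEAN iff the hit's lineage agrees with the target at or
    deeper than ``rank_required_for_homology``; any qualifying hit that
    fails that bar (including one agreeing only at a shallower rank, or a
    truncated reference lineage that never reaches it) makes the contig
    CONTAMINANT; no qualifying hit leaves it UNDECIDED.
    """
    if not is_taxonomy_deep_enough(target, config.rank_required_for_homology):
        raise ValueError(
            f"target taxonomy reaches only {target.depth()!r} but homology "
            f"classification requires {config.rank_required_for_homology!r}; "
            "use 9-mer-only mode"
        )
    required_idx = rank_index(config.rank_required_for_homology)
    best = best_hit_per_query(filter_hits(hits, config))
    labels: list[HomologyLabel] = []
    for c in sorted(contigs, key=lambda c: c.id):
        h = best.get(c.id)
        if h is None:
            labels.append(HomologyLabel(c.id, UNDECIDED))
            continue
        rank = agreement_rank(h.subject_lineage, target)
        if rank is not None and rank_index(rank) >= required_idx:
            labels.append(HomologyLabel(c.id, CLEAN, rank, h))
        else:
            labels.append(HomologyLabel(c.id, CONTAMINANT, rank, h))
    return labels


def confident_target_bin_exists(
    labels: list[HomologyLabel],
    contigs: list[Contig],
    config: RunConfig,
) -> bool:
    """Is there a single confident taxonomic bin to anchor calibration?

    Requires at least 3 CLEAN contigs, CLEAN coverage of at least 10 % of
    assembly bases, and no single conflicting phylum among the
    CONTAMINANT best hits carrying as many bases as the CLEAN bin.
    """
    length = {c.id: c.length for c in contigs}
    total = sum(length.values())
    clean = [l for l in labels if l.label == CLEAN]
    clean_bases = sum(length[l.contig_id] for l in clean)
    if len(clean) < 3 or total == 0 or clean_bases < 0.10 * total:
        return False
    phylum_bases: dict[str, int] = defaultdict(int)
    for l in labels:
        if l.label == CONTAMINANT and l.best_hit is not None:
            phylum = l.best_hit.subject_lineage.name_at("phylum")
            if phylum is not None:
                phylum_bases[phylum.casefold()] += length[l.contig_id]
    if phylum_bases and max(phylum_bases.values()) >= clean_bases:
        return False
    return True
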
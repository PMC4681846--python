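"""Synthetic contaminated assemblies with truth labels and a mock reference.

Every stage of the pipeline is testable without downloads: source genomes
are sampled from low-order Markov chains whose stationary composition
hits a requested GC content, fragmented into contigs with a truncated
lognormal length distribution, and mixed at a stated contamination
fraction.  Composition divergence between sources is induced by GC and
chain structure rather than real genomes; a user may substitute real
genome sequences anywhere a :class:`SourceGenomeSpec` provides one.

The mock reference database holds tiling fragments of each source genome
(non-overlapping among themselves, and not themselves assembly contigs)
with their lineages, so the mock aligner — which reports a hit when query
and subject share enough exact canonical 31-mers — finds within-source
hits while cross-source sharing is absent by construction.

This module also drives pre-calibration of the 9-mer cutoff factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .homology import AlignmentHit, ReferenceDB
from .seqio import Contig, RunConfig, write_fasta
from .taxonomy import Lineage, parse_lineage

__all__ = [
    "SourceGenomeSpec",
    "MixtureSpec",
    "MixtureResult",
    "generate_genome",
    "generate_mixture",
    "mock_align",
    "calibration_suite",
    "make_lineage",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_lineage(tag: str, domain: str = "Bacteria", depth: int = 7) -> Lineage:
    """A synthetic seven-rank lineage whose names carry *tag*."""
    names = [domain] + [
        f"{r.capitalize()}_{tag}"
        for r in ("phylum", "class", "order", "family", "genus", "species")
    ]
    return Lineage(tuple(names[:depth]))


@dataclass(frozen=True)
class SourceGenomeSpec:
    """Recipe for one synthetic source genome."""

    lineage: Lineage
    length: int
    gc: float
    markov_order: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.2 < self.gc < 0.8):
            raise ValueError("gc must lie in (0.2, 0.8)")
        if self.length < 1000:
            raise ValueError("genome length must be >= 1 kb")
        if self.markov_order < 0 or self.markov_order > 3:
            raise ValueError("markov_order must be in [0, 3]")


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for a contaminated assembly.

    ``contaminants`` pairs each contaminant genome with its fraction of
    assembly bases; fractions must sum below 1.  Contig lengths follow a
    lognormal(mu, sigma) truncated at 1 kb.
    """

    target: SourceGenomeSpec
    contaminants: tuple[tuple[SourceGenomeSpec, float], ...]
    n_contigs: int = 60
    contig_mu: float = 8.2
    contig_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 2:
            raise ValueError("n_contigs must be >= 2")
        total = sum(f for _, f in self.contaminants)
        if total >= 1.0 or any(f <= 0 for _, f in self.contaminants):
            raise ValueError("contaminant fractions must be positive and sum to < 1")


@dataclass
class MixtureResult:
    """A synthetic assembly plus everything needed to score and rerun it."""

    assembly: list[Contig]
    truth: pd.DataFrame  # contig_id, source, lineage, truth
    refdb: ReferenceDB
    target_lineage: Lineage
    genomes: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.assembly, outdir / "assembly.fna")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.refdb.write(outdir / "refdb")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _stationary_composition(T: np.ndarray, order: int) -> np.ndarray:
    """Base composition of the chain's stationary distribution."""
    nstates = 4**order
    rho = np.full(nstates, 1.0 / nstates)
    for _ in range(200):
        new = np.zeros(nstates)
        for s in range(nstates):
            for b in range(4):
                new[(s * 4 + b) % nstates] += rho[s] * T[s, b]
        if np.abs(new - rho).sum() < 1e-12:
            rho = new
            break
        rho = new
    comp = np.zeros(4)
    for s in range(nstates):
        comp[s % 4] += rho[s]
    return comp


def _transition_matrix(gc: float, order: int, seed: int) -> np.ndarray:
    """Row-stochastic transitions with stationary composition matching gc.

    Genome-specific structure comes from a seeded log-normal perturbation;
    iterative proportional fitting then pins the stationary base
    composition back onto the target within 1e-3.
    """
    p = _base_probs(gc)
    rng = np.random.default_rng([seed, 9001])
    nstates = 4**order
    T = p[None, :] * np.exp(rng.normal(0.0, 0.35, size=(nstates, 4)))
    T /= T.sum(axis=1, keepdims=True)
    for _ in range(40):
        comp = _stationary_composition(T, order)
        if np.abs(comp - p).max() < 1e-4:
            break
        T *= (p / np.maximum(comp, 1e-12))[None, :]
        T /= T.sum(axis=1, keepdims=True)
    return T


def generate_genome(spec: SourceGenomeSpec) -> str:
    """Sample a genome from an order-``markov_order`` Markov chain.

    The chain's stationary composition matches the requested GC within
    ±0.01 (fitting tolerance plus sampling noise at >= 50 kb); the same
    spec always yields the identical sequence.
    """
    rng = np.random.default_rng([spec.seed, 7177])
    p = _base_probs(spec.gc)
    if spec.markov_order == 0:
        out = rng.choice(4, size=spec.length, p=p).astype(np.uint8)
        return _BASES[out].tobytes().decode("ascii")
    T = _transition_matrix(spec.gc, spec.markov_order, spec.seed)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    nstates = 4**spec.markov_order
    u = rng.random(spec.length)
    # seed the state with i.i.d. stationary-ish bases
    init = rng.choice(4, size=spec.markov_order, p=p)
    s = 0
    for b in init:
        s = (s * 4 + int(b)) % nstates
    out = np.empty(spec.length, dtype=np.uint8)
    for i in range(spec.length):
        row = cum[s]
        x = u[i]
        b = 0
        while row[b] < x:
            b += 1
        out[i] = b
        s = (s * 4 + b) % nstates
    return _BASES[out].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Mixture generation
# ---------------------------------------------------------------------------

_REF_TILE = 25_000  # reference fragment length
_REF_GAP = 15_000  # gap between fragments


def _reference_tiles(name: str, genome: str, lineage: Lineage):
    """Tiling fragments of a genome: disjoint among themselves."""
    tiles = []
    pos = 0
    j = 0
    while pos + 1000 <= len(genome):
        end = min(pos + _REF_TILE, len(genome))
        tiles.append((f"{name}_ref_{j:03d}", genome[pos:end], lineage))
        pos = end + _REF_GAP
        j += 1
    return tiles


def generate_mixture(spec: MixtureSpec) -> MixtureResult:
    """Fragment and mix source genomes at the stated contamination fractions.

    Contigs are drawn without overlap (small random gaps between draws)
    from each source genome; per-contaminant base budgets are met within
    1 % by trimming the crossing contig.  Contig ids are assigned after a
    seeded shuffle so identifiers carry no source information.  Raises if
    a source genome cannot supply its requested bases.
    """
    rng = np.random.default_rng([spec.seed, 4242])
    sources: list[tuple[str, SourceGenomeSpec]] = [("target", spec.target)] + [
        (f"contam{i + 1}", s) for i, (s, _) in enumerate(spec.contaminants)
    ]
    genomes = {name: generate_genome(s) for name, s in sources}

    lengths = rng.lognormal(spec.contig_mu, spec.contig_sigma, spec.n_contigs)
    lengths = np.maximum(lengths.astype(np.int64), 1000)
    total = int(lengths.sum())

    # Assign contigs to contaminants until each base budget is met.
    assignment = np.zeros(spec.n_contigs, dtype=np.int64)  # 0 = target
    order = rng.permutation(spec.n_contigs)
    cursor = 0
    for ci, (_, frac) in enumerate(spec.contaminants, start=1):
        budget = frac * total
        acc = 0
        while cursor < spec.n_contigs and acc < budget:
            idx = order[cursor]
            take = int(lengths[idx])
            if acc + take > budget:
                remain = int(round(budget - acc))
                if remain >= 1000:
                    lengths[idx] = remain
                    take = remain
                else:
                    break
            assignment[idx] = ci
            acc += take
            cursor += 1

    # Draw contig sequences sequentially, without overlap, per source.
    cursors = {name: 0 for name, _ in sources}
    seqs: list[tuple[str, str]] = []  # (source name, sequence)
    for idx in range(spec.n_contigs):
        name = sources[assignment[idx]][0]
        genome = genomes[name]
        L = int(lengths[idx])
        start = cursors[name]
        if start + L > len(genome):
            raise ValueError(
                f"requested bases exceed genome length for source {name!r} "
                f"({start + L} > {len(genome)})"
            )
        seqs.append((name, genome[start : start + L]))
        cursors[name] = start + L + int(rng.integers(0, 200))

    shuffle = rng.permutation(spec.n_contigs)
    assembly: list[Contig] = []
    truth_rows = []
    lineage_of = {name: s.lineage for name, s in sources}
    for new_i, old_i in enumerate(shuffle):
        src, seq = seqs[old_i]
        cid = f"ctg_{new_i:05d}"
        assembly.append(Contig(cid, seq))
        truth_rows.append(
            {
                "contig_id": cid,
                "source": src,
                "lineage": str(lineage_of[src]),
                "truth": "clean" if src == "target" else "contaminant",
            }
        )
    truth = pd.DataFrame(truth_rows)

    ref_seqs: list[Contig] = []
    ref_lineages: dict[str, Lineage] = {}
    for name, s in sources:
        for rid, seq, lin in _reference_tiles(name, genomes[name], s.lineage):
            ref_seqs.append(Contig(rid, seq))
            ref_lineages[rid] = lin
    refdb = ReferenceDB(ref_seqs, ref_lineages)
    return MixtureResult(
        assembly=assembly,
        truth=truth,
        refdb=refdb,
        target_lineage=spec.target.lineage,
        genomes=genomes,
    )


# ---------------------------------------------------------------------------
# Mock aligner
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int8)
for _b, _v in zip(b"ACGT", range(4)):
    _CODE[_b] = _v


def _raw_window_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all valid k-windows (forward strand), k <= 31."""
    b = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = len(b) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    code = np.zeros(m, dtype=np.int64)
    for j in range(k):
        seg = b[j : j + m]
        valid &= seg >= 0
        code = code * 4 + np.where(seg >= 0, seg, 0)
    return code[valid]


def _canonical_codes(seq: str, k: int) -> np.ndarray:
    """Unique canonical (strand-pooled) k-mer codes of *seq*."""
    fwd = _raw_window_codes(seq, k)
    comp = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    rc = _raw_window_codes(comp, k)[::-1]
    if fwd.size != rc.size:  # pragma: no cover - both drop the same windows
        return np.unique(np.concatenate([fwd, rc]))
    return np.unique(np.minimum(fwd, rc))


def mock_align(
    queries: list[Contig],
    db: ReferenceDB,
    k: int = 31,
    min_shared: int = 5,
) -> list[AlignmentHit]:
    """Exact shared-k-mer pseudo-aligner for exercising the homology logic.

    Reports a hit whenever a query and a reference sequence share at
    least ``min_shared`` canonical ``k``-mers, synthesising the alignment
    fields from the shared-window count: identity 1.0, alignment length
    ``shared + k - 1``, bitscore ``2 x`` that length.  This is not an
    aligner — any standard nucleotide aligner's tabular output drops in
    via :func:`prodege.seqio.read_alignment_table`.
    """
    subj_ids = sorted(c.id for c in db.sequences)
    seq_of = {c.id: c.seq for c in db.sequences}
    codes_parts = []
    subj_parts = []
    for si, sid in enumerate(subj_ids):
        codes = _canonical_codes(seq_of[sid], k)
        codes_parts.append(codes)
        subj_parts.append(np.full(codes.size, si, dtype=np.int64))
    if not codes_parts:
        return []
    all_codes = np.concatenate(codes_parts)
    all_subj = np.concatenate(subj_parts)
    order = np.argsort(all_codes, kind="stable")
    all_codes, all_subj = all_codes[order], all_subj[order]

    hits: list[AlignmentHit] = []
    for q in sorted(queries, key=lambda c: c.id):
        qc = _canonical_codes(q.seq, k)
        if qc.size == 0:
            continue
        lo = np.searchsorted(all_codes, qc, side="left")
        hi = np.searchsorted(all_codes, qc, side="right")
        n_match = hi - lo
        if not np.any(n_match):
            continue
        # Gather matched subject indices (a code may occur in several subjects).
        starts = lo[n_match > 0]
        counts = n_match[n_match > 0]
        gather = np.repeat(starts, counts) + _ranges(counts)
        shared = np.bincount(all_subj[gather], minlength=len(subj_ids))
        for si in np.flatnonzero(shared >= min_shared):
            sid = subj_ids[si]
            aln_len = int(shared[si]) + k - 1
            hits.append(
                AlignmentHit(
                    query_id=q.id,
                    subject_id=sid,
                    subject_lineage=db.lineages[sid],
                    identity=1.0,
                    aln_len=aln_len,
                    bitscore=2.0 * aln_len,
                    evalue=0.0,
                )
            )
    return hits


def _ranges(counts: np.ndarray) -> np.ndarray:
    """[0..c0-1, 0..c1-1, ...] offsets for np.repeat-based gathering."""
    total = int(counts.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(counts)[:-1]
    out[ends] = 1 - counts[:-1]
    return np.cumsum(out)


# ---------------------------------------------------------------------------
# 9-mer pre-calibration
# ---------------------------------------------------------------------------

CALIBRATION_GRID = {
    "contamination": (0.05, 0.10, 0.25, 0.40),
    "gc_gap": (0.10, 0.20, 0.30),
    "replicates": 3,
}

#: Candidate radius factors scanned by the calibration suite.
CANDIDATE_FACTORS = tuple(np.round(np.arange(0.25, 6.0 + 1e-9, 0.25), 2))


def _calibration_mixture(contamination: float, gc_gap: float, seed: int) -> MixtureSpec:
    target_gc = 0.50 - gc_gap / 2
    contam_gc = 0.50 + gc_gap / 2
    return MixtureSpec(
        target=SourceGenomeSpec(
            lineage=make_lineage("T"), length=150_000, gc=target_gc, seed=seed
        ),
        contaminants=(
            (
                SourceGenomeSpec(
                    lineage=make_lineage("C1"),
                    length=100_000,
                    gc=contam_gc,
                    seed=seed + 1,
                ),
                contamination,
            ),
        ),
        n_contigs=45,
        contig_mu=7.8,
        contig_sigma=0.45,
        seed=seed + 2,
    )


def calibration_suite(
    seed: int,
    candidates: tuple[float, ...] = CANDIDATE_FACTORS,
    target_specificity: float = 0.80,
) -> tuple[float, pd.DataFrame]:
    """Derive the pre-calibrated 9-mer radius factor on a synthetic grid.

    Runs 9-mer binning over mixtures at contamination fractions
    {5, 10, 25, 40} %, GC gaps {10, 20, 30} points, three replicate seeds
    each, evaluating every candidate factor on the same fitted geometry.
    Returns the largest factor whose *median* base-weighted specificity
    across the grid is at or above ``target_specificity``, together with
    the full grid table (one row per mixture x factor).  Raises if no
    candidate qualifies.
    """
    from .composition import CLEAN, ninemer_binning

    rows = []
    cell = 0
    for contamination in CALIBRATION_GRID["contamination"]:
        for gc_gap in CALIBRATION_GRID["gc_gap"]:
            for rep in range(CALIBRATION_GRID["replicates"]):
                cell += 1
                mix_seed = (seed + 7919 * cell) % (2**31 - 1)
                mix = generate_mixture(
                    _calibration_mixture(contamination, gc_gap, mix_seed)
                )
                config = RunConfig(min_contig_len=1000, seed=mix_seed)
                truth = dict(zip(mix.truth.contig_id, mix.truth.truth))
                length = {c.id: c.length for c in mix.assembly}
                # One geometry per mixture; each factor only moves the radius.
                base = ninemer_binning(mix.assembly, config, factor=1.0)
                eps = base.epsilon if base.epsilon is not None else 0.0
                assert base.cutoff is not None
                for f in candidates:
                    radius = eps * f
                    clean_b = contam_b = clean_ok = contam_ok = 0
                    for cid, d in base.distances.items():
                        lab = CLEAN if d <= radius else "CONTAMINANT"
                        L = length[cid]
                        if truth[cid] == "clean":
                            clean_b += L
                            clean_ok += L if lab == CLEAN else 0
                        else:
                            contam_b += L
                            contam_ok += L if lab != CLEAN else 0
                    rows.append(
                        {
                            "contamination": contamination,
                            "gc_gap": gc_gap,
                            "replicate": rep,
                            "seed": mix_seed,
                            "factor": f,
                            "specificity": contam_ok / contam_b if contam_b else 1.0,
                            "sensitivity": clean_ok / clean_b if clean_b else 1.0,
                        }
                    )
    grid = pd.DataFrame(rows)
    med = grid.groupby("factor")["specificity"].median()
    feasible = med[med >= target_specificity]
    if feasible.empty:
        raise RuntimeError(
            "no candidate factor achieves the target specificity on the grid"
        )
    return float(feasible.index.max()), grid
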
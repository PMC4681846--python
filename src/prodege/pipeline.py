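"""Engine orchestration: stage order, fallback logic, final report.

The engine runs one of two paths:

* ``HOMOLOGY_5MER`` — eukaryote screen, then nucleotide-homology
  classification against the reference database, then 5-mer PCA with a
  radius calibrated from the homology-labelled contigs to fill in the
  UNDECIDED contigs.  Homology-decided labels are final; composition only
  classifies what alignment could not.
* ``NINEMER_ONLY`` — taxonomy-free 9-mer binning with the pre-calibrated
  (or user-supplied) cutoff.  Used when the target taxonomy is shallower
  than the required rank, when no reference database or hits are
  available, or when alignment finds no single confident taxonomic bin.

Stage precedence is fixed: euk_screen > homology > composition.  The
final report is two-class (CLEAN / CONTAMINANT); the internal
EUK_CONTAMINANT distinction survives in the ``stage`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import composition as comp
from . import homology as hom
from .seqio import Contig, GeneCall, RunConfig, write_fasta
from .synth import mock_align
from .taxonomy import Lineage, is_taxonomy_deep_enough

__all__ = [
    "HOMOLOGY_5MER",
    "NINEMER_ONLY",
    "Resources",
    "DecontamReport",
    "choose_mode",
    "run_prodege",
]

HOMOLOGY_5MER = "HOMOLOGY_5MER"
NINEMER_ONLY = "NINEMER_ONLY"

logger = logging.getLogger("prodege")

_NA = "."


@dataclass
class Resources:
    """Optional external inputs: databases, precomputed hits, gene calls.

    When a database is present but its hit table is not, ``aligner`` is
    invoked (queries, db) -> hits; the default is the packaged mock
    aligner, and any external aligner's 12-column output can be loaded
    with :func:`prodege.seqio.read_alignment_table` instead.
    """

    ref_db: hom.ReferenceDB | None = None
    euk_db: hom.ReferenceDB | None = None
    hits: list[hom.AlignmentHit] | None = None
    euk_hits: list[hom.AlignmentHit] | None = None
    genes: list[GeneCall] | None = None
    aligner: Callable = mock_align


@dataclass
class DecontamReport:
    """Per-contig labels plus the run-level summary."""

    rows: pd.DataFrame
    summary: dict
    contigs: list[Contig] = field(default_factory=list, repr=False)
    projection: pd.DataFrame | None = None

    def label_of(self, contig_id: str) -> str:
        row = self.rows.loc[self.rows.contig_id == contig_id]
        if row.empty:
            raise KeyError(contig_id)
        return str(row.final_label.iloc[0])

    def write(self, outdir: str | Path) -> None:
        """Write clean.fna, contaminant.fna, report.tsv, summary.txt."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        label = dict(zip(self.rows.contig_id, self.rows.final_label))
        write_fasta(
            [c for c in self.contigs if label[c.id] == comp.CLEAN],
            outdir / "clean.fna",
        )
        write_fasta(
            [c for c in self.contigs if label[c.id] == comp.CONTAMINANT],
            outdir / "contaminant.fna",
        )
        self.rows.to_csv(outdir / "report.tsv", sep="\t", index=False)
        with open(outdir / "summary.txt", "w") as fh:
            for k, v in self.summary.items():
                fh.write(f"{k}: {v}\n")
        if self.projection is not None:
            self.projection.to_csv(outdir / "projection.tsv", sep="\t", index=False)


def choose_mode(
    target: Lineage,
    labels: list[hom.HomologyLabel] | None,
    contigs: list[Contig],
    config: RunConfig,
) -> str:
    """Pick the classification path per the fallback rules.

    NINEMER_ONLY when the target taxonomy does not reach the required
    rank, when the homology stage could not run (no database / hits), or
    when it ran but no single confident taxonomic bin emerged; otherwise
    HOMOLOGY_5MER.
    """
    if not is_taxonomy_deep_enough(target, config.rank_required_for_homology):
        return NINEMER_ONLY
    if labels is None:
        return NINEMER_ONLY
    if not hom.confident_target_bin_exists(labels, contigs, config):
        return NINEMER_ONLY
    return HOMOLOGY_5MER


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def _gene_queries(contigs: list[Contig], genes: list[GeneCall]) -> list[Contig]:
    seq = {c.id: c.seq for c in contigs}
    return [
        Contig(hom.gene_query_id(g), seq[g.contig_id][g.start : g.end])
        for g in genes
        if g.contig_id in seq
    ]


def run_prodege(
    assembly: list[Contig],
    target: Lineage,
    resources: Resources | None = None,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> DecontamReport:
    """Run the full decontamination engine on an assembly.

    Returns the per-contig report; when *outdir* is given also writes
    ``clean.fna``, ``contaminant.fna``, ``report.tsv``, ``summary.txt``
    and ``projection.tsv``.  Fully deterministic given the config seed,
    and invariant to the input contig order (contigs are processed in id
    order throughout).
    """
    if not assembly:
        raise ValueError("empty assembly")
    config = config or RunConfig()
    res = resources or Resources()
    contigs = sorted(assembly, key=lambda c: c.id)
    if len({c.id for c in contigs}) != len(contigs):
        raise ValueError("duplicate contig ids in assembly")
    length = {c.id: c.length for c in contigs}
    total_bases = sum(length.values())
    warnings: list[str] = []

    # ---- stage 0: eukaryote screen (gene-level) ---------------------------
    euk_flagged: set[str] = set()
    if res.euk_hits is not None or res.euk_db is not None:
        genes = res.genes
        if genes is None:
            genes = [
                g for c in contigs for g in hom.call_genes(c, config.min_orf_len)
            ]
        euk_hits = res.euk_hits
        if euk_hits is None:
            euk_hits = res.aligner(_gene_queries(contigs, genes), res.euk_db)
        euk_flagged = hom.screen_eukaryotic(genes, euk_hits, config)
        logger.info(
            "euk_screen: flagged=%d contigs (%d bases)",
            len(euk_flagged),
            sum(length[i] for i in euk_flagged),
        )

    # ---- stage 1: homology ------------------------------------------------
    hom_labels: list[hom.HomologyLabel] | None = None
    deep_enough = is_taxonomy_deep_enough(target, config.rank_required_for_homology)
    if deep_enough and (res.hits is not None or res.ref_db is not None):
        hits = res.hits
        if hits is None:
            hits = res.aligner(contigs, res.ref_db)
        hom_labels = hom.classify_by_homology(contigs, hits, target, config)
        counts = pd.Series([l.label for l in hom_labels]).value_counts()
        logger.info("homology: %s", counts.to_dict())

    mode = choose_mode(target, hom_labels, contigs, config)
    logger.info("mode: %s", mode)

    label_by_hom = {l.contig_id: l for l in (hom_labels or [])}
    final: dict[str, str] = {}
    stage: dict[str, str] = {}
    distance: dict[str, float | None] = {c.id: None for c in contigs}
    flags: dict[str, list[str]] = {c.id: [] for c in contigs}
    cutoff: comp.DistanceCutoff | None = None
    epsilon = None
    proj_rows = None

    for cid in euk_flagged:
        final[cid] = comp.CONTAMINANT
        stage[cid] = "euk_screen"

    if mode == HOMOLOGY_5MER:
        assert hom_labels is not None
        for l in hom_labels:
            if l.contig_id in euk_flagged:
                continue
            if l.label == hom.CLEAN:
                final[l.contig_id] = comp.CLEAN
                stage[l.contig_id] = "homology"
            elif l.label == hom.CONTAMINANT:
                final[l.contig_id] = comp.CONTAMINANT
                stage[l.contig_id] = "homology"

        mat, projectable = comp.kmer_frequency_matrix(contigs, config.kmer_small)
        ids = [c.id for c in contigs]
        lens = np.array([length[i] for i in ids])
        long_mask = lens >= config.min_contig_len
        fit_mask = projectable & long_mask
        if fit_mask.sum() < 2:
            fit_mask = projectable
        if fit_mask.sum() >= 2:
            n_comp = min(config.n_components, int(fit_mask.sum()) - 1, mat.shape[1])
            model = comp.fit_pca(mat[fit_mask], n_components=n_comp)
            coords = model.transform(mat)
            is_proj = dict(zip(ids, projectable))
            pt = {
                i: comp.KmerProjection(
                    i, coords[j], int(lens[j]), projectable=bool(projectable[j])
                )
                for j, i in enumerate(ids)
            }
            clean_ids = [
                i
                for i in ids
                if i in final
                and final[i] == comp.CLEAN
                and stage[i] == "homology"
                and is_proj[i]
            ]
            contam_ids = [
                i
                for i in ids
                if i in final and final[i] == comp.CONTAMINANT and is_proj[i]
            ]
            long_of = dict(zip(ids, long_mask))
            clean_pts = [pt[i] for i in clean_ids if long_of[i]] or [
                pt[i] for i in clean_ids
            ]
            contam_pts = [pt[i] for i in contam_ids if long_of[i]]
            cutoff = comp.calibrate_cutoff(
                clean_pts, contam_pts, config.target_specificity
            )
            if config.user_cutoff is not None:
                cutoff = comp.DistanceCutoff(
                    cutoff.center, float(config.user_cutoff), "USER"
                )
            undecided = [i for i in ids if i not in final]
            klabels = comp.classify_by_distance([pt[i] for i in undecided], cutoff)
            for i in undecided:
                final[i] = klabels[i]
                stage[i] = "kmer5"
                if not is_proj[i]:
                    flags[i].append("unprojectable")
            for j, i in enumerate(ids):
                if projectable[j]:
                    distance[i] = float(np.linalg.norm(coords[j] - cutoff.center))
            proj_rows = pd.DataFrame(
                {
                    "contig_id": ids,
                    **{
                        f"PC{a + 1}": coords[:, a]
                        for a in range(coords.shape[1])
                    },
                    "distance": [distance[i] for i in ids],
                    "label": [final[i] for i in ids],
                }
            )
            logger.info(
                "kmer5: radius=%.6g (%s), undecided classified=%d",
                cutoff.radius,
                cutoff.source,
                len(undecided),
            )
        else:
            warnings.append("insufficient contigs for composition binning")
            for i in ids:
                if i in final:
                    continue
                if not dict(zip(ids, projectable))[i]:
                    final[i] = comp.CONTAMINANT
                    flags[i].append("unprojectable")
                else:
                    final[i] = comp.CLEAN
                stage[i] = "kmer5"
    else:
        result = comp.ninemer_binning(contigs, config)
        if len(result.unprojectable) == len(contigs) and hom_labels is None:
            raise ValueError("cannot classify: no projectable contigs and no homology")
        warnings.extend(result.warnings)
        cutoff = result.cutoff
        epsilon = result.epsilon
        for c in contigs:
            if c.id in euk_flagged:
                continue
            final[c.id] = result.labels[c.id]
            stage[c.id] = "kmer9"
            d = result.distances.get(c.id)
            distance[c.id] = None if d is None or not np.isfinite(d) else d
            if c.id in result.unprojectable:
                flags[c.id].append("unprojectable")
        if result.projections:
            proj_rows = pd.DataFrame(
                {
                    "contig_id": [p.contig_id for p in result.projections],
                    **{
                        f"PC{a + 1}": [p.coords[a] for p in result.projections]
                        for a in range(len(result.projections[0].coords))
                    },
                    "bin": [
                        result.bin_of.get(p.contig_id, -1)
                        for p in result.projections
                    ],
                    "distance": [
                        result.distances[p.contig_id] for p in result.projections
                    ],
                    "label": [final[p.contig_id] for p in result.projections],
                }
            )
        if cutoff is not None:
            logger.info(
                "kmer9: eps=%.6g radius=%.6g (%s)", epsilon, cutoff.radius, cutoff.source
            )

    # ---- report -----------------------------------------------------------
    rows = []
    for c in contigs:
        if c.length < config.min_contig_len:
            flags[c.id].append("short")
        hl = label_by_hom.get(c.id)
        rows.append(
            {
                "contig_id": c.id,
                "length": c.length,
                "final_label": final[c.id],
                "stage": stage[c.id],
                "homology_label": hl.label if hl else _NA,
                "best_hit_subject": (
                    hl.best_hit.subject_id if hl and hl.best_hit else _NA
                ),
                "best_hit_rank": (
                    hl.decided_at_rank if hl and hl.decided_at_rank else _NA
                ),
                "pc_distance": (
                    _fmt(distance[c.id]) if distance[c.id] is not None else _NA
                ),
                "flags": ",".join(flags[c.id]) if flags[c.id] else _NA,
            }
        )
    df = pd.DataFrame(rows)
    clean_bases = int(df.loc[df.final_label == comp.CLEAN, "length"].sum())
    summary = {
        "mode": mode,
        "n_contigs": len(contigs),
        "total_bases": total_bases,
        "n_clean": int((df.final_label == comp.CLEAN).sum()),
        "n_contaminant": int((df.final_label == comp.CONTAMINANT).sum()),
        "bases_clean": clean_bases,
        "bases_contaminant": total_bases - clean_bases,
        "cutoff_radius": _fmt(cutoff.radius) if cutoff is not None else _NA,
        "cutoff_source": cutoff.source if cutoff is not None else _NA,
        "epsilon": _fmt(epsilon) if epsilon is not None else _NA,
        "seed": config.seed,
        "warnings": ";".join(warnings) if warnings else _NA,
        "config": config.asdict(),
    }
    report = DecontamReport(
        rows=df, summary=summary, contigs=contigs, projection=proj_rows
    )
    if outdir is not None:
        report.write(outdir)
    return report
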
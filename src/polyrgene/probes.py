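"""RenSeq capture-probe design and capture simulation.

120-mer probes are tiled per exon to give at least 1x coverage of every
R-gene coding base without crossing exon-exon junctions (for cross-utility
on genomic and cDNA libraries); extra half-step probes densify conserved
NLR domains; the panel is screened against intergenic sequence (seeded
identity search) and a GC window standing in for hybridisation
thermodynamics. A read-level capture simulator reports on-target
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import DomainHit, GeneModel
from .subgenome import ScoringParams, score_pair

log = logging.getLogger(__name__)

PROBE_LENGTH = 120


@dataclass
class Probe:
    probe_id: str
    gene_id: str
    exon_index: int  # 0-based index into the gene's exon list
    genome_start: int  # 1-based inclusive
    sequence: str
    gc: float
    status: str = "kept"  # kept | off_target_dropped | gc_dropped

    @property
    def genome_end(self) -> int:
        return self.genome_start + PROBE_LENGTH - 1


def _gc(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(seq) if seq else 0.0


def tile_probes(
    genes: list[GeneModel],
    contigs: dict[str, str],
    step: int = PROBE_LENGTH,
) -> list[Probe]:
    """Tile 120-mers across every exon of every gene.

    Per exon of length L >= 120: probes at offsets 0, step, 2*step, ... plus
    a final probe anchored to the exon end, so every CDS base of the exon is
    covered at least once. No probe crosses an exon boundary; exons shorter
    than 120 nt are skipped with a logged warning. Non-ACGTN characters in
    an exon are a hard error.
    """
    probes: list[Probe] = []
    for gene in genes:
        contig = contigs.get(gene.chromosome)
        if contig is None:
            raise ValueError(f"{gene.gene_id}: contig {gene.chromosome!r} not provided")
        for idx, (s, e) in enumerate(sorted(gene.exons)):
            exon_seq = contig[s - 1 : e].upper()
            if set(exon_seq) - set("ACGTN"):
                raise ValueError(f"{gene.gene_id} exon {idx}: non-ACGTN characters")
            L = e - s + 1
            if L < PROBE_LENGTH:
                log.warning(
                    "%s exon %d (%d nt) shorter than probe length: left uncovered",
                    gene.gene_id,
                    idx,
                    L,
                )
                continue
            offsets = list(range(0, L - PROBE_LENGTH + 1, step))
            last = L - PROBE_LENGTH
            if offsets[-1] != last:
                offsets.append(last)
            for off in offsets:
                start = s + off
                seq = exon_seq[off : off + PROBE_LENGTH]
                probes.append(
                    Probe(
                        probe_id=f"{gene.gene_id}|{idx}|{start}",
                        gene_id=gene.gene_id,
                        exon_index=idx,
                        genome_start=start,
                        sequence=seq,
                        gc=_gc(seq),
                    )
                )
    return probes


def lift_domains_to_genome(
    gene: GeneModel, hits: list[DomainHit]
) -> list[tuple[int, int]]:
    """Genome intervals (1-based inclusive) of protein-domain hits.

    Protein coordinates are mapped onto the spliced CDS (x3) and then onto
    genome coordinates exon by exon; minus-strand genes map through their
    transcription order. A domain spanning an intron yields one interval
    per exon piece.
    """
    # genome coordinate of every CDS base, in transcription order
    coords: list[int] = []
    for s, e in gene.exons:
        if gene.strand == "+":
            coords.extend(range(s, e + 1))
        else:
            coords.extend(range(e, s - 1, -1))
    intervals = []
    for h in hits:
        if h.gene_id != gene.gene_id:
            continue
        lo = (h.protein_start - 1) * 3
        hi = h.protein_end * 3 - 1
        if hi >= len(coords):
            hi = len(coords) - 1
        if lo > hi:
            continue
        run = [coords[lo]]
        prev = coords[lo]
        for c in coords[lo + 1 : hi + 1]:
            if abs(c - prev) != 1:
                run.append(prev)
                intervals.append((min(run[0], run[1]), max(run[0], run[1])))
                run = [c]
            prev = c
        run.append(prev)
        intervals.append((min(run[0], run[1]), max(run[0], run[1])))
    return intervals


DENSIFY_DOMAINS = ("NB-ARC", "TIR", "RPW8")


def densify_domains(
    probes: list[Probe],
    genes: list[GeneModel],
    contigs: dict[str, str],
    domain_hits: list[DomainHit],
    extra_step: int = 60,
) -> list[Probe]:
    """Add half-step offset probes inside conserved NLR domain intervals.

    Only NB-ARC/TIR/RPW8 intervals are densified; new probes obey the
    junction rule (they come from re-tiling the covering exons at
    ``extra_step``) and are de-duplicated by genome start.
    """
    by_gene = {g.gene_id: g for g in genes}
    hits_by_gene: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        if h.domain_name in DENSIFY_DOMAINS:
            hits_by_gene.setdefault(h.gene_id, []).append(h)

    existing = {(p.gene_id, p.genome_start) for p in probes}
    out = list(probes)
    for gid, hits in hits_by_gene.items():
        gene = by_gene.get(gid)
        if gene is None:
            continue
        intervals = lift_domains_to_genome(gene, hits)
        if not intervals:
            continue
        dense = tile_probes([gene], contigs, step=extra_step)
        for p in dense:
            if (gid, p.genome_start) in existing:
                continue
            mid_ok = any(
                p.genome_start <= hi and p.genome_end >= lo for lo, hi in intervals
            )
            if mid_ok:
                existing.add((gid, p.genome_start))
                out.append(p)
    return out


def screen_probes(
    probes: list[Probe],
    intergenic: dict[str, str],
    identity_threshold: float = 0.9,
    gc_bounds: tuple[float, float] = (0.3, 0.7),
    params: ScoringParams | None = None,
) -> tuple[list[Probe], dict[str, int]]:
    """Screen the panel for off-target capture and GC composition.

    A probe is dropped when any intergenic sequence matches it at >=
    ``identity_threshold`` over the full probe length (seeded local
    alignment score >= threshold x 120, since match is +1), or when its GC
    fraction falls outside ``gc_bounds``. Statuses are recorded on the
    probes; returns (kept panel, report counts).
    """
    params = params or ScoringParams()
    min_score = identity_threshold * PROBE_LENGTH
    report = {"kept": 0, "off_target_dropped": 0, "gc_dropped": 0}
    kept = []
    for p in probes:
        if not gc_bounds[0] <= p.gc <= gc_bounds[1]:
            p.status = "gc_dropped"
            report["gc_dropped"] += 1
            continue
        off = False
        for seq in intergenic.values():
            if score_pair(p.sequence, seq, params) >= min_score:
                off = True
                break
        if off:
            p.status = "off_target_dropped"
            report["off_target_dropped"] += 1
            continue
        p.status = "kept"
        report["kept"] += 1
        kept.append(p)
    return kept, report


def probe_coverage(probes: list[Probe], gene: GeneModel) -> float:
    """Fraction of the gene's CDS bases (in exons >= 120 nt) covered by >= 1 probe."""
    eligible = [(s, e) for s, e in gene.exons if e - s + 1 >= PROBE_LENGTH]
    total = sum(e - s + 1 for s, e in eligible)
    if total == 0:
        return 1.0
    covered = 0
    for s, e in eligible:
        mask = np.zeros(e - s + 1, dtype=bool)
        for p in probes:
            if p.gene_id != gene.gene_id:
                continue
            lo = max(p.genome_start, s)
            hi = min(p.genome_end, e)
            if lo <= hi:
                mask[lo - s : hi - s + 1] = True
        covered += int(mask.sum())
    return covered / total


@dataclass
class CaptureReport:
    n_reads: int
    frac_rgene: float
    frac_other_gene: float
    frac_intergenic: float
    mean_rgene_depth: float
    per_gene_depth: dict[str, float]


def simulate_capture(
    panel: list[Probe],
    contigs: dict[str, str],
    genes: list[GeneModel],
    rgene_ids: set[str],
    n_reads: int,
    on_target_affinity: float = 0.9,
    read_length: int = 100,
    flank: int = 200,
    seed: int = 0,
) -> tuple[list[tuple[str, int]], CaptureReport]:
    """Simulate hybridisation capture and report enrichment.

    Each read (``read_length`` nt) starts, with probability
    ``on_target_affinity``, uniformly within a probe-covered interval
    extended by ``flank`` nt on each side; otherwise uniformly in the
    genome. The report gives the fraction of reads overlapping annotated
    R-genes, other genes, and intergenic space, plus mean per-R-gene depth.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not panel:
        raise ValueError("empty probe panel")
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in genes}

    # on-target sampling intervals: probe +/- flank, clipped to the contig
    targets = []
    for p in panel:
        chrom = gene_by_id[p.gene_id].chromosome
        clen = len(contigs[chrom])
        lo = max(1, p.genome_start - flank)
        hi = min(clen - read_length + 1, p.genome_end + flank - read_length + 1)
        if hi >= lo:
            targets.append((chrom, lo, hi))
    widths = np.array([hi - lo + 1 for _, lo, hi in targets], dtype=float)
    tprob = widths / widths.sum()

    chrom_names = sorted(contigs)
    clens = np.array([max(len(contigs[c]) - read_length + 1, 1) for c in chrom_names], dtype=float)
    cprob = clens / clens.sum()

    gene_spans: dict[str, list[tuple[str, int, int]]] = {}
    for g in genes:
        gene_spans.setdefault(g.chromosome, []).append((g.gene_id, g.start, g.end))

    on_target = rng.random(n_reads) < on_target_affinity
    reads: list[tuple[str, int]] = []
    in_rgene = in_other = 0
    depth: dict[str, int] = {gid: 0 for gid in rgene_ids}
    t_idx = rng.choice(len(targets), size=int(on_target.sum()), p=tprob)
    c_idx = rng.choice(len(chrom_names), size=int(n_reads - on_target.sum()), p=cprob)
    ti = ci = 0
    for is_on in on_target:
        if is_on:
            chrom, lo, hi = targets[t_idx[ti]]
            ti += 1
            start = int(rng.integers(lo, hi + 1))
        else:
            chrom = chrom_names[c_idx[ci]]
            ci += 1
            start = int(rng.integers(1, len(contigs[chrom]) - read_length + 2))
        reads.append((chrom, start))
        end = start + read_length - 1
        hit_r = hit_g = False
        for gid, gs, ge in gene_spans.get(chrom, []):
            if start <= ge and end >= gs:
                if gid in rgene_ids:
                    hit_r = True
                    depth[gid] += 1
                else:
                    hit_g = True
        if hit_r:
            in_rgene += 1
        elif hit_g:
            in_other += 1

    per_gene_depth = {}
    for gid, cnt in depth.items():
        g = gene_by_id.get(gid)
        span = (g.end - g.start + 1) if g else 1
        per_gene_depth[gid] = cnt * read_length / span
    report = CaptureReport(
        n_reads=n_reads,
        frac_rgene=in_rgene / n_reads,
        frac_other_gene=in_other / n_reads,
        frac_intergenic=1.0 - (in_rgene + in_other) / n_reads,
        mean_rgene_depth=float(np.mean(list(per_gene_depth.values()))) if per_gene_depth else 0.0,
        per_gene_depth=per_gene_depth,
    )
    return reads, report
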
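"""Synthetic polyploid genomes, expression and genotypes with truth labels.

Emulates the study system end to end at desk scale: two diverged diploid
ancestor CDS sets, a 28-chromosome octoploid mosaic of their genes with a
tunable retention bias (boosted on homeolog 1 to mimic the dominant
subgenome, compensated on the others so the genome-wide A fraction equals
the nominal bias), NLR domain architectures drawn from a subtype frequency
table, tandem R-gene clusters, tissue and fruit expression matrices with
additive cis-eQTL effects in biparental families, SNP-array marker tables
with quality classes and injected Mendelian errors, and codon-evolution
pairs at a target dN/dS. Every generator is deterministic under its seed,
and the truth tables suffice to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import DomainHit, ExpressionMatrix, GeneModel, Marker
from .molevol import CODON_TABLE, STOP_CODONS

_BASES = np.array(list("ACGT"))
_NONSTOP = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
_STOPS = sorted(STOP_CODONS)

# Octoploid NLR subtype frequency table (counts) used as generator default.
DEFAULT_SUBTYPE_COUNTS = {
    "NBS": 193,
    "NBS-LRR": 22,
    "CC-NBS": 163,
    "CC-NBS-LRR": 30,
    "RPW8": 91,
    "RPW8-NBS": 45,
    "TIR": 134,
    "TIR-NBS": 195,
    "TIR-NBS-LRR": 103,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic octoploid.

    Defaults mirror the emulated system: 7 chromosome groups x 4 homeologs,
    ~10% divergence between the two diploid ancestors, 3% drift of each
    octoploid gene copy from its ancestor, a 0.65 probability that a gene
    derives from ancestor A (the dominant, F. vesca-like subgenome, with
    the boost concentrated on homeolog 1), a 1.6x transcription upweight of
    A-derived genes, and three biparental families of 18 progeny plus two
    parents each (n = 60).
    """

    seed: int = 0
    n_groups: int = 7
    homeologs_per_group: int = 4
    genes_per_chromosome: int = 72
    ancestor_divergence: float = 0.10
    gene_drift: float = 0.03
    retention_bias: float = 0.65
    homeolog1_boost: float = 0.15
    a_expression_factor: float = 1.6
    nlr_fraction: float = 0.10
    rlk_fraction: float = 0.03
    subtype_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS)
    )
    cluster_fraction: float = 0.7
    cluster_size: int = 3
    within_cluster_spacer: int = 1_000
    between_gene_spacer: int = 8_000
    n_families: int = 3
    progeny_per_family: int = 18
    markers_per_chromosome: int = 80
    map_length_bp: int = 25_000_000
    morgans_per_bp: float = 2.5e-8
    n_eqtl_genes: int = 12
    eqtl_beta: float = 8.0
    eqtl_h2: float = 0.75
    mendelian_error_rate: float = 0.02
    multimap_discard_rate: float = 0.1
    chrom_prefix: str = "Fvb"

    def __post_init__(self) -> None:
        for name in (
            "ancestor_divergence",
            "gene_drift",
            "retention_bias",
            "nlr_fraction",
            "cluster_fraction",
            "mendelian_error_rate",
            "multimap_discard_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A CDS of ``n_codons`` codons with a start codon, no internal stop,
    and a terminal stop codon."""
    body = rng.choice(_NONSTOP, size=max(n_codons - 2, 0))
    stop = _STOPS[int(rng.integers(len(_STOPS)))]
    return "ATG" + "".join(body) + stop


def mutate_cds(seq: str, rate: float, rng: np.random.Generator, nonsyn_accept: float = 0.5) -> str:
    """Per-site substitution at ``rate`` with a synonymous bias.

    Proposed changes that create an internal stop are rejected; synonymous
    changes are always accepted, nonsynonymous ones with probability
    ``nonsyn_accept``.
    """
    chars = list(seq)
    n = len(chars)
    hit = np.flatnonzero(rng.random(n) < rate)
    for i in hit:
        if i < 3 or i >= n - 3:  # keep start and stop codons intact
            continue
        old = chars[i]
        alt = [b for b in "ACGT" if b != old]
        new = alt[int(rng.integers(3))]
        ci = (i // 3) * 3
        codon = chars[ci] + chars[ci + 1] + chars[ci + 2] if ci + 2 < n else None
        if codon is None:
            continue
        mutated = list(codon)
        mutated[i - ci] = new
        mcodon = "".join(mutated)
        if mcodon in STOP_CODONS and ci + 3 < n:  # internal stop: reject
            continue
        syn = CODON_TABLE.get(mcodon) == CODON_TABLE.get(codon)
        if syn or rng.random() < nonsyn_accept:
            chars[i] = new
    return "".join(chars)


def _encode_protein_block(protein: str, rng: np.random.Generator) -> str:
    """Codons for an exact amino-acid motif (used to plant motif evidence)."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in CODON_TABLE.items():
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    out = []
    for aa in protein:
        options = sorted(by_aa[aa])
        out.append(options[int(rng.integers(len(options)))])
    return "".join(out)


# ---------------------------------------------------------------------------
# Ancestors and octoploid mosaic
# ---------------------------------------------------------------------------

def generate_ancestors(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], dict[str, dict]]:
    """Two diverged diploid ancestor CDS sets from a shared common ancestor.

    Each descendant is mutated at ``ancestor_divergence / 2`` substitutions
    per site so the two sets sit at the configured mutual divergence.
    Returns (set A, set B, per-locus metadata).
    """
    if not 0.0 <= config.ancestor_divergence < 0.3:
        raise ValueError("ancestor_divergence must be in [0, 0.3)")
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_groups * config.genes_per_chromosome
    n_nlr = int(round(config.nlr_fraction * n_loci))
    n_rlk = int(round(config.rlk_fraction * n_loci))
    loci: dict[str, dict] = {}
    subtype_labels = sorted(config.subtype_counts)
    subtype_p = np.array([config.subtype_counts[s] for s in subtype_labels], dtype=float)
    subtype_p /= subtype_p.sum()
    kind = np.array(["plain"] * n_loci, dtype=object)
    special = rng.permutation(n_loci)
    kind[special[:n_nlr]] = "nlr"
    kind[special[n_nlr : n_nlr + n_rlk]] = "rlk"
    ancestors_a, ancestors_b = {}, {}
    for i in range(n_loci):
        name = f"locus{i:04d}"
        if kind[i] == "nlr":
            n_codons = int(rng.integers(620, 700))
            subtype = subtype_labels[int(rng.choice(len(subtype_labels), p=subtype_p))]
        elif kind[i] == "rlk":
            n_codons = int(rng.integers(520, 600))
            subtype = "RLK-like"
        else:
            n_codons = int(rng.integers(200, 650))
            subtype = "none"
        cds = random_cds(n_codons, rng)
        if kind[i] == "rlk":
            # plant an exact GLPL motif so the common-domain + motif rule fires
            block = _encode_protein_block("GLPLAL", rng)
            cds = cds[:150] + block + cds[150 + len(block) :]
        loci[name] = {"kind": str(kind[i]), "subtype": subtype, "n_codons": n_codons}
        ancestors_a[f"A_{name}"] = mutate_cds(cds, config.ancestor_divergence / 2.0, rng)
        ancestors_b[f"B_{name}"] = mutate_cds(cds, config.ancestor_divergence / 2.0, rng)
    return ancestors_a, ancestors_b, loci


_SUBTYPE_DOMAINS = {
    "NBS": ("NB-ARC",),
    "NBS-LRR": ("NB-ARC", "LRR"),
    "CC-NBS": ("CC", "NB-ARC"),
    "CC-NBS-LRR": ("CC", "NB-ARC", "LRR"),
    "RPW8": ("RPW8",),
    "RPW8-NBS": ("RPW8", "NB-ARC"),
    "TIR": ("TIR",),
    "TIR-NBS": ("TIR", "NB-ARC"),
    "TIR-NBS-LRR": ("TIR", "NB-ARC", "LRR"),
    "RLK-like": ("LRR", "kinase"),
}

_DOMAIN_SPANS = {
    "CC": (5, 60),
    "TIR": (5, 150),
    "RPW8": (5, 120),
    "NB-ARC": (170, 440),
    "LRR": (460, 600),
    "kinase": (300, 500),
}


@dataclass
class OctoploidGenome:
    contigs: dict[str, str]
    genes: list[GeneModel]
    truth: pd.DataFrame
    domain_hits: list[DomainHit]
    ancestors_a: dict[str, str]
    ancestors_b: dict[str, str]


def _ancestry_probability(config: SimulationConfig, homeolog: int) -> float:
    """P(gene derives from ancestor A) on a given homeolog.

    Homeolog 1 carries the dominance boost; homeologs 2..n are compensated
    so the chromosome-group mean stays exactly at ``retention_bias``.
    """
    rho, boost = config.retention_bias, config.homeolog1_boost
    n = config.homeologs_per_group
    if homeolog == 1:
        p = rho + boost
    else:
        p = rho - boost / (n - 1)
    return float(min(max(p, 0.0), 1.0))


def generate_octoploid(
    ancestors_a: dict[str, str],
    ancestors_b: dict[str, str],
    loci: dict[str, dict],
    config: SimulationConfig,
) -> OctoploidGenome:
    """A 28-chromosome octoploid gene mosaic with truth labels.

    Each chromosome ``<prefix><group>-<homeolog>`` carries a drifted copy of
    every locus of its group, drawn from ancestor A with the
    homeolog-dependent retention probability. NLR genes get multi-exon
    structures and domain-architecture labels from their subtype; a
    configurable fraction of NLRs is laid out in tandem clusters
    (short inter-gene spacers), the rest spaced widely.
    """
    rng = np.random.default_rng(config.seed + 1)
    locus_names = sorted(loci)
    per_group = config.genes_per_chromosome
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    rows = []
    domain_hits: list[DomainHit] = []
    for group in range(1, config.n_groups + 1):
        group_loci = locus_names[(group - 1) * per_group : group * per_group]
        for homeolog in range(1, config.homeologs_per_group + 1):
            chrom = f"{config.chrom_prefix}{group}-{homeolog}"
            p_a = _ancestry_probability(config, homeolog)
            # order loci so most NLRs sit in consecutive cluster runs
            nlr_slots = [l for l in group_loci if loci[l]["kind"] == "nlr"]
            other_slots = [l for l in group_loci if loci[l]["kind"] != "nlr"]
            ordered: list[tuple[str, str | None]] = []
            i = 0
            cid = 0
            while i < len(nlr_slots):
                run = nlr_slots[i : i + config.cluster_size]
                if len(run) >= config.cluster_size and rng.random() < config.cluster_fraction:
                    cid += 1
                    ordered.extend((l, f"{chrom}_cluster{cid}") for l in run)
                    i += config.cluster_size
                else:
                    ordered.append((nlr_slots[i], None))
                    i += 1
            # interleave the remaining genes between cluster blocks
            blocks: list[list[tuple[str, str | None]]] = []
            j = 0
            while j < len(ordered):
                blk = [ordered[j]]
                while (
                    j + 1 < len(ordered)
                    and ordered[j + 1][1] is not None
                    and ordered[j + 1][1] == ordered[j][1]
                ):
                    j += 1
                    blk.append(ordered[j])
                blocks.append(blk)
                j += 1
            layout: list[tuple[str, str | None]] = []
            oi = 0
            for blk in blocks:
                layout.extend(blk)
                take = min(len(other_slots) - oi, max(1, len(other_slots) // max(len(blocks), 1)))
                layout.extend((l, None) for l in other_slots[oi : oi + take])
                oi += take
            layout.extend((l, None) for l in other_slots[oi:])

            pieces: list[str] = []
            pos = 0
            prev_cluster: str | None = "__start__"
            for locus, cluster_id in layout:
                info = loci[locus]
                from_a = bool(rng.random() < p_a)
                source = ancestors_a[f"A_{locus}"] if from_a else ancestors_b[f"B_{locus}"]
                cds = mutate_cds(source, config.gene_drift, rng)
                same_cluster = cluster_id is not None and cluster_id == prev_cluster
                spacer_len = (
                    config.within_cluster_spacer if same_cluster else config.between_gene_spacer
                )
                spacer = "".join(rng.choice(_BASES, size=spacer_len))
                pieces.append(spacer)
                pos += spacer_len
                gene_id = f"{chrom}_{locus}"
                strand = "+" if rng.random() < 0.5 else "-"
                is_nlr = info["kind"] == "nlr"
                gseq = cds if strand == "+" else _revcomp(cds)
                if is_nlr:
                    exons, gene_seq = _split_exons(gseq, pos + 1, rng)
                else:
                    exons = [(pos + 1, pos + len(gseq))]
                    gene_seq = gseq
                if strand == "-":
                    exons = exons[::-1]
                pieces.append(gene_seq)
                pos += len(gene_seq)
                protein = _translate(cds)
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        chromosome=chrom,
                        strand=strand,
                        exons=exons,
                        cds_seq=cds,
                        protein_seq=protein,
                    )
                )
                subtype = info["subtype"]
                for dom in _SUBTYPE_DOMAINS.get(subtype, ()):
                    lo, hi = _DOMAIN_SPANS[dom]
                    hi = min(hi, len(protein))
                    if lo < hi:
                        domain_hits.append(DomainHit(gene_id, dom, lo, hi, 100.0))
                rows.append(
                    {
                        "gene_id": gene_id,
                        "chromosome": chrom,
                        "locus": locus,
                        "start": min(s for s, _ in exons),
                        "end": max(e for _, e in exons),
                        "strand": strand,
                        "ancestry": "A_vesca_like" if from_a else "B_iinumae_like",
                        "kind": info["kind"],
                        "subtype": subtype,
                        "cluster_id": cluster_id or "",
                    }
                )
                prev_cluster = cluster_id if cluster_id is not None else "__none__"
            tail = "".join(rng.choice(_BASES, size=config.between_gene_spacer))
            pieces.append(tail)
            contigs[chrom] = "".join(pieces)
    truth = pd.DataFrame(rows)
    return OctoploidGenome(contigs, genes, truth, domain_hits, ancestors_a, ancestors_b)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _translate(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - 2, 3):
        aa = CODON_TABLE.get(cds[i : i + 3], "X")
        if aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


def _split_exons(
    gene_seq: str, genome_start: int, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], str]:
    """Split a (strand-oriented) gene sequence into 2-4 exons with random
    ~120-260 nt introns; returns (exon genome intervals in ascending order,
    genomic sequence including introns)."""
    n = len(gene_seq)
    n_exons = int(rng.integers(2, 5))
    cuts = sorted(rng.choice(np.arange(150, n - 150), size=n_exons - 1, replace=False))
    segments = []
    prev = 0
    for c in cuts:
        segments.append(gene_seq[prev:c])
        prev = int(c)
    segments.append(gene_seq[prev:])
    out = []
    exons = []
    pos = genome_start
    for k, seg in enumerate(segments):
        if k > 0:
            intron = "".join(rng.choice(_BASES, size=int(rng.integers(120, 260))))
            out.append(intron)
            pos += len(intron)
        exons.append((pos, pos + len(seg) - 1))
        out.append(seg)
        pos += len(seg)
    return exons, "".join(out)


# ---------------------------------------------------------------------------
# Families, markers, expression
# ---------------------------------------------------------------------------

@dataclass
class PopulationData:
    fruit: ExpressionMatrix
    atlas: ExpressionMatrix
    markers: list[Marker]
    pedigree: dict[str, tuple[str, str]]
    families: pd.Series
    eqtl_truth: pd.DataFrame
    mendelian_errors: list[tuple[str, str]]
    gene_positions: dict[str, tuple[str, int]]


def _project_position(chrom: str, start: int, contig_len: int, config: SimulationConfig) -> tuple[str, int]:
    group = chrom.split(config.chrom_prefix)[-1].split("-")[0]
    pos = int(start / max(contig_len, 1) * config.map_length_bp)
    return f"{config.chrom_prefix}{group}", pos


def simulate_expression_and_genotypes(
    genome: OctoploidGenome, config: SimulationConfig
) -> PopulationData:
    """Biparental families, SNP markers with linkage, and fruit/atlas
    expression with planted additive cis-eQTL.

    Parents are drawn with phased haplotypes; progeny gametes recombine
    along each chromosome (Haldane). Focal genes receive
    TPM = baseline + beta x dosage + Gaussian noise scaled to the target
    per-gene h2. Marker quality classes exercise the QC filters and
    Mendelian errors are injected (as genotypes impossible for the cross)
    at the configured rate. A-derived genes are transcriptionally
    upweighted to emulate the dominant subgenome.
    """
    rng = np.random.default_rng(config.seed + 2)
    parents = []
    pedigree: dict[str, tuple[str, str]] = {}
    fam_of: dict[str, str] = {}
    individuals: list[str] = []
    for f in range(1, config.n_families + 1):
        p1, p2 = f"F{f}_P1", f"F{f}_P2"
        parents.extend([p1, p2])
        individuals.extend([p1, p2])
        fam_of[p1] = fam_of[p2] = f"fam{f}"
        for k in range(1, config.progeny_per_family + 1):
            ind = f"F{f}_{k:02d}"
            individuals.append(ind)
            pedigree[ind] = (p1, p2)
            fam_of[ind] = f"fam{f}"

    # marker map: sorted positions per diploid chromosome
    chroms = [f"{config.chrom_prefix}{g}" for g in range(1, config.n_groups + 1)]
    marker_ids, marker_chrom, marker_pos = [], [], []
    for chrom in chroms:
        pos = np.sort(rng.integers(1, config.map_length_bp, size=config.markers_per_chromosome))
        for i, p in enumerate(pos):
            marker_ids.append(f"AX_{chrom}_{i:03d}")
            marker_chrom.append(chrom)
            marker_pos.append(int(p))
    m = len(marker_ids)

    # Phased parental haplotypes (allele 1 = B). Each haplotype is a mosaic
    # of a small founder pool per chromosome, so nearby markers are in
    # strong local LD across the population (as on a real SNP array, where
    # one locus shows several near-equally-significant markers).
    n_founders = 6
    freq = rng.uniform(0.2, 0.8, size=m)
    founders = (rng.random((n_founders, m)) < freq).astype(np.int8)
    chrom_idx = {c: [i for i in range(m) if marker_chrom[i] == c] for c in chroms}

    def mosaic_haplotype() -> np.ndarray:
        h = np.empty(m, dtype=np.int8)
        for chrom in chroms:
            idx = chrom_idx[chrom]
            cur = int(rng.integers(n_founders))
            prev_pos = None
            for i in idx:
                if prev_pos is not None:
                    d = (marker_pos[i] - prev_pos) * config.morgans_per_bp
                    if rng.random() < 1.0 - np.exp(-16.0 * d):
                        cur = int(rng.integers(n_founders))
                h[i] = founders[cur, i]
                prev_pos = marker_pos[i]
        return h

    haplo: dict[str, np.ndarray] = {}
    for p in parents:
        haplo[p] = np.stack([mosaic_haplotype(), mosaic_haplotype()])

    def gamete(parent: str) -> np.ndarray:
        h = haplo[parent]
        out = np.empty(m, dtype=np.int8)
        i0 = 0
        for chrom in chroms:
            idx = [i for i in range(m) if marker_chrom[i] == chrom]
            cur = int(rng.integers(2))
            prev_pos = None
            for i in idx:
                if prev_pos is not None:
                    d = (marker_pos[i] - prev_pos) * config.morgans_per_bp
                    r = 0.5 * (1.0 - np.exp(-2.0 * d))
                    if rng.random() < r:
                        cur = 1 - cur
                out[i] = h[cur, i]
                prev_pos = marker_pos[i]
            i0 += len(idx)
        return out

    geno = np.zeros((len(individuals), m), dtype=np.int8)
    for r_i, ind in enumerate(individuals):
        if ind in pedigree:
            p1, p2 = pedigree[ind]
            geno[r_i] = gamete(p1) + gamete(p2)
        else:
            geno[r_i] = haplo[ind].sum(axis=0)

    # marker records with quality classes and injected Mendelian errors
    classes = rng.choice(
        ["PHR", "NMH", "OTV", "CRBT", "Other"], size=m, p=[0.7, 0.15, 0.06, 0.05, 0.04]
    )
    call_of = {0: "AA", 1: "AB", 2: "BB"}
    calls_tab = [[call_of[int(geno[r_i, j])] for j in range(m)] for r_i in range(len(individuals))]
    mendelian_errors: list[tuple[str, str]] = []
    prog_rows = [r_i for r_i, ind in enumerate(individuals) if ind in pedigree]
    for j in range(m):
        if classes[j] not in {"PHR", "NMH"}:
            continue
        for r_i in prog_rows:
            if rng.random() >= config.mendelian_error_rate:
                continue
            ind = individuals[r_i]
            p1, p2 = pedigree[ind]
            g1 = call_of[int(geno[individuals.index(p1), j])]
            g2 = call_of[int(geno[individuals.index(p2), j])]
            from .eqtl import possible_offspring

            impossible = sorted({"AA", "AB", "BB"} - possible_offspring(g1, g2))
            if not impossible:
                continue
            calls_tab[r_i][j] = impossible[int(rng.integers(len(impossible)))]
            mendelian_errors.append((marker_ids[j], ind))
    markers = []
    for j in range(m):
        mk = Marker(
            marker_id=marker_ids[j],
            quality_class=str(classes[j]),
            map_chromosome=marker_chrom[j],
            map_position_bp=marker_pos[j],
            calls={ind: calls_tab[r_i][j] for r_i, ind in enumerate(individuals)},
        )
        mk.recompute_maf()
        markers.append(mk)

    # gene map positions projected onto the diploid marker map
    gene_positions = {}
    for g in genome.genes:
        gene_positions[g.gene_id] = _project_position(
            g.chromosome, g.start, len(genome.contigs[g.chromosome]), config
        )

    truth = genome.truth.set_index("gene_id")
    a_like = truth["ancestry"] == "A_vesca_like"

    # fruit expression: log-normal baseline, A-like upweight, planted eQTL
    gene_ids = list(truth.index)
    n_genes = len(gene_ids)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base *= np.where(a_like.to_numpy(), config.a_expression_factor, 1.0)
    multimap = rng.random(n_genes) < config.multimap_discard_rate
    base *= np.where(multimap, 1.0 - 0.5, 1.0)
    fruit = np.tile(base[:, None], (1, len(individuals)))
    fruit += rng.normal(0.0, 0.15, size=fruit.shape) * base[:, None]

    # choose eQTL genes among well-expressed NLR/RLK genes, causal marker = nearest on map
    marker_df = pd.DataFrame(
        {"chromosome": marker_chrom, "position_bp": marker_pos}, index=marker_ids
    )
    phr = [marker_ids[j] for j in range(m) if classes[j] in {"PHR", "NMH"}]
    # family-centred dosages: the association model carries family fixed
    # effects, so a planted marker must segregate within families
    fam_labels = np.array([fam_of[i] for i in individuals])
    centred = geno.astype(float).copy()
    for fam in np.unique(fam_labels):
        rows = fam_labels == fam
        centred[rows] -= centred[rows].mean(axis=0)

    def within_family_var(j: int) -> float:
        return float(centred[:, j].var())

    def has_ld_partner(j: int, chrom: str, pos: int) -> bool:
        cj = centred[:, j]
        if cj.std() == 0:
            return False
        for k in range(m):
            if k == j or classes[k] not in {"PHR", "NMH"} or marker_chrom[k] != chrom:
                continue
            if abs(marker_pos[k] - pos) > 1_200_000:
                continue
            ck = centred[:, k]
            if ck.std() == 0:
                continue
            if abs(float(np.corrcoef(cj, ck)[0, 1])) >= 0.8:
                return True
        return False

    rlike = [gid for gid in gene_ids if truth.loc[gid, "kind"] in {"nlr", "rlk"}]
    plain = [gid for gid in gene_ids if truth.loc[gid, "kind"] == "plain"]
    rng.shuffle(rlike)
    rng.shuffle(plain)
    candidates = rlike + plain  # prefer R-gene-like loci, top up from the rest
    eqtl_rows = []
    used_markers: set[str] = set()
    for gid in candidates:
        if len(eqtl_rows) >= config.n_eqtl_genes:
            break
        chrom, pos = gene_positions[gid]
        sub = marker_df.loc[[mid for mid in phr if marker_df.loc[mid, "chromosome"] == chrom]]
        if sub.empty:
            continue
        dist = (sub["position_bp"] - pos).abs()
        causal = dist.idxmin()
        if causal in used_markers or dist.min() > 1_500_000:
            continue
        # plant only at loci with local marker support, so the multi-marker
        # significance rule has LD partners to recruit
        j = marker_ids.index(causal)
        if within_family_var(j) < 0.15:
            continue
        if not has_ld_partner(j, chrom, int(marker_df.loc[causal, "position_bp"])):
            continue
        used_markers.add(causal)
        dosage = geno[:, j].astype(float)
        if np.ptp(dosage) == 0:
            continue
        gi = gene_ids.index(gid)
        effect = config.eqtl_beta * dosage
        var_g = effect.var()
        if var_g == 0:
            continue
        noise_sd = float(np.sqrt(var_g * (1.0 - config.eqtl_h2) / config.eqtl_h2))
        fruit[gi] = 1.0 + effect + rng.normal(0.0, noise_sd, size=len(individuals))
        fruit[gi] = np.clip(fruit[gi], 0.0, None)
        eqtl_rows.append(
            {
                "gene_id": gid,
                "causal_marker": causal,
                "beta": config.eqtl_beta,
                "h2": config.eqtl_h2,
                "map_chromosome": chrom,
                "map_position_bp": pos,
            }
        )
    fruit_df = pd.DataFrame(np.clip(fruit, 0.0, None), index=gene_ids, columns=individuals)
    fruit_meta = pd.DataFrame(
        {
            "tissue": "mature_receptacle",
            "genotype": individuals,
            "family": [fam_of[i] for i in individuals],
            "replicate": 1,
        },
        index=pd.Index(individuals, name="sample"),
    )

    # tissue atlas: NLRs dominant in root and leaf
    tissues = [
        ("root", 3),
        ("leaf", 3),
        ("green_receptacle", 2),
        ("white_receptacle", 2),
        ("turning_receptacle", 2),
        ("red_receptacle", 2),
        ("achene", 2),
    ]
    is_nlr = (truth["kind"] == "nlr").to_numpy()
    cols, meta_rows = [], []
    atlas_vals = []
    for tissue, reps in tissues:
        tissue_mean = rng.lognormal(0.0, 1.0, size=n_genes)
        if tissue in {"root", "leaf"}:
            tissue_mean = np.where(is_nlr, tissue_mean * 6.0, tissue_mean)
        else:
            tissue_mean = np.where(is_nlr, tissue_mean * 0.5, tissue_mean)
        for rep in range(1, reps + 1):
            sample = f"{tissue}_r{rep}"
            cols.append(sample)
            meta_rows.append({"tissue": tissue, "genotype": "ref", "family": "", "replicate": rep})
            atlas_vals.append(tissue_mean * rng.lognormal(0.0, 0.2, size=n_genes))
    atlas_df = pd.DataFrame(np.column_stack(atlas_vals), index=gene_ids, columns=cols)
    atlas_meta = pd.DataFrame(meta_rows, index=pd.Index(cols, name="sample"))

    return PopulationData(
        fruit=ExpressionMatrix(fruit_df, fruit_meta),
        atlas=ExpressionMatrix(atlas_df, atlas_meta),
        markers=markers,
        pedigree=pedigree,
        families=pd.Series(fam_of),
        eqtl_truth=pd.DataFrame(eqtl_rows),
        mendelian_errors=mendelian_errors,
        gene_positions=gene_positions,
    )


# ---------------------------------------------------------------------------
# Codon evolution at a target omega
# ---------------------------------------------------------------------------

def simulate_codon_evolution(
    n_pairs: int,
    n_codons: int,
    omega_target: float,
    divergence: float,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """CDS pairs evolved to ``divergence`` substitutions/site at a target
    dN/dS.

    Substitutions are proposed uniformly over sites and bases and accepted
    with probability 1 for synonymous changes and ``omega_target`` (scaled)
    for nonsynonymous ones; stop-creating proposals are rejected. With a
    uniform proposal process this acceptance scheme yields an expected
    NG86 omega equal to the target.
    """
    if omega_target <= 0:
        raise ValueError("omega_target must be positive")
    rng = np.random.default_rng(seed)
    p_syn = min(1.0, 1.0 / omega_target) if omega_target > 1 else 1.0
    p_non = min(1.0, omega_target)
    pairs = []
    for _ in range(n_pairs):
        cds = random_cds(n_codons + 2, rng)
        body = cds[3:-3]  # mutate only internal codons, keep start/stop intact
        target_subs = int(round(divergence * len(body)))
        derived = list(body)
        subs = 0
        guard = 0
        while subs < target_subs and guard < 200 * max(target_subs, 1):
            guard += 1
            i = int(rng.integers(len(derived)))
            old = derived[i]
            new = "ACGT"[int(rng.integers(4))]
            if new == old:
                continue
            ci = (i // 3) * 3
            codon = "".join(derived[ci : ci + 3])
            cand = list(codon)
            cand[i - ci] = new
            ccodon = "".join(cand)
            if ccodon in STOP_CODONS:
                continue
            syn = CODON_TABLE[ccodon] == CODON_TABLE[codon]
            accept = p_syn if syn else p_non
            if rng.random() < accept:
                derived[i] = new
                subs += 1
        pairs.append((cds, cds[:3] + "".join(derived) + cds[-3:]))
    return pairs
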
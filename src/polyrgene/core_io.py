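"""Shared domain types and readers/writers for the formats every stage touches.

Coordinate convention: 1-based inclusive in every persisted file (GFF3
standard); any half-open representation is internal only and invisible at
interfaces.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

DOMAIN_VOCAB = {
    "TIR",
    "NB-ARC",
    "LRR",
    "RPW8",
    "CC",
    "WRKY",
    "F-box",
    "Malectin",
    "kinase",
    "other",
}

GENOTYPE_TOKENS = {"AA", "AB", "BB", "NA"}
MARKER_CLASSES = {"PHR", "NMH", "MHR", "OTV", "CRBT", "Other"}

_CHROM_RE = re.compile(r"^(?P<prefix>[A-Za-z_]*?)(?P<group>\d+)-(?P<homeolog>\d+)$")


def parse_chromosome(name: str) -> tuple[int, int] | None:
    """Parse ``<prefix><group>-<homeolog>`` (e.g. ``Fvb5-2``) -> (5, 2).

    Returns None when the label does not follow the convention.
    """
    m = _CHROM_RE.match(name)
    if m is None:
        return None
    return int(m.group("group")), int(m.group("homeolog"))


@dataclass
class GeneModel:
    """A protein-coding gene model with exon structure and sequences.

    ``exons`` are [start, end] pairs in genome coordinates (1-based
    inclusive), sorted 5'->3' in transcription order: ascending start on the
    plus strand, descending on the minus strand. ``cds_seq`` is the spliced
    coding sequence already in transcription order (minus-strand models are
    reverse-complemented), so ``translate(cds_seq) == protein_seq`` for
    complete models.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_seq: str
    protein_seq: str

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for s, e in self.exons:
            if not 1 <= s <= e:
                raise ValueError(f"{self.gene_id}: bad exon [{s},{e}]")
        total = sum(e - s + 1 for s, e in self.exons)
        if self.cds_seq and total != len(self.cds_seq):
            raise ValueError(
                f"{self.gene_id}: exon span {total} != CDS length {len(self.cds_seq)}"
            )

    def translation(self) -> str:
        return str(Seq(self.cds_seq).translate())


@dataclass
class DomainHit:
    """A protein-domain hit (hmmscan-domtblout-like), 1-based inclusive aa coords."""

    gene_id: str
    domain_name: str
    protein_start: int
    protein_end: int
    score: float = 0.0


@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    protein_start: int
    match_string: str


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with per-sample metadata.

    ``values`` is indexed by gene_id with one column per sample; ``meta`` is
    indexed by sample with (free-form) columns such as tissue, genotype,
    family, replicate.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.meta) and not self.meta.index.equals(self.values.columns):
            self.meta = self.meta.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class Marker:
    """A SNP-array marker with quality class and per-individual calls.

    ``map_chromosome``/``map_position_bp`` are diploid-projected map
    coordinates. Calls are in {AA, AB, BB, NA}.
    """

    marker_id: str
    quality_class: str
    map_chromosome: str
    map_position_bp: int
    calls: dict[str, str]
    maf: float = 0.0

    def recompute_maf(self) -> float:
        counts = {"A": 0, "B": 0}
        for c in self.calls.values():
            if c == "NA":
                continue
            counts["A"] += c.count("A")
            counts["B"] += c.count("B")
        total = counts["A"] + counts["B"]
        self.maf = min(counts.values()) / total if total else 0.0
        return self.maf


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path, width: int = 70) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path, fasta_path) -> list[GeneModel]:
    """Read gene models from GFF3 + genome FASTA.

    Accepts gene/mRNA/exon/CDS features; CDS features define the coding
    sequence (exon features are used when a gene has no CDS rows).
    Minus-strand models are spliced in transcription order and
    reverse-complemented. Raises if a feature references a contig absent
    from the FASTA.
    """
    contigs = read_fasta(fasta_path)
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attr = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: bad coordinates") from exc
            attrs = _parse_attributes(attr)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{ln}: gene without ID")
                genes[gid] = {
                    "chromosome": seqid,
                    "strand": strand,
                    "cds": [],
                    "exons": [],
                    "attrs": attrs,
                }
                order.append(gid)
            elif ftype in {"CDS", "exon"}:
                parent = attrs.get("Parent", attrs.get("ID", ""))
                gid = parent.removesuffix(".mRNA1").removesuffix(".t1")
                if gid not in genes:
                    # tolerate exon rows preceding their gene only if ID known
                    raise ValueError(f"{path}:{ln}: feature references unknown gene {gid!r}")
                key = "cds" if ftype == "CDS" else "exons"
                genes[gid][key].append((start_i, end_i))

    models = []
    for gid in order:
        info = genes[gid]
        chrom = info["chromosome"]
        if chrom not in contigs:
            raise ValueError(f"gene {gid}: contig {chrom!r} absent from FASTA")
        spans = sorted(info["cds"] or info["exons"])
        if not spans:
            continue
        seq = "".join(contigs[chrom][s - 1 : e] for s, e in spans)
        if info["strand"] == "-":
            seq = str(Seq(seq).reverse_complement())
            spans = spans[::-1]
        prot = str(Seq(seq).translate()).rstrip("*") if len(seq) % 3 == 0 else ""
        model = GeneModel(
            gene_id=gid,
            chromosome=chrom,
            strand=info["strand"],
            exons=spans,
            cds_seq=seq,
            protein_seq=prot,
        )
        model.validate()
        models.append(model)
    return models


def _version_header(params: dict | None = None) -> str:
    from . import __version__

    extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"#!polyrgene version={__version__}{extra}\n"


def write_gff3(calls, gene_models: list[GeneModel], path, params: dict | None = None) -> None:
    """Write R-gene calls as GFF3 gene features.

    Each call must reference a known gene model; subtype/family/evidence are
    carried in the ``rgene_subtype``, ``rgene_family`` and ``rgene_evidence``
    attribute keys. A write-then-read round trip preserves coordinates,
    strand and these attributes.
    """
    by_id = {g.gene_id: g for g in gene_models}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_version_header(params))
        for call in calls:
            g = by_id.get(call.gene_id)
            if g is None:
                raise ValueError(f"unknown gene_id {call.gene_id!r} in call list")
            attrs = (
                f"ID={g.gene_id};rgene_subtype={call.subtype};"
                f"rgene_family={call.family};rgene_evidence={call.evidence}"
            )
            fh.write(
                f"{g.chromosome}\tpolyrgene\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.chromosome}\tpolyrgene\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_rgene_gff3(path):
    """Read back R-gene calls written by :func:`write_gff3`.

    Returns a list of ``RGeneCall`` plus a dict of gene coordinates
    {gene_id: (chromosome, start, end, strand)}.
    """
    from .annotation import RGeneCall

    calls, coords = [], {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[2] != "gene":
                continue
            attrs = _parse_attributes(parts[8])
            gid = attrs["ID"]
            subtype = attrs.get("rgene_subtype", "none")
            calls.append(
                RGeneCall(
                    gene_id=gid,
                    is_rgene=subtype != "none",
                    evidence=attrs.get("rgene_evidence", "canonical_domain"),
                    subtype=subtype,
                    family=attrs.get("rgene_family", "non-NLR"),
                )
            )
            coords[gid] = (parts[0], int(parts[3]), int(parts[4]), parts[6])
    return calls, coords


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def read_domain_table(path) -> list[DomainHit]:
    """Read a TSV of domain hits: gene_id, domain_name, protein_start, protein_end, score.

    Unknown domain names map to "other" with a logged warning; end < start is
    a hard error naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    hits = []
    for ln, row in enumerate(df.itertuples(index=False), 2):
        try:
            start, end = int(row.protein_start), int(row.protein_end)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{ln}: malformed coordinates") from exc
        if not 1 <= start <= end:
            raise ValueError(f"{path}:{ln}: bad domain interval [{start},{end}]")
        name = str(row.domain_name)
        if name not in DOMAIN_VOCAB:
            log.warning("%s:%d: unknown domain %r mapped to 'other'", path, ln, name)
            name = "other"
        hits.append(
            DomainHit(str(row.gene_id), name, start, end, float(getattr(row, "score", 0.0)))
        )
    return hits


def read_marker_table(path) -> list[Marker]:
    """Read a SNP-array marker TSV.

    Columns: marker_id, quality_class, map_chromosome, map_position_bp, then
    one column per individual with calls in {AA, AB, BB, NA}. Any other
    genotype token is an error (with line number), never a silent missing.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    fixed = ["marker_id", "quality_class", "map_chromosome", "map_position_bp"]
    individuals = [c for c in df.columns if c not in fixed]
    markers = []
    for ln, (_, row) in enumerate(df.iterrows(), 2):
        try:
            pos = int(row["map_position_bp"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{ln}: malformed map position") from exc
        if pos < 0:
            raise ValueError(f"{path}:{ln}: negative map position")
        calls = {}
        for ind in individuals:
            tok = str(row[ind])
            if tok not in GENOTYPE_TOKENS:
                raise ValueError(f"{path}:{ln}: bad genotype {tok!r} for {ind}")
            calls[ind] = tok
        m = Marker(
            marker_id=row["marker_id"],
            quality_class=row["quality_class"],
            map_chromosome=row["map_chromosome"],
            map_position_bp=pos,
            calls=calls,
        )
        m.recompute_maf()
        markers.append(m)
    return markers


def write_marker_table(markers: list[Marker], path, params: dict | None = None) -> None:
    individuals = sorted({i for m in markers for i in m.calls})
    with open(path, "w") as fh:
        fh.write(_version_header(params))
        fh.write(
            "\t".join(
                ["marker_id", "quality_class", "map_chromosome", "map_position_bp"] + individuals
            )
            + "\n"
        )
        for m in markers:
            row = [m.marker_id, m.quality_class, m.map_chromosome, str(m.map_position_bp)]
            row += [m.calls.get(i, "NA") for i in individuals]
            fh.write("\t".join(row) + "\n")


def read_expression(path, meta_path=None) -> ExpressionMatrix:
    """Read a genes x samples TPM TSV (first column gene_id), optional sample metadata TSV."""
    values = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (values.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    meta = pd.DataFrame(index=values.columns)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(values=values, meta=meta)


def write_expression(matrix: ExpressionMatrix, path, meta_path=None) -> None:
    with open(path, "w") as fh:
        fh.write(_version_header())
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")
    if meta_path is not None:
        matrix.meta.to_csv(meta_path, sep="\t", index_label="sample")
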
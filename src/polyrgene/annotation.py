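"""R-gene identification and NLR subtype classification.

Implements the rule-based inclusion logic (canonical domain, or common
domain plus R-gene-associated motif), heptad-profile coiled-coil detection,
exact/degenerate motif scanning, the nine-subtype NLR taxonomy with
TIR > RPW8 > CC N-terminal precedence, tandem cluster detection, and domain
sequence extraction.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core_io import DomainHit, GeneModel, MotifHit

log = logging.getLogger(__name__)

CANONICAL_DOMAINS = {"NB-ARC", "TIR", "RPW8"}
COMMON_DOMAINS = {"LRR", "kinase", "Malectin"}

SUBTYPES = (
    "NBS",
    "NBS-LRR",
    "CC-NBS",
    "CC-NBS-LRR",
    "RPW8",
    "RPW8-NBS",
    "TIR",
    "TIR-NBS",
    "TIR-NBS-LRR",
)

FAMILY_OF_SUBTYPE = {
    "NBS": "NBS-only",
    "NBS-LRR": "NBS-only",
    "CC-NBS": "CNL",
    "CC-NBS-LRR": "CNL",
    "RPW8": "RPW8-type",
    "RPW8-NBS": "RPW8-type",
    "TIR": "TNL",
    "TIR-NBS": "TNL",
    "TIR-NBS-LRR": "TNL",
}

FAMILIES = ("NBS-only", "CNL", "RPW8-type", "TNL")


@dataclass
class RGeneCall:
    gene_id: str
    is_rgene: bool
    evidence: str  # canonical_domain | common_domain_plus_motif | curated_override | none
    subtype: str  # one of SUBTYPES, or RLK-like / other-R / none
    family: str  # NBS-only | CNL | RPW8-type | TNL | non-NLR


@dataclass
class CoilSegment:
    gene_id: str
    protein_start: int  # 1-based inclusive
    protein_end: int
    max_probability: float


@dataclass
class ClusterCall:
    cluster_id: str
    chromosome: str
    members: list[str]  # gene ids ordered by position
    span_bp: int


# ---------------------------------------------------------------------------
# Coiled-coil detection (heptad-profile sliding window)
# ---------------------------------------------------------------------------

# Two-Gaussian (coiled-coil vs globular) score-distribution parameters per
# window, used to convert the best geometric-mean propensity into a
# probability: P = N_cc / (N_cc + W * N_glob) with prior weight W = 30.
_GAUSS = {
    14: (1.82, 0.28, 0.74, 0.22),
    21: (1.63, 0.24, 0.77, 0.20),
    28: (1.58, 0.22, 0.79, 0.19),
}
_PRIOR_WEIGHT = 30.0

_HEPTAD = "abcdefg"


def load_coil_profile() -> dict[str, np.ndarray]:
    """Load the bundled heptad position-weight profile: aa -> 7 propensities."""
    path = resources.files("polyrgene.data") / "coil_profile.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    return {row.aa: np.array([getattr(row, p) for p in _HEPTAD]) for row in df.itertuples()}


def _coil_scores(protein_seq: str, window: int, profile: dict[str, np.ndarray]) -> np.ndarray:
    """Per-residue score: max geometric-mean propensity over all windows
    covering the residue and all 7 heptad register phases."""
    n = len(protein_seq)
    logp = np.empty((n, 7))
    for i, aa in enumerate(protein_seq):
        logp[i] = np.log(profile.get(aa, profile["X"]))
    best = np.zeros(n)
    for phase in range(7):
        # residue i in register position (i + phase) mod 7
        pos = (np.arange(n) + phase) % 7
        lp = logp[np.arange(n), pos]
        csum = np.concatenate([[0.0], np.cumsum(lp)])
        for start in range(0, n - window + 1):
            gm = math.exp((csum[start + window] - csum[start]) / window)
            seg = slice(start, start + window)
            np.maximum(best[seg], gm, out=best[seg])
    return best


def _score_to_prob(score: np.ndarray, window: int) -> np.ndarray:
    mcc, scc, mg, sg = _GAUSS[window]
    ncc = np.exp(-0.5 * ((score - mcc) / scc) ** 2) / scc
    ng = np.exp(-0.5 * ((score - mg) / sg) ** 2) / sg
    return ncc / (ncc + _PRIOR_WEIGHT * ng)


def detect_coiled_coil(
    protein_seq: str,
    gene_id: str = "",
    window: int = 21,
    threshold: float = 0.5,
    profile: dict[str, np.ndarray] | None = None,
) -> list[CoilSegment]:
    """Detect coiled-coil segments by sliding heptad-register scoring.

    Each residue receives the maximum geometric-mean propensity over every
    window x register-phase combination covering it; scores map to
    probabilities through a two-Gaussian model, and segments are maximal
    runs with probability >= ``threshold``. Sequences shorter than the
    window yield an empty list.
    """
    if window not in _GAUSS:
        raise ValueError(f"window must be one of {sorted(_GAUSS)}")
    if len(protein_seq) < window:
        return []
    if profile is None:
        profile = load_coil_profile()
    prob = _score_to_prob(_coil_scores(protein_seq.upper(), window, profile), window)
    segments = []
    i = 0
    n = len(prob)
    while i < n:
        if prob[i] >= threshold:
            j = i
            while j + 1 < n and prob[j + 1] >= threshold:
                j += 1
            segments.append(
                CoilSegment(gene_id, i + 1, j + 1, float(prob[i : j + 1].max()))
            )
            i = j + 1
        else:
            i += 1
    return segments


def coil_domain_hits(segments: list[CoilSegment]) -> list[DomainHit]:
    """One CC DomainHit per detected segment."""
    return [
        DomainHit(s.gene_id, "CC", s.protein_start, s.protein_end, s.max_probability)
        for s in segments
    ]


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def compile_motif(motif_id: str, pattern: str) -> re.Pattern:
    """Compile a motif pattern (aa letters, 'x' wildcard, [..] alternatives)."""
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch in "xX":
            out.append(".")
        elif ch in _AA:
            out.append(ch)
        elif ch == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise ValueError(f"motif {motif_id!r}: unclosed '[' in {pattern!r}")
            inner = pattern[i + 1 : j]
            if not inner or any(c not in _AA for c in inner):
                raise ValueError(f"motif {motif_id!r}: bad alternative set {inner!r}")
            out.append(f"[{inner}]")
            i = j
        else:
            raise ValueError(f"motif {motif_id!r}: illegal character {ch!r}")
        i += 1
    return re.compile("".join(out))


def read_motif_file(path) -> dict[str, re.Pattern]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(r.motif_id): compile_motif(str(r.motif_id), str(r.pattern)) for r in df.itertuples()}


def default_motifs() -> dict[str, re.Pattern]:
    return read_motif_file(resources.files("polyrgene.data") / "motifs_default.tsv")


def scan_motifs(protein_seq: str, motif_set: dict[str, re.Pattern], gene_id: str = "") -> list[MotifHit]:
    """All non-overlapping occurrences per motif, leftmost-first (1-based)."""
    hits = []
    for mid, pat in motif_set.items():
        for m in pat.finditer(protein_seq):
            hits.append(MotifHit(gene_id, mid, m.start() + 1, m.group(0)))
    return hits


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def assign_nlr_subtype(domains: list[DomainHit] | set[str]) -> tuple[str, str]:
    """Map domain presence flags to the nine NLR subtypes and four families.

    N-terminal precedence is TIR > RPW8 > CC. The NBS flag appends "-NBS";
    LRR appends "-LRR" only on top of NBS (the taxonomy has no X-LRR rows
    without a nucleotide-binding domain, and no RPW8-NBS-LRR row). Flag sets
    without a TIR/RPW8/NB-ARC anchor are not NLRs.
    """
    names = {d.domain_name for d in domains} if not isinstance(domains, set) else domains
    tir, rpw8, cc = "TIR" in names, "RPW8" in names, "CC" in names
    nbs, lrr = "NB-ARC" in names, "LRR" in names
    if tir and rpw8:
        log.warning("simultaneous TIR and RPW8 domains; classifying as TNL")
    if tir:
        prefix = "TIR"
    elif rpw8:
        prefix = "RPW8"
    elif cc:
        prefix = "CC"
    else:
        prefix = ""
    if not (tir or rpw8 or nbs):
        return "none", "non-NLR"
    if prefix in {"CC", ""} and not nbs:  # CC alone is not an NLR anchor
        return "none", "non-NLR"
    subtype = prefix
    if nbs:
        subtype = f"{prefix}-NBS" if prefix else "NBS"
        if lrr and prefix != "RPW8":  # no RPW8-NBS-LRR row in the taxonomy
            subtype += "-LRR"
    family = FAMILY_OF_SUBTYPE[subtype]
    return subtype, family


def classify_gene(
    domains: list[DomainHit],
    motifs: list[MotifHit],
    override: bool = False,
) -> RGeneCall:
    """Rule-based R-gene call from domain and motif evidence.

    A gene is an R-gene iff it carries a canonical domain (NB-ARC, TIR,
    RPW8), or a common domain (LRR, kinase, Malectin) supported by at least
    one R-gene-associated motif hit, or a curated override. LRR + kinase
    combinations without an NLR anchor are called RLK-like.
    """
    gene_id = ""
    for h in domains:
        gene_id = h.gene_id
        break
    for h in motifs:
        gene_id = gene_id or h.gene_id
    names = {d.domain_name for d in domains}
    has_canonical = bool(names & CANONICAL_DOMAINS)
    has_common = bool(names & COMMON_DOMAINS)
    if has_canonical:
        evidence = "canonical_domain"
        is_rgene = True
    elif has_common and motifs:
        evidence = "common_domain_plus_motif"
        is_rgene = True
    elif override:
        evidence = "curated_override"
        is_rgene = True
    else:
        return RGeneCall(gene_id, False, "none", "none", "non-NLR")

    subtype, family = assign_nlr_subtype(names)
    if subtype == "none":
        subtype = "RLK-like" if {"LRR", "kinase"} <= names else "other-R"
    return RGeneCall(gene_id, is_rgene, evidence, subtype, family)


def subtype_table(calls: list[RGeneCall]) -> pd.DataFrame:
    """Counts and within-NLR percentages per subtype and family for one genome.

    Percentages are count / total NLR x 100 rounded to one decimal; family
    rows are the sums of their component subtypes.
    """
    counts = {s: 0 for s in SUBTYPES}
    for c in calls:
        if c.subtype in counts:
            counts[c.subtype] += 1
    total = sum(counts.values())
    rows = []
    for fam in FAMILIES:
        members = [s for s in SUBTYPES if FAMILY_OF_SUBTYPE[s] == fam]
        for s in members:
            rows.append((s, "subtype", counts[s]))
        rows.append((fam, "family", sum(counts[s] for s in members)))
    rows.append(("Total", "total", total))
    df = pd.DataFrame(rows, columns=["label", "level", "count"])
    df["pct"] = (
        (df["count"] / total * 100).round(1) if total else 0.0
    )
    return df


def family_summary(family_counts: dict[str, int]) -> pd.DataFrame:
    """Totals and within-NLR percentages from family-level counts.

    Used for summary accounting when only family totals are available
    (e.g. comparing published per-family counts); percentages are
    count / total x 100 rounded to one decimal.
    """
    total = sum(family_counts.values())
    df = pd.DataFrame(
        {"count": pd.Series(family_counts)},
    )
    df["pct"] = (df["count"] / total * 100).round(1) if total else 0.0
    df.loc["Total"] = [total, 100.0 if total else 0.0]
    return df


def detect_clusters(
    positions: list[tuple[str, str, int]],
    max_gap_bp: int = 100_000,
    min_size: int = 3,
) -> list[ClusterCall]:
    """Find tandem R-gene clusters per chromosome.

    ``positions`` is (gene_id, chromosome, position). Clusters are maximal
    runs of consecutive R-genes on one chromosome with inter-gene gap
    <= ``max_gap_bp`` and at least ``min_size`` members.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid, chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append((pos, gid))
    clusters = []
    k = 0
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        run = [items[0]] if items else []
        for prev, cur in zip(items, items[1:]):
            if cur[0] - prev[0] <= max_gap_bp:
                run.append(cur)
            else:
                if len(run) >= min_size:
                    k += 1
                    clusters.append(_make_cluster(k, chrom, run))
                run = [cur]
        if len(run) >= min_size:
            k += 1
            clusters.append(_make_cluster(k, chrom, run))
    return clusters


def _make_cluster(k: int, chrom: str, run: list[tuple[int, str]]) -> ClusterCall:
    return ClusterCall(
        cluster_id=f"cluster_{k}",
        chromosome=chrom,
        members=[gid for _, gid in run],
        span_bp=run[-1][0] - run[0][0],
    )


def extract_domain_sequence(
    gene: GeneModel, hits: list[DomainHit], domain_name: str
) -> list[tuple[str, str]]:
    """FASTA records (id, aa sequence) for each hit of ``domain_name`` on the gene.

    Record IDs follow ``geneid|domain|start-end``. Coordinates past the
    protein end are a hard error.
    """
    records = []
    for h in hits:
        if h.gene_id != gene.gene_id or h.domain_name != domain_name:
            continue
        if h.protein_end > len(gene.protein_seq) or h.protein_start < 1:
            raise ValueError(
                f"{gene.gene_id}: domain [{h.protein_start},{h.protein_end}] outside "
                f"protein of length {len(gene.protein_seq)}"
            )
        records.append(
            (
                f"{gene.gene_id}|{domain_name}|{h.protein_start}-{h.protein_end}",
                gene.protein_seq[h.protein_start - 1 : h.protein_end],
            )
        )
    return records
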
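"""Ortholog pairing, codon alignment and Nei-Gojobori (1986) dN/dS.

The NG86 estimator counts synonymous/nonsynonymous sites per codon from the
standard genetic code, averages observed differences over all minimal
substitution pathways (equal pathway weighting, stop-codon pathways
excluded), and applies the Jukes-Cantor correction. It deliberately stands
in for ML codon-model estimators: it is closed-form, dependency-free and
verifiable by exhaustive enumeration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .subgenome import ScoringParams, SeedIndex, _best_score, score_pair

log = logging.getLogger(__name__)

BASES = "TCAG"
CODON_TABLE = {}
for _i, _b1 in enumerate(BASES):
    for _j, _b2 in enumerate(BASES):
        for _k, _b3 in enumerate(BASES):
            _aa = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"[
                _i * 16 + _j * 4 + _k
            ]
            CODON_TABLE[_b1 + _b2 + _b3] = _aa
STOP_CODONS = {c for c, a in CODON_TABLE.items() if a == "*"}


@dataclass
class OrthologPair:
    query_id: str
    subject_id: str
    source: str  # syntenic | best_hit
    score: float


@dataclass
class DnDsResult:
    query_id: str
    subject_id: str
    n_codons: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    dN: float
    dS: float
    omega: float  # nan when undefined (dS == 0)
    omega_defined: bool
    saturated: bool


@dataclass
class GroupStats:
    label: str
    n: int
    median_omega: float
    anova_F: float = math.nan
    anova_df1: int = 0
    anova_df2: int = 0
    anova_p: float = math.nan
    pearson_r: float = math.nan
    pearson_p: float = math.nan


# ---------------------------------------------------------------------------
# Ortholog pairing
# ---------------------------------------------------------------------------

def pair_orthologs(
    queries: dict[str, str],
    subjects: dict[str, str],
    synteny: dict[str, str] | None = None,
    params: ScoringParams | None = None,
    min_score: int | None = None,
) -> list[OrthologPair]:
    """Pick one subject per query: the collinear subject when the query lies
    in a provided synteny block, else the best-scoring subject passing the
    score threshold. Queries with no qualifying subject are omitted."""
    params = params or ScoringParams()
    threshold = params.min_score if min_score is None else min_score
    idx = SeedIndex(subjects, params.word_size)
    pairs = []
    for qid, qseq in queries.items():
        if synteny and qid in synteny:
            sid = synteny[qid]
            if sid not in subjects:
                raise ValueError(f"synteny block for {qid!r} names unknown subject {sid!r}")
            pairs.append(OrthologPair(qid, sid, "syntenic", score_pair(qseq, subjects[sid], params)))
            continue
        best_sid, best = None, threshold - 1
        for sid in sorted(idx.candidates(qseq)):
            s = score_pair(qseq, subjects[sid], params)
            if s > best:
                best_sid, best = sid, s
        if best_sid is not None:
            pairs.append(OrthologPair(qid, best_sid, "best_hit", best))
    return pairs


# ---------------------------------------------------------------------------
# Alignment and back-translation
# ---------------------------------------------------------------------------

def align_proteins(p1: str, p2: str) -> tuple[str, str]:
    """Global pairwise protein alignment (BLOSUM62, gap open 10 / extend 0.5)."""
    if not p1 and not p2:
        return "", ""
    if not p1 or not p2:
        longer = p1 or p2
        gaps = "-" * len(longer)
        return (longer, gaps) if p1 else (gaps, longer)
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(p1, p2)[0]
    return str(aln[0]), str(aln[1])


def backtranslate(
    aligned1: str, aligned2: str, cds1: str, cds2: str
) -> list[tuple[str, str]]:
    """Expand a protein alignment to codon columns from the source CDSs.

    Each amino-acid column becomes its source codon, each gap a "---"
    column; trailing stop codons are trimmed before checking that each CDS
    translates to its ungapped protein (mismatches raise with the offending
    codon position).
    """

    def prep(aligned: str, cds: str, which: int) -> list[str]:
        if len(cds) % 3 != 0:
            raise ValueError(f"sequence {which}: CDS length not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1].upper() in STOP_CODONS:
            codons = codons[:-1]
        protein = aligned.replace("-", "")
        if len(codons) != len(protein):
            raise ValueError(
                f"sequence {which}: {len(codons)} codons vs {len(protein)} aligned residues"
            )
        for pos, (codon, aa) in enumerate(zip(codons, protein), 1):
            trans = CODON_TABLE.get(codon.upper(), "X")
            if "N" in codon.upper():
                trans = "X"
            if trans != aa.upper() and trans != "X" and aa.upper() != "X":
                raise ValueError(
                    f"sequence {which}: codon {codon!r} at position {pos} does not encode {aa!r}"
                )
        return codons

    codons1, codons2 = prep(aligned1, cds1, 1), prep(aligned2, cds2, 2)
    out = []
    i = j = 0
    for a1, a2 in zip(aligned1, aligned2):
        c1 = "---"
        c2 = "---"
        if a1 != "-":
            c1 = codons1[i]
            i += 1
        if a2 != "-":
            c2 = codons2[j]
            j += 1
        out.append((c1, c2))
    return out


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _syn_fraction(codon: str) -> float:
    """Synonymous site count for one codon (sum over positions of the
    fraction of the three single-nucleotide changes that are synonymous;
    changes to stop codons count as nonsynonymous)."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for k in range(3):
        for b in BASES:
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES = {c: _syn_fraction(c) for c in CODON_TABLE if c not in STOP_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over all minimal
    substitution pathways between two codons (stop intermediates excluded;
    if every pathway passes through a stop, all pathways are used)."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        ok = True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            steps.append((CODON_TABLE[cur] == CODON_TABLE[nxt], nxt))
            cur = nxt
        paths.append((ok, steps))
    valid = [steps for ok, steps in paths if ok]
    if not valid:
        valid = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in valid:
        for is_syn, _ in steps:
            if is_syn:
                sd += 1.0
            else:
                nd += 1.0
    k = len(valid)
    return sd / k, nd / k


def _comparable(c1: str, c2: str) -> bool:
    for c in (c1, c2):
        if "-" in c or "N" in c or len(c) != 3 or c in STOP_CODONS or c not in CODON_TABLE:
            return False
    return True


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 distance from a proportion of differences; flags saturation at p >= 3/4."""
    if p >= 0.75:
        return math.inf, True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def compute_dnds(
    codon_alignment: list[tuple[str, str]],
    query_id: str = "",
    subject_id: str = "",
) -> DnDsResult:
    """NG86 dN/dS from a codon alignment.

    Codon pairs containing gaps, N, or stop codons are excluded; at least
    one comparable pair is required.
    """
    S_sites = N_sites = Sd = Nd = 0.0
    n_codons = 0
    for c1, c2 in codon_alignment:
        c1, c2 = c1.upper(), c2.upper()
        if not _comparable(c1, c2):
            continue
        n_codons += 1
        s_avg = (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2.0
        S_sites += s_avg
        N_sites += 3.0 - s_avg
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codon pairs in alignment")
    pN = Nd / N_sites if N_sites else 0.0
    pS = Sd / S_sites if S_sites else 0.0
    dN, satN = jukes_cantor(pN)
    dS, satS = jukes_cantor(pS)
    defined = dS > 0 and not (satN or satS)
    omega = dN / dS if defined else math.nan
    return DnDsResult(
        query_id=query_id,
        subject_id=subject_id,
        n_codons=n_codons,
        N_sites=N_sites,
        S_sites=S_sites,
        Nd=Nd,
        Sd=Sd,
        dN=dN,
        dS=dS,
        omega=omega,
        omega_defined=defined,
        saturated=satN or satS,
    )


def dnds_pipeline(
    cds1: str, cds2: str, query_id: str = "", subject_id: str = ""
) -> DnDsResult:
    """Protein alignment -> back-translation -> NG86 for one CDS pair."""

    def translate(cds: str) -> str:
        codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        if codons and codons[-1].upper() in STOP_CODONS:
            codons = codons[:-1]
        return "".join(CODON_TABLE.get(c.upper(), "X") for c in codons)

    a1, a2 = align_proteins(translate(cds1), translate(cds2))
    return compute_dnds(backtranslate(a1, a2, cds1, cds2), query_id, subject_id)


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------

def group_contrasts(
    omega: np.ndarray,
    labels: list[str],
    expression: np.ndarray | None = None,
) -> dict[str, GroupStats]:
    """Group medians, one-way ANOVA across groups, and Pearson correlation
    of omega with mean log10(TPM + 1) expression when provided.

    Groups with fewer than two finite omega values are excluded from the
    ANOVA with a warning. ANOVA statistics are attached to every group
    (they are a property of the partition, not of one group).
    """
    omega = np.asarray(omega, dtype=float)
    labels_arr = np.asarray(labels)
    finite = np.isfinite(omega)
    groups = {}
    for lab in dict.fromkeys(labels):
        mask = (labels_arr == lab) & finite
        vals = omega[mask]
        groups[lab] = vals
    usable = {lab: v for lab, v in groups.items() if len(v) >= 2}
    for lab in groups:
        if lab not in usable:
            log.warning("group %r has n < 2; excluded from ANOVA", lab)
    F = p = math.nan
    df1 = df2 = 0
    if len(usable) >= 2:
        F, p = stats.f_oneway(*usable.values())
        n_total = sum(len(v) for v in usable.values())
        df1 = len(usable) - 1
        df2 = n_total - len(usable)
    r = rp = math.nan
    if expression is not None:
        expr = np.log10(np.asarray(expression, dtype=float) + 1.0)
        mask = finite & np.isfinite(expr)
        if mask.sum() >= 3:
            r, rp = stats.pearsonr(omega[mask], expr[mask])
    return {
        lab: GroupStats(
            label=lab,
            n=len(vals),
            median_omega=float(np.median(vals)) if len(vals) else math.nan,
            anova_F=float(F),
            anova_df1=df1,
            anova_df2=df2,
            anova_p=float(p),
            pearson_r=float(r),
            pearson_p=float(rp),
        )
        for lab, vals in groups.items()
    }
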
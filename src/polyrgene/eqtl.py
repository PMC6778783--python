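"""Expression summaries and fruit eQTL mapping.

TPM normalisation, tissue summaries of an expression atlas, correlation-
distance hierarchical clustering, Box-Cox phenotype normalisation, SNP-array
marker QC (quality classes + Mendelian consistency), VanRaden kinship, an
EMMA-style single-spectral-decomposition mixed model for per-marker
association (with a plain linear-model fallback), Benjamini-Hochberg FDR,
multi-marker eQTL calling, cis/trans phasing against a diploid-projected
map, and variance-component heritability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import cluster as scipy_cluster
from scipy import stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, Marker, parse_chromosome

log = logging.getLogger(__name__)


@dataclass
class BoxCoxParams:
    lmbda: float
    offset: float


@dataclass
class Locus:
    chromosome: str
    peak_marker: str
    peak_q: float
    n_markers: int
    markers: list[str]
    phase: str = ""  # cis | trans (set by phase_eqtl)


@dataclass
class EqtlResult:
    gene_id: str
    peak_marker: str
    peak_q: float
    n_colocating: int
    phase: str  # cis | cis+trans | none
    h2_estimate: float
    loci: list[Locus] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def tpm(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million from raw counts and effective gene lengths."""
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive effective length")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero-sum sample(s): {bad}")
    return ExpressionMatrix(values=rate.div(totals, axis=1) * 1e6)


def tissue_summary(atlas: ExpressionMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Per-tissue expressed-gene counts and mean TPM, replicates averaged first.

    A gene is expressed in a tissue when its replicate-mean TPM exceeds
    ``threshold``; the "global" column marks expression in any tissue.
    """
    if "tissue" not in atlas.meta.columns:
        raise ValueError("sample metadata must carry a 'tissue' column")
    tissue_means = atlas.values.T.groupby(atlas.meta["tissue"]).mean().T
    expressed = tissue_means > threshold
    out = pd.DataFrame(
        {
            "expressed_genes": expressed.sum(axis=0),
            "mean_tpm": tissue_means.mean(axis=0),
        }
    )
    out.loc["global"] = [int(expressed.any(axis=1).sum()), tissue_means.mean(axis=None)]
    return out


def expressed_mask(atlas: ExpressionMatrix, threshold: float = 1.0) -> pd.DataFrame:
    tissue_means = atlas.values.T.groupby(atlas.meta["tissue"]).mean().T
    return tissue_means > threshold


def hcluster(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomeration of columns under 1 - Pearson r distance.

    Columns are ordered lexicographically first so merge order is
    deterministic under ties; constant columns get correlation 0 (distance
    1) with a warning. Returns (scipy linkage matrix, leaf labels).
    """
    labels = sorted(matrix.columns)
    X = matrix[labels].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        log.warning("constant column(s) %s: correlations set to 0", [labels[i] for i in np.flatnonzero(sd == 0)])
    n = len(labels)
    corr = np.zeros((n, n))
    for i in range(n):
        corr[i, i] = 1.0
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                c = 0.0
            else:
                c = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
            corr[i, j] = corr[j, i] = c
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = scipy_cluster.hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Z, labels


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def _boxcox_transform(x: np.ndarray, lmbda: float) -> np.ndarray:
    if abs(lmbda) < 1e-12:
        return np.log(x)
    return (np.power(x, lmbda) - 1.0) / lmbda


def _boxcox_loglik(x: np.ndarray, lmbda: float) -> float:
    y = _boxcox_transform(x, lmbda)
    n = len(x)
    var = y.var()
    if var <= 0:
        return -math.inf
    return -n / 2.0 * math.log(var) + (lmbda - 1.0) * float(np.log(x).sum())


def boxcox(vector: np.ndarray, bounds: tuple[float, float] = (-5.0, 5.0), tol: float = 1e-5):
    """Box-Cox normalisation with MLE lambda by golden-section search.

    An offset of 1 is applied first when any value is <= 0 (TPM zeros are
    common). Constant input returns the identity transform (lambda 1) with
    a warning. Returns (transformed vector, BoxCoxParams).
    """
    x = np.asarray(vector, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in Box-Cox input")
    offset = 1.0 if (x <= 0).any() else 0.0
    x = x + offset
    if np.ptp(x) == 0:
        log.warning("constant vector: Box-Cox left as identity")
        return np.asarray(vector, dtype=float), BoxCoxParams(1.0, offset)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = bounds
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = _boxcox_loglik(x, c), _boxcox_loglik(x, d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _boxcox_loglik(x, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _boxcox_loglik(x, d)
    lmbda = (a + b) / 2.0
    return _boxcox_transform(x, lmbda), BoxCoxParams(lmbda, offset)


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

_OFFSPRING = {
    ("AA", "AA"): {"AA"},
    ("AA", "AB"): {"AA", "AB"},
    ("AA", "BB"): {"AB"},
    ("AB", "AB"): {"AA", "AB", "BB"},
    ("AB", "BB"): {"AB", "BB"},
    ("BB", "BB"): {"BB"},
}


def possible_offspring(p1: str, p2: str) -> set[str]:
    key = tuple(sorted((p1, p2)))
    return _OFFSPRING.get(key, {"AA", "AB", "BB"})


def filter_markers(
    markers: list[Marker],
    pedigree: dict[str, tuple[str, str]],
    keep_classes: tuple[str, ...] = ("PHR", "NMH"),
) -> tuple[list[Marker], dict[str, int]]:
    """Marker QC: quality-class filter, Mendelian-consistency filter,
    monomorphic-marker drop.

    ``pedigree`` maps progeny id -> (parent1 id, parent2 id); individuals
    without pedigree entries are retained unchecked. Progeny calls that are
    impossible given the parental genotypes are set to missing. Markers left
    monomorphic after cleaning are dropped. Returns the cleaned markers and
    an audit log of action counts.
    """
    audit = {"class_dropped": 0, "mendelian_set_missing": 0, "monomorphic_dropped": 0, "kept": 0}
    out = []
    for m in markers:
        if m.quality_class not in keep_classes:
            audit["class_dropped"] += 1
            continue
        calls = dict(m.calls)
        for ind, call in calls.items():
            if call == "NA" or ind not in pedigree:
                continue
            p1, p2 = pedigree[ind]
            g1, g2 = calls.get(p1, "NA"), calls.get(p2, "NA")
            if g1 == "NA" or g2 == "NA":
                continue
            if call not in possible_offspring(g1, g2):
                calls[ind] = "NA"
                audit["mendelian_set_missing"] += 1
        observed = {c for c in calls.values() if c != "NA"}
        if len(observed) <= 1:
            audit["monomorphic_dropped"] += 1
            continue
        cleaned = Marker(
            marker_id=m.marker_id,
            quality_class=m.quality_class,
            map_chromosome=m.map_chromosome,
            map_position_bp=m.map_position_bp,
            calls=calls,
        )
        cleaned.recompute_maf()
        out.append(cleaned)
        audit["kept"] += 1
    return out, audit


def dosage_matrix(markers: list[Marker], individuals: list[str]) -> pd.DataFrame:
    """Individuals x markers B-allele dosage matrix (0/1/2, NaN missing)."""
    code = {"AA": 0.0, "AB": 1.0, "BB": 2.0, "NA": np.nan}
    data = {
        m.marker_id: [code[m.calls.get(ind, "NA")] for ind in individuals] for m in markers
    }
    return pd.DataFrame(data, index=individuals)


# ---------------------------------------------------------------------------
# Kinship and mixed-model association
# ---------------------------------------------------------------------------

def kinship(dosages: pd.DataFrame) -> pd.DataFrame:
    """VanRaden genomic relationship matrix from 0/1/2 dosages.

    Missing dosages are mean-imputed; monomorphic markers (allele frequency
    0 or 1) are excluded. K = ZZ' / (2 sum p(1-p)) with Z the centred
    dosage matrix.
    """
    M = dosages.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(M, axis=0)
    nan_idx = np.where(np.isnan(M))
    M[nan_idx] = np.take(col_mean, nan_idx[1])
    p = M.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("no polymorphic markers for kinship")
    M = M[:, keep]
    p = p[keep]
    Z = M - 2.0 * p
    denom = 2.0 * float((p * (1.0 - p)).sum())
    K = Z @ Z.T / denom
    return pd.DataFrame(K, index=dosages.index, columns=dosages.index)


def _mlm_neg_loglik(log_delta: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over beta and sigma_g^2.

    REML rather than ML: the genomic relationship matrix is singular in the
    intercept direction (centred dosages), and the ML profile degenerates
    to delta -> 0 there; restricting to the residual space cancels that
    divergence.
    """
    big = 1e300  # finite penalty keeps the golden-section bracket well-defined
    delta = 10.0 ** log_delta
    w = 1.0 / (lam + delta)
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return big
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
    except np.linalg.LinAlgError:
        return big
    r = yt - Xt @ beta
    n, p = Xt.shape
    sigma2 = float((w * r * r).sum()) / (n - p)
    if sigma2 <= 0:
        return big
    ll = -0.5 * (
        (n - p) * (math.log(2 * math.pi * sigma2) + 1.0)
        - float(np.log(w).sum())
        + logdet_xwx
    )
    return -ll


def _mlm_fit(lam, yt, Xt) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profile the variance ratio delta = sigma_e^2/sigma_g^2 on a log grid
    refined by golden-section; return (delta, beta, cov(beta), sigma_g^2)."""
    grid = np.linspace(-5.0, 5.0, 21)
    vals = [_mlm_neg_loglik(g, lam, yt, Xt) for g in grid]
    i = int(np.argmin(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        _mlm_neg_loglik, bounds=(a, b), args=(lam, yt, Xt), method="bounded",
        options={"xatol": 1e-4},
    )
    delta = 10.0 ** float(res.x)
    w = 1.0 / (lam + delta)
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ (Xw.T @ yt)
    r = yt - Xt @ beta
    n, p = Xt.shape
    sigma_g2 = float((w * r * r).sum()) / (n - p)
    cov = XtWX_inv * sigma_g2
    return delta, beta, cov, sigma_g2


def associate(
    phenotype: pd.Series,
    dosages: pd.DataFrame,
    K: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-marker association of a phenotype with genotype dosages.

    With a kinship matrix, fits y = mu + covariates + marker*beta + u,
    u ~ N(0, sigma_g^2 K), via one spectral decomposition of K and a
    per-marker profiled variance ratio (EMMA-style), testing the marker
    coefficient with a Wald t-test. Without K, a plain linear model is
    fitted. Missing dosages are mean-imputed. Requires >= 10 non-missing
    phenotype values.
    """
    y_all = phenotype.dropna()
    if len(y_all) < 10:
        raise ValueError("need >= 10 non-missing phenotype values")
    individuals = [i for i in dosages.index if i in y_all.index]
    y = y_all.loc[individuals].to_numpy(dtype=float)
    n = len(individuals)
    X0 = [np.ones(n)]
    if covariates is not None:
        C = covariates.loc[individuals].to_numpy(dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X0.extend(C.T)
    X0 = np.column_stack(X0)
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("singular covariate matrix")

    M = dosages.loc[individuals].to_numpy(dtype=float).copy()
    col_mean = np.nanmean(M, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_idx = np.where(np.isnan(M))
    M[nan_idx] = np.take(col_mean, nan_idx[1])

    results = []
    if K is not None:
        Ksub = K.loc[individuals, individuals].to_numpy(dtype=float)
        lam, U = np.linalg.eigh((Ksub + Ksub.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
        yt = U.T @ y
        X0t = U.T @ X0
        for j, marker in enumerate(dosages.columns):
            xt = U.T @ M[:, j]
            Xt = np.column_stack([X0t, xt])
            if np.ptp(M[:, j]) == 0:
                results.append((marker, 0.0, np.nan, 1.0))
                continue
            _, beta, cov, _ = _mlm_fit(lam, yt, Xt)
            b = float(beta[-1])
            se = float(math.sqrt(max(cov[-1, -1], 0.0)))
            df = n - Xt.shape[1]
            if se == 0 or df <= 0:
                results.append((marker, b, se, 1.0))
                continue
            t = b / se
            p = 2.0 * stats.t.sf(abs(t), df)
            results.append((marker, b, se, float(p)))
    else:
        for j, marker in enumerate(dosages.columns):
            x = M[:, j]
            if np.ptp(x) == 0:
                results.append((marker, 0.0, np.nan, 1.0))
                continue
            X = np.column_stack([X0, x])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            df = n - X.shape[1]
            sigma2 = float(r @ r) / df
            XtX_inv = np.linalg.inv(X.T @ X)
            se = math.sqrt(max(sigma2 * XtX_inv[-1, -1], 0.0))
            if se == 0:
                results.append((marker, float(beta[-1]), se, 1.0))
                continue
            t = float(beta[-1]) / se
            p = 2.0 * stats.t.sf(abs(t), df)
            results.append((marker, float(beta[-1]), se, float(p)))
    return pd.DataFrame(results, columns=["marker_id", "beta", "se", "p"]).set_index("marker_id")


def fdr(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = pvalues.dropna()
    if p.empty:
        return pd.Series(dtype=float)
    _, q, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
    return pd.Series(q, index=p.index).reindex(pvalues.index)


# ---------------------------------------------------------------------------
# eQTL calling, phasing, heritability
# ---------------------------------------------------------------------------

def call_eqtl(
    qvalues: pd.Series,
    marker_map: pd.DataFrame,
    q_threshold: float = 0.05,
    min_markers: int = 2,
    window_bp: int = 5_000_000,
) -> list[Locus]:
    """Cluster significant markers into loci.

    ``marker_map`` is indexed by marker_id with columns chromosome,
    position_bp. Significant markers (q < threshold) are clustered per
    chromosome, splitting when consecutive markers are more than
    ``window_bp`` apart; only loci with >= ``min_markers`` markers are
    reported, with the minimum-q marker as peak.
    """
    sig = qvalues[qvalues < q_threshold].dropna()
    loci: list[Locus] = []
    if sig.empty:
        return loci
    mapped = marker_map.loc[marker_map.index.intersection(sig.index)]
    for chrom, sub in mapped.groupby("chromosome", sort=True):
        sub = sub.sort_values("position_bp")
        run: list[str] = []
        last = None
        for mid, row in sub.iterrows():
            if last is not None and row["position_bp"] - last > window_bp:
                loci.extend(_flush_locus(run, str(chrom), sig, min_markers))
                run = []
            run.append(mid)
            last = row["position_bp"]
        loci.extend(_flush_locus(run, str(chrom), sig, min_markers))
    return loci


def _flush_locus(run: list[str], chrom: str, qvals: pd.Series, min_markers: int) -> list[Locus]:
    if len(run) < min_markers:
        return []
    q = qvals.loc[run]
    peak = q.idxmin()
    return [Locus(chrom, peak, float(q.min()), len(run), list(run))]


def project_chromosome(octoploid_chrom: str, prefix: str = "Fvb") -> str | None:
    """Project an octoploid chromosome label (e.g. Fvb5-2) onto the diploid
    map (Fvb5)."""
    parsed = parse_chromosome(octoploid_chrom)
    if parsed is None:
        return None
    return f"{prefix}{parsed[0]}"


def phase_eqtl(
    loci: list[Locus],
    gene_map_chromosome: str | None,
    gene_map_position: int | None,
    marker_map: pd.DataFrame,
    cis_window: int = 5_000_000,
) -> str:
    """Label each locus cis or trans and return the gene-level phase.

    A locus is cis when its peak marker lies on the gene's projected
    chromosome within ``cis_window``; the gene phase is "cis", "cis+trans"
    (at least one of each), or "none". A trans-only outcome is reported but
    flagged in the log (none were observed in fruit R-gene data).
    """
    if gene_map_chromosome is None or gene_map_position is None:
        log.warning("gene without a projected map position: phase undetermined")
        return "none"
    has_cis = has_trans = False
    for locus in loci:
        row = marker_map.loc[locus.peak_marker]
        same = str(row["chromosome"]) == str(gene_map_chromosome)
        near = same and abs(int(row["position_bp"]) - int(gene_map_position)) <= cis_window
        locus.phase = "cis" if near else "trans"
        has_cis |= near
        has_trans |= not near
    if not loci:
        return "none"
    if has_cis and has_trans:
        return "cis+trans"
    if has_cis:
        return "cis"
    log.warning("trans-only eQTL observed: flagged")
    return "trans"


def heritability(
    phenotype: pd.Series,
    K: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    peak_dosage: pd.Series | None = None,
) -> float:
    """Narrow-sense heritability estimate in [0, 1].

    With kinship: sigma_g^2 / (sigma_g^2 + sigma_e^2) = 1/(1 + delta) from
    the null mixed model (no marker term). Without kinship: adjusted R^2 of
    the peak-marker linear model, clipped to [0, 1].
    """
    y_all = phenotype.dropna()
    if K is not None:
        individuals = [i for i in K.index if i in y_all.index]
        y = y_all.loc[individuals].to_numpy(dtype=float)
        n = len(y)
        X = [np.ones(n)]
        if covariates is not None:
            C = covariates.loc[individuals].to_numpy(dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            X.extend(C.T)
        Xm = np.column_stack(X)
        Ksub = K.loc[individuals, individuals].to_numpy(dtype=float)
        lam, U = np.linalg.eigh((Ksub + Ksub.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
        try:
            delta, _, _, _ = _mlm_fit(lam, U.T @ y, U.T @ Xm)
        except np.linalg.LinAlgError:
            log.warning("non-convergent variance profile; using peak-marker fallback")
            return heritability(phenotype, None, covariates, peak_dosage)
        # var(u) = sigma_g^2 * mean(diag K); delta = sigma_e^2 / sigma_g^2
        kbar = float(np.mean(np.diag(Ksub)))
        h2 = kbar / (kbar + delta)
        return float(min(max(h2, 0.0), 1.0))
    if peak_dosage is None:
        raise ValueError("need either kinship or a peak-marker dosage")
    individuals = [i for i in peak_dosage.index if i in y_all.index]
    y = y_all.loc[individuals].to_numpy(dtype=float)
    x = peak_dosage.loc[individuals].to_numpy(dtype=float)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    ss_res = float(r @ r)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - 2, 1)
    return float(min(max(adj, 0.0), 1.0))


def eqtl_scan(
    expression: ExpressionMatrix,
    markers: list[Marker],
    pedigree: dict[str, tuple[str, str]],
    gene_positions: dict[str, tuple[str | None, int | None]],
    families: pd.Series | None = None,
    q_threshold: float = 0.05,
    min_markers: int = 2,
    window_bp: int = 5_000_000,
    cis_window: int = 5_000_000,
    use_kinship: bool = True,
) -> list[EqtlResult]:
    """Full per-gene eQTL pipeline: marker QC -> Box-Cox -> mixed-model
    association -> BH-FDR -> multi-marker locus calling -> cis/trans phase
    -> heritability.

    ``gene_positions`` maps gene_id -> (diploid-projected chromosome,
    position); ``families`` (individual -> family label) enters as fixed
    covariates to absorb population structure.
    """
    clean, _ = filter_markers(markers, pedigree)
    if not clean:
        return []
    individuals = [i for i in expression.samples]
    dos = dosage_matrix(clean, individuals)
    K = kinship(dos) if use_kinship else None
    covs = None
    if families is not None:
        covs = pd.get_dummies(families.loc[individuals], drop_first=True, dtype=float)
    marker_map = pd.DataFrame(
        {
            "chromosome": [m.map_chromosome for m in clean],
            "position_bp": [m.map_position_bp for m in clean],
        },
        index=[m.marker_id for m in clean],
    )
    results = []
    for gene in expression.genes:
        y_raw = expression.values.loc[gene]
        if np.ptp(y_raw.to_numpy(dtype=float)) == 0:
            continue
        y_t, _ = boxcox(y_raw.to_numpy(dtype=float))
        y = pd.Series(y_t, index=y_raw.index)
        assoc = associate(y, dos, K=K, covariates=covs)
        q = fdr(assoc["p"])
        loci = call_eqtl(q, marker_map, q_threshold, min_markers, window_bp)
        chrom, pos = gene_positions.get(gene, (None, None))
        phase = phase_eqtl(loci, chrom, pos, marker_map, cis_window)
        if not loci:
            continue
        peak = min(loci, key=lambda l: l.peak_q)
        h2 = heritability(
            y, K=K, covariates=covs, peak_dosage=dos[peak.peak_marker] if not use_kinship else None
        )
        results.append(
            EqtlResult(
                gene_id=gene,
                peak_marker=peak.peak_marker,
                peak_q=peak.peak_q,
                n_colocating=peak.n_markers,
                phase=phase,
                h2_estimate=h2,
                loci=loci,
            )
        )
    return results
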
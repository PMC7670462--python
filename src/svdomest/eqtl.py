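"""Expression normalization, genotype imputation, mixed-model association,
eQTL block construction, hotspot detection and master-regulator ranking.

The association model is the two-step approximation popularised by EMMAX:
per gene, the variance components of a kinship + residual mixed model are
estimated once by REML, then every SV is tested by generalized least
squares with the hidden-factor covariates.  Blocks chain adjacent
significant SVs that are in linkage disequilibrium above the genome-wide
background; a block is cis when its lead SV lies within 50 kb of the
gene's transcription start or stop site.  Trans-eQTL hotspots are scored
by a sliding-window Poisson test with Benjamini-Hochberg control, and each
hotspot's candidate master regulator is ranked by an iterative-group
(minimal hypergeometric prefix) enrichment of the hotspot's target genes
among the regulator's strongest expression correlates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: defaults quoted throughout the analysis
N_HIDDEN_FACTORS = 20
PCA_OUTLIER_SD = 2.5
MAF_MIN = 0.01
MISSING_MAX = 0.40
CIS_WINDOW = 50_000
HOTSPOT_WINDOW = 50_000
HOTSPOT_ADJ_P = 0.05
BLOCK_MIN_SVS = 3


@dataclass
class ExpressionMatrix:
    """Genes x accessions expression with gene coordinates.

    ``stage`` tracks the processing state: ``raw_fpkm`` -> ``filtered`` ->
    ``qq_normalized`` (or ``simulated`` for generator output, which lives
    on the same scale as qq-normalized data).
    """

    values: pd.DataFrame
    genes: pd.DataFrame  # index gene id; columns chrom, tss, tes[, strand]
    stage: str = "raw_fpkm"

    @property
    def accessions(self) -> pd.Index:
        return self.values.columns


@dataclass
class ImputationParams:
    """KNN genotype-imputation parameters (window, neighbours, weight
    exponent, concordance threshold)."""

    w: int = 80
    k: int = 3
    p: float = -7.0
    r: float = 0.8

    def __post_init__(self) -> None:
        if not (self.w >= self.k >= 1):
            raise ValueError("need w >= k >= 1")
        if not 0.0 < self.r <= 1.0:
            raise ValueError("r must lie in (0, 1]")


# ---------------------------------------------------------------------------
# expression normalization
# ---------------------------------------------------------------------------


def fpkm_from_counts(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (gene length * library fragments)."""
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    L = gene_lengths.loc[counts.index].values[:, None].astype(float)
    N = library_sizes.loc[counts.columns].values[None, :].astype(float)
    return counts * 1e9 / (L * N)


def quantile_normal_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene rank-to-normal-quantile transform (mid-rank ties)."""
    n = values.shape[1]
    ranks = values.rank(axis=1, method="average")
    return pd.DataFrame(
        stats.norm.ppf(ranks / (n + 1)), index=values.index, columns=values.columns
    )


def pca_outlier_accessions(
    fpkm: pd.DataFrame, n_pcs: int = 3, sd: float = PCA_OUTLIER_SD
) -> list[str]:
    """Accessions beyond ``sd`` standard deviations on any leading PC."""
    X = fpkm.T.values.astype(float)
    X = X - X.mean(axis=0)
    k = min(n_pcs, min(X.shape) - 1)
    if k < 1:
        return []
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    bad = (np.abs(z) > sd).any(axis=1)
    return list(fpkm.columns[bad])


def normalize_expression(
    fpkm: Optional[pd.DataFrame] = None,
    counts: Optional[pd.DataFrame] = None,
    gene_lengths: Optional[pd.Series] = None,
    library_sizes: Optional[pd.Series] = None,
    genes: Optional[pd.DataFrame] = None,
    outlier_sd: float = PCA_OUTLIER_SD,
) -> ExpressionMatrix:
    """Full normalization: FPKM -> median-zero filter -> PCA outlier
    removal on PC1-3 -> per-gene quantile-normal transform.

    Provide either an FPKM matrix or raw counts plus gene lengths and
    library sizes.  Raises when fewer than 4 accessions survive filtering.
    """
    if fpkm is None:
        if counts is None or gene_lengths is None or library_sizes is None:
            raise ValueError("need fpkm, or counts with gene_lengths and library_sizes")
        fpkm = fpkm_from_counts(counts, gene_lengths, library_sizes)
    if (fpkm.values < 0).any():
        raise ValueError("FPKM values must be non-negative")

    expressed = fpkm.median(axis=1) > 0
    fpkm = fpkm.loc[expressed]

    outliers = pca_outlier_accessions(fpkm, sd=outlier_sd)
    if outliers:
        log.info("removing %d PCA-outlier accessions", len(outliers))
        fpkm = fpkm.drop(columns=outliers)
    if fpkm.shape[1] < 4:
        raise ValueError("fewer than 4 accessions after filtering")

    values = quantile_normal_transform(fpkm)
    g = genes if genes is not None else pd.DataFrame(index=values.index)
    return ExpressionMatrix(values=values, genes=g.loc[values.index] if len(g) else g,
                            stage="qq_normalized")


def derive_hidden_factors(matrix: ExpressionMatrix, k: int = N_HIDDEN_FACTORS) -> pd.DataFrame:
    """Leading principal components of expression as per-accession covariates.

    These play the role of hidden/confounding expression factors; the
    components are pairwise orthogonal and ordered by explained variance.
    """
    if matrix.stage not in ("qq_normalized", "simulated"):
        raise ValueError("expression must be quantile-normalized first")
    n = matrix.values.shape[1]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the accession count {n}")
    if k == 0:
        return pd.DataFrame(index=matrix.values.columns)
    X = matrix.values.T.values.astype(float)
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    return pd.DataFrame(
        scores, index=matrix.values.columns, columns=[f"factor{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# kinship and imputation
# ---------------------------------------------------------------------------


def compute_kinship(dosages: pd.DataFrame) -> pd.DataFrame:
    """Balding-Nichols-style kinship: frequency-standardized genotype
    similarity averaged over sites.

    ``dosages`` holds A-allele counts {0, 1, 2} (sites x accessions) with
    missing allowed (mean-imputed per site).  The result is symmetric and
    positive semi-definite.
    """
    G = dosages.astype("float64")
    G = G.apply(lambda row: row.fillna(row.mean()), axis=1).values
    p = G.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites are monomorphic")
    G = G[poly]
    p = p[poly]
    Z = (G - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    K = Z.T @ Z / len(p)
    return pd.DataFrame(K, index=dosages.columns, columns=dosages.columns)


def knn_impute(
    dosages: pd.DataFrame, params: ImputationParams = ImputationParams()
) -> pd.DataFrame:
    """Fill missing dosages from the k nearest accessions.

    For each missing entry, accession distances are mean squared dosage
    differences over a window of ``w`` consecutive sites centred on the
    target site; the ``k`` nearest accessions called at the site vote with
    weights ``distance ** p``, and the fill is applied only when the top
    vote's weight share reaches the concordance threshold ``r``.
    Non-missing entries are never changed.
    """
    G = dosages.astype("float64").values.copy()
    n_sites, n_acc = G.shape
    half = params.w // 2
    out = G.copy()
    eps = 1e-6
    for s in range(n_sites):
        miss = np.where(np.isnan(G[s]))[0]
        if len(miss) == 0:
            continue
        lo = max(0, s - half)
        hi = min(n_sites, lo + params.w)
        W = G[lo:hi]  # window x accessions
        called = ~np.isnan(G[s])
        if not called.any():
            log.debug("site %d: all accessions missing; left missing", s)
            continue
        diff = W[:, miss, None] - W[:, None, :]  # window x miss x acc
        sq = diff**2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist = np.nanmean(sq, axis=0)  # miss x acc
        dist[np.isnan(dist)] = np.inf
        dist[:, ~called] = np.inf
        for mi, j in enumerate(miss):
            d = dist[mi].copy()
            d[j] = np.inf
            order = np.argsort(d)[: params.k]
            order = order[np.isfinite(d[order])]
            if len(order) == 0:
                continue
            wts = (d[order] + eps) ** params.p
            votes = {}
            for nb, wt in zip(order, wts):
                g = G[s, nb]
                votes[g] = votes.get(g, 0.0) + wt
            top_g, top_w = max(votes.items(), key=lambda kv: kv[1])
            if top_w / sum(votes.values()) >= params.r:
                out[s, j] = top_g
    return pd.DataFrame(out, index=dosages.index, columns=dosages.columns).astype("float64")


def imputation_masking_experiment(
    dosages: pd.DataFrame,
    mask_fraction: float,
    params: ImputationParams = ImputationParams(),
    seed: int = 0,
) -> dict:
    """Mask called entries at random, impute, and report accuracy and
    filling rate on the masked cells."""
    rng = np.random.default_rng(seed)
    G = dosages.astype("float64")
    called = np.argwhere(~np.isnan(G.values))
    k = int(round(mask_fraction * len(called)))
    chosen = called[rng.choice(len(called), size=k, replace=False)]
    masked = G.copy()
    vals = masked.values
    truth = []
    for i, j in chosen:
        truth.append(vals[i, j])
        vals[i, j] = np.nan
    imputed = knn_impute(masked, params)
    filled, correct = 0, 0
    for (i, j), t in zip(chosen, truth):
        v = imputed.values[i, j]
        if not np.isnan(v):
            filled += 1
            correct += int(v == t)
    return dict(
        n_masked=k,
        filling_rate=filled / k if k else float("nan"),
        accuracy=correct / filled if filled else float("nan"),
    )


# ---------------------------------------------------------------------------
# mixed-model association
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Family-wise threshold alpha/m and its -log10."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    thr = alpha / m
    return thr, float(-np.log10(thr))


def _reml_delta(yt: np.ndarray, Ct: np.ndarray, lam: np.ndarray) -> float:
    """Profile-REML estimate of delta = sigma_e^2 / sigma_g^2 on rotated data."""
    n, q = Ct.shape

    def crit(log_delta: float) -> float:
        delta = 10.0**log_delta
        w = 1.0 / (lam + delta)
        WC = Ct * w[:, None]
        A = Ct.T @ WC
        sign, logdetA = np.linalg.slogdet(A)
        beta = np.linalg.solve(A, WC.T @ yt)
        r = yt - Ct @ beta
        R = float(np.sum(w * r * r))
        return (n - q) * np.log(max(R, 1e-300)) + np.sum(np.log(lam + delta)) + logdetA

    grid = np.linspace(-5, 5, 41)
    vals = [crit(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(crit, bounds=(g0 - 0.5, g0 + 0.5), method="bounded")
    return float(10.0 ** res.x)


def filter_sv_dosages(
    dosages: pd.DataFrame, maf_min: float = MAF_MIN, missing_max: float = MISSING_MAX
) -> pd.DataFrame:
    """Apply the association-ready site filters: missing rate, then
    per-site mean imputation of what remains, then minor allele frequency."""
    G = dosages.astype("float64")
    miss = G.isna().mean(axis=1)
    G = G.loc[miss <= missing_max]
    G = G.apply(lambda row: row.fillna(row.mean()), axis=1)
    p = G.mean(axis=1) / 2
    maf = np.minimum(p, 1 - p)
    keep = (maf >= maf_min) & (G.var(axis=1) > 0)
    return G.loc[keep]


def _gls_scan_one(
    yt: np.ndarray,
    Ct: np.ndarray,
    lam: np.ndarray,
    R: np.ndarray,
    R2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """GLS test of every SV for one rotated trait.

    ``R`` holds the rotated dosages (svs x n, equal to G @ U) and ``R2``
    its elementwise square; both are shared across traits, so the per-SV
    work reduces to a few matrix-vector products (Frisch-Waugh-Lovell with
    per-trait GLS weights).
    """
    n, q = Ct.shape
    delta = _reml_delta(yt, Ct, lam)
    w = 1.0 / (lam + delta)
    sw = np.sqrt(w)
    ys = yt * sw
    Cs = Ct * sw[:, None]
    Q, _ = np.linalg.qr(Cs)
    qy = Q.T @ ys
    yr2 = float(ys @ ys - qy @ qy)

    GtQ = R @ (sw[:, None] * Q)  # svs x q
    gg = R2 @ w - np.einsum("ij,ij->i", GtQ, GtQ)
    gy = R @ (sw * ys) - GtQ @ qy
    dof = n - q - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gg
        rss = yr2 - beta * gy
        se2 = rss / dof / gg
        tstat = beta / np.sqrt(se2)
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    return beta, p


def association_scan(
    y: pd.Series,
    dosages: pd.DataFrame,
    covariates: Optional[pd.DataFrame],
    kinship: pd.DataFrame,
    eigen: Optional[tuple[np.ndarray, np.ndarray]] = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """EMMAX-style scan of one expression trait against every SV.

    Variance components are estimated once by REML on the covariate-only
    model, then each SV is tested by GLS; returns effect estimates and
    two-sided p-values.  ``dosages`` should normally pass through
    :func:`filter_sv_dosages` first (set ``prefiltered=True`` to skip the
    internal call).
    """
    acc = list(y.index)
    G = dosages if prefiltered else filter_sv_dosages(dosages)
    G = G[acc]
    if eigen is None:
        lam, U = eigh(kinship.loc[acc, acc].values)
        lam = np.clip(lam, 0, None)
    else:
        lam, U = eigen

    n = len(acc)
    C = np.ones((n, 1))
    if covariates is not None and covariates.shape[1] > 0:
        C = np.hstack([C, covariates.loc[acc].values.astype(float)])

    yt = U.T @ y.values.astype(float)
    Ct = U.T @ C
    R = G.values @ U
    beta, p = _gls_scan_one(yt, Ct, lam, R, R**2)
    res = pd.DataFrame({"sv": G.index, "beta": beta, "p": p})
    res = res[np.isfinite(res["p"])]
    res["p"] = res["p"].clip(lower=np.finfo(float).tiny)
    return res.reset_index(drop=True)


def eqtl_scan(
    expr: ExpressionMatrix,
    dosages: pd.DataFrame,
    covariates: Optional[pd.DataFrame],
    kinship: pd.DataFrame,
    maf_min: float = MAF_MIN,
    missing_max: float = MISSING_MAX,
) -> pd.DataFrame:
    """Scan every gene; returns tidy (gene, sv, beta, p) rows.

    The kinship eigendecomposition and the rotated dosage matrix are
    computed once and shared across genes; only the REML weights and the
    covariate projection are per-gene.
    """
    acc = list(expr.values.columns)
    G = filter_sv_dosages(dosages[acc], maf_min, missing_max)
    lam, U = eigh(kinship.loc[acc, acc].values)
    lam = np.clip(lam, 0, None)
    n = len(acc)
    C = np.ones((n, 1))
    if covariates is not None and covariates.shape[1] > 0:
        C = np.hstack([C, covariates.loc[acc].values.astype(float)])
    Ct = U.T @ C
    R = G.values @ U
    R2 = R**2
    out = []
    for gene, y in expr.values.iterrows():
        yt = U.T @ y.values.astype(float)
        beta, p = _gls_scan_one(yt, Ct, lam, R, R2)
        res = pd.DataFrame({"gene": gene, "sv": G.index, "beta": beta, "p": p})
        res = res[np.isfinite(res["p"])]
        res["p"] = res["p"].clip(lower=np.finfo(float).tiny)
        out.append(res)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# LD background and blocks
# ---------------------------------------------------------------------------


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    m1, m2 = np.nanmean(g1), np.nanmean(g2)
    a, b = g1 - m1, g2 - m2
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("nan")
    return float(((a * b).sum() / denom) ** 2)


def ld_background(
    dosages: pd.DataFrame,
    positions: pd.DataFrame,
    max_dist: float = 10e6,
    bin_width: float = 250_000,
    max_pairs: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Background LD level and the distance at which decay reaches it.

    Pairwise r^2 within ``max_dist`` is binned by distance; the background
    is the mean r^2 over the plateau (bins where the decay slope falls
    below 1% of its initial magnitude) and the background distance is
    where the smoothed curve first comes within 5% (of its total drop) of
    that level.  Falls back to the last bin with a warning when no plateau
    exists inside ``max_dist``.
    """
    ids = [i for i in dosages.index if i in positions.index]
    G = dosages.loc[ids].astype("float64")
    G = G.apply(lambda row: row.fillna(row.mean()), axis=1)
    var_ok = G.var(axis=1) > 0
    G = G.loc[var_ok]
    if G.shape[0] < 2:
        raise ValueError("need at least two polymorphic sites")
    pos = positions.loc[G.index]

    rng = np.random.default_rng(seed)
    pairs = []
    for chrom in pos["chrom"].unique():
        idx = np.where((pos["chrom"] == chrom).values)[0]
        p = pos["pos"].values[idx]
        order = np.argsort(p)
        idx, p = idx[order], p[order]
        for a in range(len(idx)):
            b = a + 1
            while b < len(idx) and p[b] - p[a] <= max_dist:
                pairs.append((idx[a], idx[b], p[b] - p[a]))
                b += 1
    if not pairs:
        raise ValueError("no site pairs within max_dist")
    if len(pairs) > max_pairs:
        chosen = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in chosen]

    X = G.values
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc * Xc).sum(axis=1))
    i1 = np.array([a for a, _, _ in pairs])
    i2 = np.array([b for _, b, _ in pairs])
    d = np.array([dd for _, _, dd in pairs], dtype=float)
    num = np.einsum("ij,ij->i", Xc[i1], Xc[i2])
    r2 = (num / (norms[i1] * norms[i2])) ** 2

    nbins = int(np.ceil(max_dist / bin_width))
    which = np.minimum((d / bin_width).astype(int), nbins - 1)
    sums = np.bincount(which, weights=r2, minlength=nbins)
    cnts = np.bincount(which, minlength=nbins)
    with np.errstate(invalid="ignore"):
        curve = sums / cnts
    ok = cnts > 0
    centers = (np.arange(nbins) + 0.5) * bin_width
    curve, centers = curve[ok], centers[ok]
    if len(curve) < 3:
        warnings.warn("too few distance bins; using last bin as background")
        return float(curve[-1]), float(centers[-1])

    k = min(5, len(curve))
    smooth = np.convolve(curve, np.ones(k) / k, mode="same")
    slope = np.gradient(smooth, centers)
    init = np.abs(slope[: max(2, len(slope) // 10)]).mean()
    plateau = np.abs(slope) < 0.01 * init if init > 0 else np.ones_like(slope, bool)
    if not plateau.any():
        warnings.warn("no LD plateau within max_dist; using r^2 at max distance")
        return float(smooth[-1]), float(centers[-1])
    bg = float(curve[plateau].mean())
    drop = smooth[0] - bg
    close = smooth - bg <= 0.05 * max(drop, 1e-12)
    dist_bg = float(centers[close][0]) if close.any() else float(centers[-1])
    return bg, dist_bg


def build_eqtl_blocks(
    results: pd.DataFrame,
    positions: pd.DataFrame,
    gene_coords: pd.DataFrame,
    dosages: pd.DataFrame,
    r2_bg: float,
    dist_bg: float,
    sig_threshold: float,
    min_svs: int = BLOCK_MIN_SVS,
    cis_window: float = CIS_WINDOW,
    member_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Chain significant SVs per gene into eQTL blocks and classify them.

    Adjacent significant SVs (position-sorted within a chromosome) join one
    block when their r^2 exceeds the LD background AND their distance is
    below the background decay distance; chains with at least ``min_svs``
    members survive.  The lead SV is the member with the smallest p
    (leftmost on ties); the block is cis when the lead SV is within
    ``cis_window`` of the gene's TSS or TES on the same chromosome.
    Output is invariant to the input row order.

    ``member_threshold`` supports the two-tier convention of a suggestive
    membership cutoff with a stricter significance requirement on the lead
    SV; when omitted both default to ``sig_threshold``.
    """
    member_threshold = member_threshold if member_threshold is not None else sig_threshold
    sig = results[results["p"] < max(member_threshold, sig_threshold)]
    G = dosages.astype("float64")
    G = G.apply(lambda row: row.fillna(row.mean()), axis=1)

    rows = []
    for gene, sub in sig.groupby("gene", sort=True):
        sub = sub.drop_duplicates("sv")
        svs = [s for s in sub["sv"] if s in positions.index]
        if len(svs) < min_svs:
            continue
        info = positions.loc[svs].copy()
        info["p"] = sub.set_index("sv").loc[svs, "p"]
        for chrom, chrom_svs in info.groupby("chrom", sort=True):
            chrom_svs = chrom_svs.sort_values("pos", kind="mergesort")
            ids = list(chrom_svs.index)
            chains: list[list[str]] = [[ids[0]]]
            for prev, cur in zip(ids, ids[1:]):
                dist = chrom_svs.loc[cur, "pos"] - chrom_svs.loc[prev, "pos"]
                r2 = pairwise_r2(G.loc[prev].values, G.loc[cur].values)
                if dist < dist_bg and r2 > r2_bg:
                    chains[-1].append(cur)
                else:
                    chains.append([cur])
            for chain in chains:
                if len(chain) < min_svs:
                    continue
                member = chrom_svs.loc[chain]
                lead = member.sort_values(["p", "pos"], kind="mergesort").index[0]
                if member.loc[lead, "p"] >= sig_threshold:
                    continue
                lead_pos = int(member.loc[lead, "pos"])
                g = gene_coords.loc[gene]
                same_chrom = g["chrom"] == chrom
                dist_gene = min(abs(lead_pos - int(g["tss"])), abs(lead_pos - int(g["tes"])))
                rows.append(
                    dict(
                        gene=gene,
                        chrom=chrom,
                        start=int(member["pos"].min()),
                        end=int(member["pos"].max()) + 1,
                        n_svs=len(chain),
                        svs=tuple(chain),
                        lead_sv=lead,
                        lead_p=float(member.loc[lead, "p"]),
                        lead_pos=lead_pos,
                        cis=bool(same_chrom and dist_gene <= cis_window),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "start", "end", "n_svs", "svs",
            "lead_sv", "lead_p", "lead_pos", "cis",
        ],
    )
    if len(df):
        df["class"] = np.where(df["cis"], "cis", "trans")
    else:
        df["class"] = pd.Series(dtype=object)
    return df


# ---------------------------------------------------------------------------
# hotspots and master regulators
# ---------------------------------------------------------------------------


def detect_hotspots(
    trans_blocks: pd.DataFrame,
    window: float = HOTSPOT_WINDOW,
    step: Optional[float] = None,
    adj_p_max: float = HOTSPOT_ADJ_P,
    genome_span: Optional[dict[str, tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Sliding-window Poisson clustering test on trans-eQTL lead positions.

    Windows are scored by the number of distinct target genes whose trans
    lead SV falls inside; the null rate is the genome-wide mean density of
    (gene, lead) points.  One-sided Poisson tail p-values are
    Benjamini-Hochberg adjusted across windows and overlapping significant
    windows merge into hotspots carrying their target-gene sets.
    """
    if trans_blocks.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_targets", "targets", "adj_p"]
        )
    step = step or window / 5
    points = trans_blocks[["gene", "chrom", "lead_pos"]].drop_duplicates()
    if genome_span is None:
        genome_span = {
            c: (0, int(points.loc[points["chrom"] == c, "lead_pos"].max()) + int(window))
            for c in points["chrom"].unique()
        }
    total_span = sum(hi - lo for lo, hi in genome_span.values())
    rate = len(points) * window / total_span  # expected targets per window

    wins = []
    for chrom, (lo, hi) in genome_span.items():
        sub = points[points["chrom"] == chrom]
        start = lo
        while start < hi:
            inside = sub[(sub["lead_pos"] >= start) & (sub["lead_pos"] < start + window)]
            n = inside["gene"].nunique()
            wins.append((chrom, int(start), int(start + window), n, tuple(sorted(inside["gene"].unique()))))
            start += step
    wdf = pd.DataFrame(wins, columns=["chrom", "start", "end", "n_targets", "targets"])
    wdf["p"] = stats.poisson.sf(wdf["n_targets"] - 1, rate)
    wdf.loc[wdf["n_targets"] == 0, "p"] = 1.0
    wdf["adj_p"] = multipletests(wdf["p"], method="fdr_bh")[1]

    sig = wdf[(wdf["adj_p"] < adj_p_max) & (wdf["n_targets"] > 0)].sort_values(
        ["chrom", "start"]
    )
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        cur = None
        for _, r in sub.iterrows():
            if cur is not None and r["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], r["end"])
                cur["targets"] |= set(r["targets"])
                cur["adj_p"] = min(cur["adj_p"], r["adj_p"])
            else:
                if cur is not None:
                    rows.append(cur)
                cur = dict(
                    chrom=chrom, start=r["start"], end=r["end"],
                    targets=set(r["targets"]), adj_p=r["adj_p"],
                )
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "targets", "adj_p"])
    if len(out):
        out["n_targets"] = out["targets"].map(len)
        out["targets"] = out["targets"].map(lambda s: tuple(sorted(s)))
    else:
        out["n_targets"] = pd.Series(dtype=int)
    return out[["chrom", "start", "end", "n_targets", "targets", "adj_p"]]


def iga_enrichment_p(ranked_is_target: Sequence[bool]) -> float:
    """Minimal hypergeometric prefix p over target positions in a ranking."""
    flags = np.asarray(ranked_is_target, dtype=bool)
    N = len(flags)
    t = int(flags.sum())
    if t == 0:
        return 1.0
    best = 1.0
    x = 0
    for j, f in enumerate(flags, start=1):
        if f:
            x += 1
            best = min(best, float(stats.hypergeom.sf(x - 1, N, t, j)))
    return best


def rank_master_regulator(
    targets: Sequence[str],
    expr: ExpressionMatrix,
    genes_in_window: Sequence[str],
) -> pd.DataFrame:
    """Rank hotspot-window genes as candidate master regulators.

    For each candidate, all other expressed genes are ranked by absolute
    Pearson correlation with the candidate and the hotspot's target genes
    are tested for enrichment at the top of that ranking with the minimal
    hypergeometric (iGA-style) prefix p.  Candidates are ordered by that p.
    """
    candidates = [g for g in genes_in_window if g in expr.values.index]
    if not candidates:
        raise ValueError("no expression data for any gene in the hotspot window")
    X = expr.values
    targets = set(targets)
    rows = []
    for cand in candidates:
        others = X.drop(index=cand)
        y = X.loc[cand].values.astype(float)
        yc = y - y.mean()
        denom_y = np.sqrt((yc * yc).sum())
        M = others.values.astype(float)
        Mc = M - M.mean(axis=1, keepdims=True)
        denom = np.sqrt((Mc * Mc).sum(axis=1)) * denom_y
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(Mc @ yc / denom)
        corr = np.nan_to_num(corr)
        order = np.argsort(-corr, kind="mergesort")
        flags = [others.index[i] in targets for i in order]
        rows.append(dict(candidate=cand, iga_p=iga_enrichment_p(flags)))
    out = pd.DataFrame(rows).sort_values(["iga_p", "candidate"], kind="mergesort")
    return out.reset_index(drop=True)
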
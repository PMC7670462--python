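"""Population analyses across domestication stages.

Per-group allele frequencies, a Fisher's-exact selection scan with
Bonferroni control over the domestication / improvement / modern-breeding
transitions, per-accession genotype composition, windowed nucleotide
diversity and Weir-Cockerham F_ST, and a genotype-sharing-ratio
introgression scan for wild segments in cultivated accessions.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .records import A_HOM, B_HOM, HET, STAGE_GROUPS, GenotypeMatrix

log = logging.getLogger(__name__)

#: corrected-P cutoff defining selection
SELECTION_ALPHA = 1e-3
#: sliding windows for diversity / F_ST / introgression (bp)
WINDOW_SIZE = 1_000_000
WINDOW_STEP = 250_000
#: introgression call thresholds
INTROGRESSION_RATIO_MAX = 0.9
INTROGRESSION_MIN_SVS = 2

STAGE_PAIRS = (("SP", "SLC"), ("SLC", "heirloom"), ("heirloom", "modern"))


def group_allele_frequencies(
    matrix: GenotypeMatrix, groups: Sequence[str] = STAGE_GROUPS
) -> pd.DataFrame:
    """Per-SV, per-group A/B allele counts and A-allele frequency.

    Counts follow the allele-dosage convention: A count = 2*A_HOM + HET over
    non-missing calls.  Groups with no called accession at an SV get NaN
    frequency.
    """
    out = {}
    for grp in groups:
        acc = matrix.accessions_in_group(grp)
        sub = matrix.calls[acc]
        n_called = sub.notna().sum(axis=1).astype(float)
        a = sub.astype("float64").sum(axis=1)  # dosage sum = 2*hom_A + het
        total = 2 * n_called
        b = total - a
        freq = np.where(total > 0, a / total.replace(0, np.nan), np.nan)
        out[(grp, "A")] = a.astype(float)
        out[(grp, "B")] = b.astype(float)
        out[(grp, "freq")] = freq
    df = pd.DataFrame(out, index=matrix.sv_ids)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["group", "stat"])
    return df


def fisher_selection_scan(
    freqs: pd.DataFrame,
    pair: tuple[str, str],
    alpha: float = SELECTION_ALPHA,
    bonferroni_m: Optional[int] = None,
) -> pd.DataFrame:
    """Two-tailed Fisher's exact test of allele counts between two groups.

    Bonferroni correction uses the number of SVs actually tested in this
    pair unless ``bonferroni_m`` overrides it.  SVs with a zero-margin table
    (a group entirely missing) are skipped.  ``selected`` marks corrected
    P < ``alpha``; ``direction`` records whether the A allele fell or rose
    from the first to the second group.
    """
    g1, g2 = pair
    rows = []
    for sv in freqs.index:
        a1, b1 = freqs.loc[sv, (g1, "A")], freqs.loc[sv, (g1, "B")]
        a2, b2 = freqs.loc[sv, (g2, "A")], freqs.loc[sv, (g2, "B")]
        if (a1 + b1) == 0 or (a2 + b2) == 0:
            log.debug("SV %s skipped in %s->%s: zero-margin table", sv, g1, g2)
            continue
        table = np.round([[a1, b1], [a2, b2]]).astype(np.int64)
        _, p = fisher_exact(table, alternative="two-sided")
        f1 = a1 / (a1 + b1)
        f2 = a2 / (a2 + b2)
        rows.append(
            dict(
                sv=sv,
                pair=f"{g1}->{g2}",
                p_raw=float(p),
                direction="A_down" if f2 < f1 else "A_up",
            )
        )
    res = pd.DataFrame(rows)
    if res.empty:
        raise ValueError("no SV with defined counts in both groups")
    m = bonferroni_m if bonferroni_m is not None else len(res)
    res["p_corrected"] = np.minimum(1.0, res["p_raw"] * m)
    res["selected"] = res["p_corrected"] < alpha
    return res.set_index("sv")


def genotype_composition(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-accession fractions of A_HOM / B_HOM / HET / MISSING over all SVs."""
    if matrix.calls.empty:
        raise ValueError("empty genotype matrix")
    n = len(matrix.sv_ids)
    c = matrix.calls
    return pd.DataFrame(
        {
            "A_HOM": (c == A_HOM).sum() / n,
            "B_HOM": (c == B_HOM).sum() / n,
            "HET": (c == HET).sum() / n,
            "MISSING": c.isna().sum() / n,
        }
    )


# ---------------------------------------------------------------------------
# windowed diversity and differentiation
# ---------------------------------------------------------------------------


def _windows(max_pos: int, window: int, step: int):
    start = 0
    while start <= max_pos:
        yield start, start + window
        start += step


def _site_pi(freq: np.ndarray, n_alleles: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity 2p(1-p) * n/(n-1) (0 where n < 2)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2 * freq * (1 - freq) * n_alleles / (n_alleles - 1)
    pi[n_alleles < 2] = 0.0
    return pi


def _wc_components(
    p: np.ndarray, h: np.ndarray, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components (a, b, c) per site, 2 populations.

    ``p``: allele-A frequencies (2 x sites); ``h``: observed heterozygote
    fractions; ``n``: individuals sampled per population.
    """
    r = 2
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def windowed_diversity_fst(
    matrix: GenotypeMatrix,
    groups: Sequence[str] = STAGE_GROUPS,
    pairs: Sequence[tuple[str, str]] = STAGE_PAIRS,
    window: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """Nucleotide diversity per group and Weir-Cockerham F_ST per pair,
    in sliding windows along genome A.

    pi is the sum of per-site heterozygosities (with the n/(n-1)
    small-sample correction) divided by the window length; F_ST is the
    ratio-of-averages estimator aggregated over the window's sites.
    Negative F_ST values are reported unclipped; windows without variants
    carry NaN statistics and a zero count.
    """
    if matrix.positions is None:
        raise ValueError("genotype matrix has no positions")
    pos = matrix.positions
    calls = matrix.calls

    # per-group per-site summaries
    stats = {}
    for grp in groups:
        acc = matrix.accessions_in_group(grp)
        sub = calls[acc].astype("float64").values
        called = ~np.isnan(sub)
        n_ind = called.sum(axis=1).astype(float)
        dose = np.nansum(sub, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = dose / (2 * n_ind)
        het = np.nansum(sub == 1, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            hfrac = het / n_ind
        stats[grp] = (freq, hfrac, n_ind)

    rows = []
    for chrom in pos["chrom"].unique():
        on_chrom = (pos["chrom"] == chrom).values
        p = pos["pos"].values
        for w0, w1 in _windows(int(p[on_chrom].max()), window, step):
            in_win = on_chrom & (p >= w0) & (p < w1)
            row = dict(chrom=chrom, start=w0, end=w1, n_variants=int(in_win.sum()))
            for grp in groups:
                freq, _, n_ind = stats[grp]
                if in_win.any():
                    pi = _site_pi(freq[in_win].copy(), 2 * n_ind[in_win])
                    row[f"pi_{grp}"] = float(np.nansum(pi)) / window
                else:
                    row[f"pi_{grp}"] = np.nan
            for g1, g2 in pairs:
                if not in_win.any():
                    row[f"fst_{g1}_{g2}"] = np.nan
                    continue
                pmat = np.vstack([stats[g1][0][in_win], stats[g2][0][in_win]])
                hmat = np.vstack([stats[g1][1][in_win], stats[g2][1][in_win]])
                nmat = np.vstack([stats[g1][2][in_win], stats[g2][2][in_win]])
                a, b, c = _wc_components(pmat, hmat, nmat)
                num = np.nansum(a)
                den = np.nansum(a + b + c)
                row[f"fst_{g1}_{g2}"] = float(num / den) if den > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def site_fst(p: np.ndarray, h: np.ndarray, n: np.ndarray) -> float:
    """Single-site Weir-Cockerham F_ST between two populations."""
    a, b, c = _wc_components(
        np.asarray(p, float).reshape(2, 1),
        np.asarray(h, float).reshape(2, 1),
        np.asarray(n, float).reshape(2, 1),
    )
    den = (a + b + c)[0]
    return float(a[0] / den) if den > 0 else float("nan")


# ---------------------------------------------------------------------------
# introgression
# ---------------------------------------------------------------------------


def introgression_scan(
    matrix: GenotypeMatrix,
    focal_groups: Sequence[str] = ("heirloom", "modern"),
    donor_group: str = "SP",
    window: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    ratio_max: float = INTROGRESSION_RATIO_MAX,
    min_svs: int = INTROGRESSION_MIN_SVS,
) -> pd.DataFrame:
    """Detect wild-donor introgression segments in cultivated accessions.

    For each SV call of a focal accession, the genotype-sharing ratio is the
    percentage of its own group sharing the exact genotype state divided by
    the percentage of donor (SP) accessions sharing it; the focal accession
    itself is excluded from its own group's percentage, and missing calls
    enter neither numerator nor denominator.  Sites with zero donor sharing
    are skipped.  Windows whose mean ratio is <= ``ratio_max`` with at
    least ``min_svs`` contributing SVs are reported.
    """
    if matrix.positions is None:
        raise ValueError("genotype matrix has no positions")
    donors = matrix.accessions_in_group(donor_group)
    if not donors:
        raise ValueError(f"donor group {donor_group!r} is empty")
    pos = matrix.positions
    calls = matrix.calls
    donor_calls = calls[donors].astype("float64").values

    rows = []
    for grp in focal_groups:
        members = matrix.accessions_in_group(grp)
        own_calls = calls[members].astype("float64").values
        for ai, acc in enumerate(members):
            mine = calls[acc].astype("float64").values
            have = ~np.isnan(mine)
            # own-group sharing excluding self
            own = own_calls.copy()
            own[:, ai] = np.nan
            own_n = (~np.isnan(own)).sum(axis=1)
            own_share = np.nansum(own == mine[:, None], axis=1)
            don_n = (~np.isnan(donor_calls)).sum(axis=1)
            don_share = np.nansum(donor_calls == mine[:, None], axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                own_pct = own_share / own_n
                don_pct = don_share / don_n
            usable = have & (don_pct > 0) & (own_n > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = own_pct / don_pct
            p = pos["pos"].values
            for chrom in pos["chrom"].unique():
                on_chrom = (pos["chrom"] == chrom).values & usable
                if not on_chrom.any():
                    continue
                for w0, w1 in _windows(int(p[(pos["chrom"] == chrom).values].max()), window, step):
                    in_win = on_chrom & (p >= w0) & (p < w1)
                    n = int(in_win.sum())
                    if n < min_svs:
                        continue
                    mean_ratio = float(np.nanmean(ratio[in_win]))
                    if mean_ratio <= ratio_max:
                        rows.append(
                            dict(
                                accession=acc,
                                group=grp,
                                chrom=chrom,
                                start=w0,
                                end=w1,
                                mean_ratio=mean_ratio,
                                n_svs=n,
                            )
                        )
    return pd.DataFrame(
        rows, columns=["accession", "group", "chrom", "start", "end", "mean_ratio", "n_svs"]
    )


def sharing_ratio(own_pct: float, donor_pct: float) -> float:
    """Genotype-sharing ratio for a single site (own-group % over donor %)."""
    if donor_pct <= 0:
        raise ValueError("donor sharing percentage must be positive")
    return own_pct / donor_pct
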
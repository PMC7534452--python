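"""Linkage disequilibrium: pairwise r^2, decay-versus-distance curves, and
the two-locus allelic-combination screen for incompatibility-like
segregation distortion.

r^2 is the squared Pearson correlation of {0,1} allele codes over lines
complete (homozygous, non-missing) at both SNPs.  Decay curves are
distance-binned means followed by isotonic (non-increasing) adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from . import codes
from .types import GenotypeMatrix, NAMPanel, RILPopulation


# ---------------------------------------------------------------------------
# pairwise r^2
# ---------------------------------------------------------------------------

def pairwise_r2(geno: GenotypeMatrix, snp_a, snp_b):
    """(r^2, p) between two SNPs over lines homozygous at both.

    Returns ``(nan, nan)`` with fewer than 3 complete pairs or when either
    SNP is monomorphic among them.
    """
    a = geno.marker_column(snp_a)
    b = geno.marker_column(snp_b)
    ok = codes.is_homozygous(a) & codes.is_homozygous(b)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    if np.var(x) == 0 or np.var(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


def _pairwise_r2_matrix(g: np.ndarray):
    """All-pairs r^2 for a code matrix, excluding HET/MISSING pairwise.

    Returns (r2, n_complete) as (m, m) arrays; entries with < 3 complete
    pairs or a monomorphic margin are nan.
    """
    valid = codes.is_homozygous(g)
    X = np.where(valid, g, 0).astype(float)
    V = valid.astype(float)
    n = V.T @ V
    sx = X.T @ V
    sy = sx.T
    sxy = X.T @ X
    sxx = (X**2).T @ V
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx**2
        vary = n * syy - sy**2
        r2 = cov**2 / (varx * vary)
    r2[(n < 3) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2, n.astype(int)


def _r2_pvalues(r2: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided correlation-test p-values from r^2 and pair counts."""
    with np.errstate(invalid="ignore", divide="ignore"):
        df = n - 2
        t2 = r2 * df / np.maximum(1 - r2, 1e-300)
        p = stats.f.sf(t2, 1, np.maximum(df, 1))
    p[np.isnan(r2) | (df < 1)] = np.nan
    return p


# ---------------------------------------------------------------------------
# decay curves
# ---------------------------------------------------------------------------

@dataclass
class LDDecay:
    n_snps: int
    pairs: pd.DataFrame           # chrom, dist_bp, r2
    bin_centers_bp: np.ndarray
    smoothed_r2: np.ndarray       # isotonic non-increasing
    level: float
    d_at_r2: float                # bp where the smoothed curve crosses level


def _geno_and_coords(obj):
    if isinstance(obj, NAMPanel):
        return obj.merged, obj.snp_chrom, obj.snp_bp
    if isinstance(obj, RILPopulation):
        t = obj.genetic_map.table
        order = {m: i for i, m in enumerate(obj.genotypes.marker_ids)}
        cols = np.array([order[m] for m in t["marker"]])
        return (obj.genotypes.take_markers(cols),
                t["chrom"].to_numpy(dtype=object),
                t["bp"].to_numpy(dtype=np.int64))
    raise TypeError("expected NAMPanel or RILPopulation")


def ld_decay(
    panel,
    n_snps: int = 10000,
    level: float = 0.1,
    seed=None,
    max_dist_bp: float = 10e6,
    n_bins: int = 50,
) -> LDDecay:
    """Intra-chromosomal LD decay on a random SNP sample.

    Samples up to ``n_snps`` SNPs without replacement, computes pairwise r^2
    for same-chromosome pairs separated by at most ``max_dist_bp``, averages
    r^2 in ``n_bins`` log-spaced distance bins, enforces monotone decay by
    isotonic regression, and reports the smallest distance at which the
    smoothed curve falls to ``level`` (the smallest sampled distance when
    the curve starts at or below the level).
    """
    geno, chroms, bps = _geno_and_coords(panel)
    rng = np.random.default_rng(seed)
    m = geno.n_markers
    take = np.sort(rng.choice(m, size=min(n_snps, m), replace=False))
    rows = []
    for chrom in pd.unique(chroms[take]):
        sel = take[chroms[take] == chrom]
        g = geno.geno[:, sel]
        pos = bps[sel]
        r2, _ = _pairwise_r2_matrix(g)
        iu, ju = np.triu_indices(len(sel), k=1)
        dist = pos[ju] - pos[iu]
        ok = (dist > 0) & (dist <= max_dist_bp) & ~np.isnan(r2[iu, ju])
        rows.append(pd.DataFrame({
            "chrom": chrom, "dist_bp": dist[ok], "r2": r2[iu, ju][ok]}))
    pairs = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "dist_bp", "r2"])
    if len(pairs) == 0:
        raise ValueError("no informative intra-chromosomal pair")
    d = pairs["dist_bp"].to_numpy(dtype=float)
    r2v = pairs["r2"].to_numpy(dtype=float)
    edges = np.geomspace(max(d.min(), 1.0), d.max() + 1, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=r2v, minlength=n_bins)
    cnts = np.bincount(which, minlength=n_bins)
    has = cnts > 0
    centers = np.sqrt(edges[:-1] * edges[1:])[has]
    means = sums[has] / cnts[has]
    iso = IsotonicRegression(increasing=False).fit(centers, means)
    smoothed = iso.predict(centers)
    if smoothed[0] <= level:
        d_at = float(d.min())
    else:
        below = np.flatnonzero(smoothed <= level)
        d_at = float(centers[below[0]]) if len(below) else float("inf")
    return LDDecay(
        n_snps=len(take), pairs=pairs, bin_centers_bp=centers,
        smoothed_r2=smoothed, level=level, d_at_r2=d_at,
    )


def interchromosomal_mean_r2(panel, n_snps: int = 2000, seed=None) -> float:
    """Mean r^2 over between-chromosome pairs of a random SNP sample."""
    geno, chroms, _ = _geno_and_coords(panel)
    rng = np.random.default_rng(seed)
    take = np.sort(rng.choice(geno.n_markers,
                              size=min(n_snps, geno.n_markers), replace=False))
    r2, _ = _pairwise_r2_matrix(geno.geno[:, take])
    iu, ju = np.triu_indices(len(take), k=1)
    inter = chroms[take][iu] != chroms[take][ju]
    vals = r2[iu, ju][inter]
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# incompatibility screen
# ---------------------------------------------------------------------------

@dataclass
class IncompatibilityHit:
    region_a: tuple  # (chrom, bp)
    region_b: tuple
    snp_a: object
    snp_b: object
    r2: float
    p_value: float
    combination_freqs: dict  # (state_a, state_b) -> frequency
    low_class: tuple         # ((state_a, state_b), frequency)


_CLASS_LABEL = {codes.REF: "REF", codes.ALT: "ALT"}


def _combination_freqs(a: np.ndarray, b: np.ndarray):
    ok = codes.is_homozygous(a) & codes.is_homozygous(b)
    n = int(ok.sum())
    freqs = {}
    for sa in (codes.REF, codes.ALT):
        for sb in (codes.REF, codes.ALT):
            label = (_CLASS_LABEL[sa], _CLASS_LABEL[sb])
            freqs[label] = float(np.sum((a[ok] == sa) & (b[ok] == sb)) / n) if n else float("nan")
    low = min(freqs.items(), key=lambda kv: kv[1])
    return freqs, low


def interchromosomal_screen(
    pop: RILPopulation,
    window_bp: float = 1e6,
    alpha: float = 0.05,
    refine: bool = True,
) -> list:
    """Scan thinned between-chromosome SNP pairs for distorted allelic
    combinations.

    One SNP per ``window_bp`` window (the least-missing SNP) represents each
    region; all cross-chromosome pairs are tested by the r^2 correlation
    test with Bonferroni correction at ``alpha``.  With ``refine`` each
    significant pair is re-localized over every SNP pair within one window
    of it, picking the pair with the most depleted allelic-combination
    class (ties broken by p-value) -- the depleted class, not the r^2 peak,
    is what marks the causal region pair in an incompatibility.  Hits are
    sorted by (depleted-class frequency, p-value).
    """
    geno, chroms, bps = _geno_and_coords(pop)
    if len(np.unique(chroms)) < 2:
        raise ValueError("need at least two chromosomes")
    miss = (geno.geno == codes.MISSING).sum(axis=0)
    keep = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        wins = (bps[idx] // int(window_bp)).astype(int)
        for w in np.unique(wins):
            cand = idx[wins == w]
            keep.append(cand[np.argmin(miss[cand])])
    keep = np.sort(np.array(keep))
    g = geno.geno[:, keep]
    r2, n = _pairwise_r2_matrix(g)
    p = _r2_pvalues(r2, n)
    iu, ju = np.triu_indices(len(keep), k=1)
    inter = chroms[keep][iu] != chroms[keep][ju]
    pv = p[iu, ju]
    tested = inter & ~np.isnan(pv)
    n_tests = int(tested.sum())
    if n_tests == 0:
        return []
    sig = tested & (pv < alpha / n_tests)
    hits = []
    seen = set()
    for i, j, pval in zip(iu[sig], ju[sig], pv[sig]):
        ka, kb = keep[i], keep[j]
        if refine:
            ka, kb = _refine_pair(geno, chroms, bps, ka, kb, window_bp)
        if (ka, kb) in seen:
            continue
        seen.add((ka, kb))
        a, b = geno.geno[:, ka], geno.geno[:, kb]
        freqs, low = _combination_freqs(a, b)
        r2_ab, p_ab = _pair_r2_scalar(a, b)
        hits.append(IncompatibilityHit(
            region_a=(chroms[ka], int(bps[ka])),
            region_b=(chroms[kb], int(bps[kb])),
            snp_a=geno.marker_ids[ka],
            snp_b=geno.marker_ids[kb],
            r2=r2_ab,
            p_value=p_ab,
            combination_freqs=freqs,
            low_class=low,
        ))
    hits.sort(key=lambda h: (h.low_class[1], h.p_value))
    return hits


def _pair_r2_scalar(a: np.ndarray, b: np.ndarray):
    ok = codes.is_homozygous(a) & codes.is_homozygous(b)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    x, y = a[ok].astype(float), b[ok].astype(float)
    if np.var(x) == 0 or np.var(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


def _refine_pair(geno, chroms, bps, ka, kb, window_bp):
    """Best SNP pair within one window of (ka, kb): minimal depleted-class
    frequency, ties by p-value."""
    cand_a = np.flatnonzero((chroms == chroms[ka])
                            & (np.abs(bps - bps[ka]) <= window_bp))
    cand_b = np.flatnonzero((chroms == chroms[kb])
                            & (np.abs(bps - bps[kb]) <= window_bp))
    ga = geno.geno[:, cand_a]
    gb = geno.geno[:, cand_b]
    va = codes.is_homozygous(ga).astype(float)
    vb = codes.is_homozygous(gb).astype(float)
    # class counts over pairwise-complete lines, one gemm per 2x2 class
    cnt = {}
    for sa in (codes.REF, codes.ALT):
        ia = ((ga == sa).astype(float))
        for sb in (codes.REF, codes.ALT):
            cnt[(sa, sb)] = ia.T @ ((gb == sb).astype(float))
    n = va.T @ vb
    with np.errstate(invalid="ignore", divide="ignore"):
        low = np.min(np.stack(list(cnt.values())), axis=0) / np.maximum(n, 1)
        # correlation-test p from the 2x2 counts
        n11, n10 = cnt[(codes.ALT, codes.ALT)], cnt[(codes.ALT, codes.REF)]
        n01, n00 = cnt[(codes.REF, codes.ALT)], cnt[(codes.REF, codes.REF)]
        num = (n11 * n00 - n10 * n01)
        den = ((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
        r2 = num**2 / np.maximum(den, 1e-300)
    p = _r2_pvalues(r2, n.astype(int))
    bad = (n < 3) | (den <= 0) | np.isnan(p)
    low[bad] = np.inf
    p[bad] = np.inf
    flat = np.lexsort((p.ravel(), low.ravel()))[0]
    ia, ib = np.unravel_index(flat, low.shape)
    if not np.isfinite(low[ia, ib]):
        return ka, kb
    return int(cand_a[ia]), int(cand_b[ib])


def simulate_incompatibility(
    pop: RILPopulation,
    locus_a,
    locus_b,
    lethal_class=(codes.REF, codes.ALT),
    survival: float = 0.0,
    seed=None,
) -> RILPopulation:
    """Remove lines carrying a lethal two-locus homozygote combination.

    Emulates loss during RIL development of lines homozygous for
    ``lethal_class = (state_at_a, state_at_b)`` at two unlinked loci;
    ``survival`` keeps that fraction of affected lines (1 -> identity).
    """
    if not (0 <= survival <= 1):
        raise ValueError("survival must lie in [0, 1]")
    t = pop.genetic_map.table.set_index("marker")
    if t.loc[locus_a, "chrom"] == t.loc[locus_b, "chrom"]:
        raise ValueError("incompatibility loci must be on different chromosomes")
    a = pop.genotypes.marker_column(locus_a)
    b = pop.genotypes.marker_column(locus_b)
    affected = (a == lethal_class[0]) & (b == lethal_class[1])
    rng = np.random.default_rng(seed)
    survive = ~affected
    if survival > 0:
        survive |= affected & (rng.random(len(a)) < survival)
    keep = np.flatnonzero(survive)
    if len(keep) == 0:
        raise ValueError("no line survives the incompatibility")
    return RILPopulation(
        name=pop.name, alt_parent=pop.alt_parent, generation=pop.generation,
        genotypes=pop.genotypes.take_lines(keep),
        genetic_map=pop.genetic_map,
        truth=[pop.truth[i] for i in keep] if pop.truth is not None else None,
    )
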
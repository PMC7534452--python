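"""Single-QTL genome scans in one RIL population.

Phenotypes are simulated at a chosen marker and percent variance explained
(PVE); the scan computes a LOD curve by maximum likelihood over a
two-homozygote normal mixture weighted by multipoint genotype probabilities
(equivalent to the marker regression at fully observed markers), with
genome-wide significance from permutations and localization by 1.5-LOD
support intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import codes
from .impute import GenotypeProbabilities
from .types import GeneticMap, GenotypeMatrix


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

@dataclass
class QTLSimSpec:
    """A simulated QTL: target marker, target PVE in (0,1), seed."""

    marker: object
    pve: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.pve < 1):
            raise ValueError("pve must lie in (0, 1)")


def qtl_indicator(column: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """0/1 QTL genotype indicator from a marker column.

    Homozygotes map directly; heterozygous and missing lines draw from the
    empirical homozygote-class ratio so no line is discarded.
    """
    x = np.where(column == codes.ALT, 1.0, 0.0)
    known = codes.is_homozygous(column)
    n_alt = int(np.sum(column[known] == codes.ALT))
    n_tot = int(known.sum())
    if n_tot == 0 or n_alt == 0 or n_alt == n_tot:
        raise ValueError("marker is monomorphic among observed homozygotes")
    p_alt = n_alt / n_tot
    unknown = ~known
    x[unknown] = (rng.random(int(unknown.sum())) < p_alt).astype(float)
    return x


def simulate_qtl_phenotype(geno: GenotypeMatrix, spec: QTLSimSpec) -> np.ndarray:
    """y = a*x + e with e ~ N(0,1) and a chosen so the expected PVE equals
    the target: a = sqrt(pve / ((1 - pve) * Var(x)))."""
    rng = np.random.default_rng(spec.seed)
    x = qtl_indicator(geno.marker_column(spec.marker), rng)
    vx = float(np.var(x))
    if vx == 0:
        raise ValueError("QTL indicator has zero variance")
    a = np.sqrt(spec.pve / ((1 - spec.pve) * vx))
    return a * x + rng.standard_normal(len(x))


# ---------------------------------------------------------------------------
# scan engine
# ---------------------------------------------------------------------------

def _homozygote_weights(probs: GenotypeProbabilities) -> np.ndarray:
    """P(ALT | data) renormalized over the two homozygote states; lines with
    no homozygote mass fall back to 1/2."""
    p_ref = probs.probs[..., 0]
    p_alt = probs.probs[..., 1]
    tot = p_ref + p_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(tot > 0, p_alt / np.maximum(tot, 1e-300), 0.5)
    return w


def scan_hk(probs: GenotypeProbabilities, phenotypes: np.ndarray) -> np.ndarray:
    """Regression (Haley-Knott) LOD over all markers, vectorized over
    phenotype columns.

    ``phenotypes`` is (n_lines,) or (n_lines, q); returns (n_markers,) or
    (n_markers, q).  At a fully observed marker this equals the
    maximum-likelihood marker-regression LOD (n/2) log10(RSS0/RSS1).
    """
    Y = np.atleast_2d(np.asarray(phenotypes, dtype=float).T).T  # (n, q)
    if np.allclose(Y.var(axis=0), 0):
        raise ValueError("phenotype has zero variance")
    W = _homozygote_weights(probs)  # (n, m)
    n = W.shape[0]
    Xc = W - W.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.einsum("nm,nm->m", Xc, Xc)
    sxy = Xc.T @ Yc  # (m, q)
    tss = np.einsum("nq,nq->q", Yc, Yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rss = tss[None, :] - sxy**2 / np.maximum(sxx, 1e-300)[:, None]
        lod = (n / 2) * np.log10(np.maximum(tss[None, :], 1e-300) /
                                 np.maximum(rss, 1e-300))
    lod[sxx <= 1e-12, :] = 0.0
    lod = np.maximum(lod, 0.0)
    return lod[:, 0] if np.asarray(phenotypes).ndim == 1 else lod


def scan_em(probs: GenotypeProbabilities, phenotype: np.ndarray,
            max_iter: int = 50, tol: float = 1e-8) -> np.ndarray:
    """Maximum-likelihood LOD via EM over a two-component normal mixture
    with genotype-probability weights, vectorized over markers."""
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    W = _homozygote_weights(probs)  # prior P(alt), (n, m)
    P = np.stack([1 - W, W], axis=2)  # (n, m, 2)
    m = W.shape[1]
    # null: single normal
    mu0 = y.mean()
    s0 = y.var()
    ll0 = -n / 2 * (np.log(2 * np.pi * s0) + 1)
    # init from weighted regression
    mu = np.empty((m, 2))
    sw = P.sum(axis=0)  # (m, 2)
    yw = np.einsum("n,nmg->mg", y, P)
    mu = yw / np.maximum(sw, 1e-12)
    resid2 = np.einsum("nmg,nmg->m", P, (y[:, None, None] - mu[None]) ** 2)
    sig2 = np.maximum(resid2 / n, 1e-12)
    ll = np.full(m, -np.inf)
    for _ in range(max_iter):
        # E step
        d = y[:, None, None] - mu[None]  # (n, m, 2)
        logdens = -0.5 * (np.log(2 * np.pi * sig2)[None, :, None] +
                          d**2 / sig2[None, :, None])
        wdens = P * np.exp(logdens - logdens.max(axis=2, keepdims=True))
        tot = wdens.sum(axis=2, keepdims=True)
        ll_new = (np.log(np.maximum(tot[..., 0], 1e-300)) +
                  logdens.max(axis=2)).sum(axis=0)
        R = wdens / np.maximum(tot, 1e-300)
        # M step
        Ng = R.sum(axis=0)  # (m, 2)
        mu = np.einsum("n,nmg->mg", y, R) / np.maximum(Ng, 1e-12)
        d = y[:, None, None] - mu[None]
        sig2 = np.maximum(np.einsum("nmg,nmg->m", R, d**2) / n, 1e-12)
        if np.all(np.abs(ll_new - ll) < tol):
            ll = ll_new
            break
        ll = ll_new
    return np.maximum((ll - ll0) / np.log(10), 0.0)


def scan_ml(probs: GenotypeProbabilities, phenotype: np.ndarray,
            method: str = "em") -> np.ndarray:
    """LOD curve over all marker positions."""
    if method == "em":
        return scan_em(probs, phenotype)
    if method == "hk":
        return scan_hk(probs, phenotype)
    raise ValueError("method must be 'em' or 'hk'")


# ---------------------------------------------------------------------------
# permutations, intervals, PVE
# ---------------------------------------------------------------------------

def permutation_threshold(
    probs: GenotypeProbabilities,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    method: str = "hk",
) -> float:
    """Genome-wide LOD threshold: the 100(1-alpha) percentile of the maximum
    LOD over phenotype permutations.

    Permutations default to the fast regression scan, which coincides with
    the ML scan at fully observed markers.  Fewer than 100 permutations is
    allowed but noisy.
    """
    import warnings
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives an unstable threshold")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    if method == "hk":
        lod = scan_hk(probs, perms)  # (m, n_perm)
        maxima = lod.max(axis=0)
    else:
        maxima = np.array([scan_em(probs, perms[:, j]).max()
                           for j in range(n_perm)])
    return float(np.quantile(maxima, 1 - alpha, method="lower")
                 if alpha >= 1.0 else np.quantile(maxima, 1 - alpha))


def lod_support_interval(gmap: GeneticMap, lod: np.ndarray, drop: float = 1.5):
    """Support interval around the (leftmost) LOD peak.

    The contiguous span on the peak chromosome where LOD >= peak - drop,
    expanded outward to the nearest flanking scanned positions below the
    cutoff (endpoints included); one-sided at chromosome ends.
    Returns ``(chrom, cm_lo, cm_hi)``.
    """
    table = gmap.table
    lod = np.asarray(lod, dtype=float)
    if len(lod) != len(table):
        raise ValueError("LOD curve length differs from map")
    peak = int(np.argmax(lod))  # argmax returns the first (leftmost) maximum
    chrom = table["chrom"].iloc[peak]
    on_chrom = np.flatnonzero((table["chrom"] == chrom).to_numpy())
    cm = table["cM"].to_numpy(dtype=float)[on_chrom]
    l = lod[on_chrom]
    p = int(np.flatnonzero(on_chrom == peak)[0])
    cutoff = l[p] - drop
    lo = p
    while lo > 0 and l[lo - 1] >= cutoff:
        lo -= 1
    if lo > 0:
        lo -= 1  # expand to the flanking position below the cutoff
    hi = p
    while hi < len(l) - 1 and l[hi + 1] >= cutoff:
        hi += 1
    if hi < len(l) - 1:
        hi += 1
    return chrom, float(cm[lo]), float(cm[hi])


def estimate_pve(peak_lod: float, n: int) -> float:
    """R-squared implied by a LOD score: 1 - 10^(-2 LOD / n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if peak_lod < 0:
        raise ValueError("LOD must be non-negative")
    return float(1 - 10 ** (-2 * peak_lod / n))


# ---------------------------------------------------------------------------
# one-stop scan summary
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    gmap: GeneticMap
    lod: np.ndarray
    peak_chrom: object
    peak_cm: float
    peak_lod: float
    threshold: float
    support_interval: tuple
    est_pve: float
    detected: bool

    def to_frame(self):
        import pandas as pd
        t = self.gmap.table.copy()
        t["lod"] = self.lod
        return t


def run_scan(
    probs: GenotypeProbabilities,
    gmap: GeneticMap,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    drop: float = 1.5,
    seed=None,
    method: str = "em",
) -> ScanResult:
    """Scan, permutation threshold, support interval and PVE in one call."""
    lod = scan_ml(probs, phenotype, method=method)
    thr = permutation_threshold(probs, phenotype, n_perm, alpha, seed=seed)
    peak = int(np.argmax(lod))
    interval = lod_support_interval(gmap, lod, drop)
    n = probs.probs.shape[0]
    return ScanResult(
        gmap=gmap,
        lod=lod,
        peak_chrom=gmap.table["chrom"].iloc[peak],
        peak_cm=float(gmap.table["cM"].iloc[peak]),
        peak_lod=float(lod[peak]),
        threshold=thr,
        support_interval=interval,
        est_pve=estimate_pve(float(lod[peak]), n),
        detected=bool(lod[peak] >= thr),
    )
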
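"""Merged NAM panels and kinship-corrected association.

Populations sharing the recurrent parent are merged on a common dense SNP
index; perfectly linked neighboring SNPs are collapsed; a joint-linkage map
is built from SNPs whose ALT state is shared by enough alternate founders;
and single-SNP association uses a univariate linear mixed model
y = mu + x*beta + u + e with u ~ N(0, sg^2 K), tested by likelihood ratio
against beta = 0 (chi-square, 1 df).  The variance ratio lambda = sg^2/se^2
is profiled by one spectral decomposition of K plus 1-D optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import codes, linkage
from .types import (
    FounderPanel,
    GeneticMap,
    GenotypeMatrix,
    NAMPanel,
    RILPopulation,
)

#: Genome-wide significance for NAM association (inclusive at the boundary);
#: the corresponding LRT statistic is ~15.14, a LOD-equivalent of ~3.3.
DETECTION_P = 1e-4


def _parse_marker(marker_id: str):
    chrom, bp = str(marker_id).rsplit("_", 1)
    return chrom, int(bp)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_populations(
    pops: list,
    dense_genotypes: list,
    founder_panel: Optional[FounderPanel] = None,
) -> NAMPanel:
    """Merge populations on the union of their dense SNP positions.

    Marker identity is ``chrom_bp`` on the shared reference coordinate
    system; a population lacking a SNP contributes MISSING there.  Line ids
    are made globally unique with a population prefix.
    """
    if len(pops) < 2:
        raise ValueError("need at least two populations to merge")
    all_ids = sorted(
        {m for g in dense_genotypes for m in g.marker_ids},
        key=_parse_marker,
    )
    # chromosome order: sort by (chrom, bp); chrom names sort lexically,
    # which matches chr1..chr5-style naming
    index = {m: j for j, m in enumerate(all_ids)}
    n_total = sum(g.n_lines for g in dense_genotypes)
    merged = np.full((n_total, len(all_ids)), codes.MISSING, dtype=np.int8)
    origin = np.zeros(merged.shape, dtype=np.uint8)
    line_ids, pop_of_line = [], []
    row = 0
    for pop, g in zip(pops, dense_genotypes):
        cols = np.array([index[m] for m in g.marker_ids])
        merged[row:row + g.n_lines, cols] = g.geno
        origin[row:row + g.n_lines, cols] = g.origin
        line_ids.extend(f"{pop.name}:{l}" for l in g.line_ids)
        pop_of_line.extend([pop.name] * g.n_lines)
        row += g.n_lines
    if len(set(line_ids)) != len(line_ids):
        raise ValueError("duplicate line ids after population prefixing")
    chroms = np.array([_parse_marker(m)[0] for m in all_ids], dtype=object)
    bps = np.array([_parse_marker(m)[1] for m in all_ids], dtype=np.int64)
    return NAMPanel(
        populations=list(pops),
        merged=GenotypeMatrix(
            np.array(line_ids, dtype=object),
            np.array(all_ids, dtype=object), merged, origin),
        snp_chrom=chroms,
        snp_bp=bps,
        population_of_line=np.array(pop_of_line, dtype=object),
        founder_panel=founder_panel,
    )


def collapse_perfect_ld(panel: NAMPanel):
    """Collapse runs of neighboring SNPs with identical genotype columns.

    Identity is with respect to both marker state and missing pattern; only
    adjacent SNPs on the same chromosome collapse, and the first SNP of a
    run is kept.  Returns ``(panel, representatives)`` where
    ``representatives`` maps each kept SNP id to the ids it absorbed.
    """
    g = panel.merged.geno
    same_chrom = panel.snp_chrom[1:] == panel.snp_chrom[:-1]
    identical = np.all(g[:, 1:] == g[:, :-1], axis=0) & same_chrom
    keep = np.concatenate([[True], ~identical])
    reps: dict = {}
    current = None
    for j, k in enumerate(keep):
        if k:
            current = panel.merged.marker_ids[j]
            reps[current] = []
        else:
            reps[current].append(panel.merged.marker_ids[j])
    idx = np.flatnonzero(keep)
    new = NAMPanel(
        populations=panel.populations,
        merged=panel.merged.take_markers(idx),
        snp_chrom=panel.snp_chrom[idx],
        snp_bp=panel.snp_bp[idx],
        population_of_line=panel.population_of_line,
        founder_panel=panel.founder_panel,
        kinship=panel.kinship,
    )
    return new, reps


# ---------------------------------------------------------------------------
# joint map
# ---------------------------------------------------------------------------

@dataclass
class JointMap:
    genetic_map: GeneticMap
    share_counts: np.ndarray  # alternates sharing ALT, per retained SNP
    genotypes: GenotypeMatrix  # recoded: non-polymorphic populations MISSING


def snp_share_counts(panel: NAMPanel) -> np.ndarray:
    """Number of alternate founders carrying ALT at each merged SNP."""
    if panel.founder_panel is None:
        raise ValueError("panel carries no founder information")
    fp = panel.founder_panel
    counts = np.empty(panel.n_snps, dtype=int)
    for chrom in np.unique(panel.snp_chrom):
        mask = panel.snp_chrom == chrom
        pos = panel.snp_bp[mask]
        ppos = fp.snp_positions[chrom]
        idx = np.searchsorted(ppos, pos)
        if np.any(idx >= len(ppos)) or np.any(ppos[np.minimum(idx, len(ppos)-1)] != pos):
            raise ValueError(f"merged SNPs on {chrom} missing from founder panel")
        counts[mask] = fp.alt_share_counts(chrom)[idx]
    return counts


def build_joint_map(panel: NAMPanel, min_shared: int = 11) -> JointMap:
    """Joint-linkage map over SNPs shared by >= ``min_shared`` alternates.

    Calls in populations whose alternate founder is REF at a retained SNP
    (non-polymorphic cross) are recoded MISSING, then the map is estimated
    from the merged recombinant fractions.
    """
    fp = panel.founder_panel
    counts = snp_share_counts(panel)
    keep = np.flatnonzero(counts >= min_shared)
    geno = panel.merged.take_markers(keep).copy()
    chroms = panel.snp_chrom[keep]
    bps = panel.snp_bp[keep]
    if len(keep) == 0:
        empty = GeneticMap(pd.DataFrame({"chrom": [], "marker": [], "bp": [], "cM": []}))
        return JointMap(empty, counts[keep], geno)
    # recode non-polymorphic populations to missing
    for pop in panel.populations:
        alt_row = fp.founder_row(pop.alt_parent)
        lines = np.isin(panel.population_of_line, [pop.name])
        for chrom in np.unique(chroms):
            cmask = chroms == chrom
            ppos = fp.snp_positions[chrom]
            idx = np.searchsorted(ppos, bps[cmask])
            poly = fp.snp_alleles[chrom][alt_row][idx] == 1
            cols = np.flatnonzero(cmask)[~poly]
            geno.geno[np.ix_(lines, cols)] = codes.MISSING
    pseudo_map = GeneticMap(pd.DataFrame({
        "chrom": chroms, "marker": geno.marker_ids,
        "bp": bps, "cM": np.zeros(len(keep)),
    }))
    pseudo_pop = RILPopulation(
        name="joint", alt_parent="joint", generation=8,
        genotypes=geno, genetic_map=pseudo_map,
    )
    est = linkage.estimate_map(pseudo_pop)
    return JointMap(est, counts[keep], geno)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def kinship_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """Centered-genotype cross-product kinship K = Gc Gc' / p.

    Codes are 0 (REF), 1 (ALT), 0.5 for heterozygotes; missing calls are
    mean-imputed per SNP before centering.  All-missing SNPs are dropped.
    """
    g = geno.geno.astype(float)
    g[geno.geno == codes.HET] = 0.5
    g[geno.geno == codes.MISSING] = np.nan
    valid = ~np.isnan(g)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(valid, g, 0.0).sum(axis=0) / np.maximum(n_valid, 1)
    keep = n_valid > 0
    g = g[:, keep]
    col_mean = col_mean[keep]
    if g.shape[1] < 2:
        raise ValueError("need at least two informative SNPs for kinship")
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    gc = g - col_mean
    return gc @ gc.T / g.shape[1]


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    beta_hat: float
    lambda_hat: float
    lrt_stat: float
    p_value: float
    detected: bool


class MixedModel:
    """ML mixed model on a fixed kinship; reusable across SNPs/phenotypes.

    One eigendecomposition K = U S U' at construction; each likelihood
    evaluation is O(n) after rotating y and X by U'.
    """

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        s, U = np.linalg.eigh(K)
        if s.min() < -1e-6 * max(1.0, s.max()):
            raise ValueError("K is not positive semidefinite")
        self.s = np.maximum(s, 0.0)
        self.U = U
        self.n = K.shape[0]

    def _ml(self, UTy: np.ndarray, UTX: np.ndarray):
        """Maximize the ML log-likelihood over lambda; returns
        (loglik, beta, lambda)."""
        n = self.n
        s = self.s

        def neg_ll(log10_lam):
            lam = 10.0 ** log10_lam
            w = lam * s + 1.0
            Xw = UTX / w[:, None]
            xtx = UTX.T @ Xw
            xty = Xw.T @ UTy
            beta = np.linalg.solve(xtx, xty)
            resid = UTy - UTX @ beta
            rss = float(np.sum(resid**2 / w))
            sig2 = max(rss / n, 1e-300)
            return 0.5 * (n * np.log(2 * np.pi * sig2) + np.sum(np.log(w)) + n)

        grid = np.linspace(-5, 5, 21)
        vals = [neg_ll(g) for g in grid]
        j = int(np.argmin(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            neg_ll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8})
        cands = [(res.fun, float(res.x)), (vals[j], float(grid[j]))]
        fun, x = min(cands)
        lam = 10.0 ** x
        w = lam * s + 1.0
        Xw = UTX / w[:, None]
        beta = np.linalg.solve(UTX.T @ Xw, Xw.T @ UTy)
        return -fun, beta, lam

    def lrt(self, phenotype: np.ndarray, snp: np.ndarray,
            detection_p: float = DETECTION_P) -> LMMResult:
        """Likelihood-ratio test of a SNP effect against beta = 0."""
        y = np.asarray(phenotype, dtype=float)
        x = np.asarray(snp, dtype=float)
        if len(y) != self.n or len(x) != self.n:
            raise ValueError("phenotype/SNP length differs from K")
        if np.var(x) == 0:
            raise ValueError("monomorphic SNP")
        UTy = self.U.T @ y
        ones = self.U.T @ np.ones(self.n)
        UTx = self.U.T @ x
        ll0, _, _ = self._ml(UTy, ones[:, None])
        ll1, beta, lam = self._ml(UTy, np.column_stack([ones, UTx]))
        lrt = max(0.0, 2 * (ll1 - ll0))
        p = float(stats.chi2.sf(lrt, df=1))
        p = max(p, np.finfo(float).tiny)
        return LMMResult(
            beta_hat=float(beta[1]),
            lambda_hat=float(lam),
            lrt_stat=float(lrt),
            p_value=p,
            detected=bool(p <= detection_p),
        )


def snp_dosage(column: np.ndarray) -> np.ndarray:
    """Float dosage for association: REF 0, ALT 1, HET 0.5, MISSING nan."""
    x = np.where(column == codes.ALT, 1.0,
                 np.where(column == codes.HET, 0.5, 0.0))
    x = np.where(column == codes.MISSING, np.nan, x)
    return x


def lmm_lrt(phenotype: np.ndarray, snp_codes: np.ndarray, K: np.ndarray,
            detection_p: float = DETECTION_P) -> LMMResult:
    """One-shot mixed-model LRT for a SNP column in genotype codes.

    Lines missing the SNP are dropped (K is subset accordingly).
    """
    x = snp_dosage(np.asarray(snp_codes))
    keep = ~np.isnan(x)
    y = np.asarray(phenotype, dtype=float)[keep]
    x = x[keep]
    if len(np.unique(x)) < 2:
        raise ValueError("monomorphic SNP among non-missing lines")
    Ksub = np.asarray(K, dtype=float)[np.ix_(keep, keep)]
    return MixedModel(Ksub).lrt(y, x, detection_p)


def detect(p_value: float, threshold: float = DETECTION_P) -> bool:
    """Detection rule: p <= threshold (inclusive at the boundary)."""
    if not (0 < p_value <= 1):
        raise ValueError("p-value must lie in (0, 1]")
    return bool(p_value <= threshold)
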
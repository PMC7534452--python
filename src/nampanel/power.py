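"""NAM power experiments.

Two scenarios over a merged panel: QTL at SNPs segregating in every
population (shared alleles) and QTL private to a single population, each
simulated across a grid of effect sizes with populations progressively
dropped in a random order per replicate.  Detection uses the mixed-model
likelihood-ratio test at the causal SNP (P <= 1e-4).  A third experiment
compares dense versus sparse marker maps within one RIL population
(detection, estimated PVE, 1.5-LOD interval size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc, codes, impute, qtl
from .types import NAMPanel, RILPopulation

#: PVE grid of the NAM power experiments (fractions).
DEFAULT_PVES = (0.05, 0.075, 0.10, 0.15, 0.20, 0.40, 0.80)


@dataclass
class PowerCurve:
    grid: pd.DataFrame  # n_populations, pve, detection_rate, n_reps, se
    scenario: str
    n_reps: int
    seed: object


@dataclass
class DensityComparison:
    records: pd.DataFrame
    summary: dict
    n_reps: int


# ---------------------------------------------------------------------------
# candidate SNPs
# ---------------------------------------------------------------------------

def universal_snps(panel: NAMPanel, max_missing: float = 0.2) -> np.ndarray:
    """Indices of SNPs whose ALT state is shared by every alternate founder
    (segregating in all populations), with at most ``max_missing`` missing
    calls panel-wide."""
    counts = assoc.snp_share_counts(panel)
    k = len(panel.founder_panel.alternates)
    cand = counts == k
    cand &= np.mean(panel.merged.geno == codes.MISSING, axis=0) <= max_missing
    cand &= _is_segregating(panel.merged.geno)
    idx = np.flatnonzero(cand)
    if len(idx) == 0:
        raise ValueError("no SNP segregates in all populations "
                         "(relax max_missing or densify the panel)")
    return idx


def private_snps(panel: NAMPanel, max_missing: float = 0.2) -> np.ndarray:
    """Indices of SNPs polymorphic in exactly one population."""
    counts = assoc.snp_share_counts(panel)
    cand = (counts == 1) & _is_segregating(panel.merged.geno)
    cand &= np.mean(panel.merged.geno == codes.MISSING, axis=0) <= max_missing
    idx = np.flatnonzero(cand)
    if len(idx) == 0:
        raise ValueError("no population-private SNP available")
    return idx


def _is_segregating(geno: np.ndarray) -> np.ndarray:
    has_ref = np.any(geno == codes.REF, axis=0)
    has_alt = np.any(geno == codes.ALT, axis=0)
    return has_ref & has_alt


# ---------------------------------------------------------------------------
# kinship cache
# ---------------------------------------------------------------------------

class _KinshipCache:
    """Per-subset kinship, keyed by the population subset, computed on a
    thinned SNP set for speed."""

    def __init__(self, panel: NAMPanel, max_snps: int = 800):
        self.panel = panel
        m = panel.n_snps
        step = max(1, m // max_snps)
        self.snp_idx = np.arange(0, m, step)
        self._cache: dict = {}

    def kinship(self, pop_names: tuple) -> np.ndarray:
        key = frozenset(pop_names)
        if key not in self._cache:
            lines = np.flatnonzero(
                np.isin(self.panel.population_of_line, list(pop_names)))
            sub = self.panel.merged.take_lines(lines).take_markers(self.snp_idx)
            self._cache[key] = (lines, assoc.kinship_matrix(sub))
        return self._cache[key]


# ---------------------------------------------------------------------------
# shared / private scenarios
# ---------------------------------------------------------------------------

def _phenotype_shared(x: np.ndarray, pve: float, rng) -> np.ndarray:
    vx = float(np.var(x))
    a = np.sqrt(pve / ((1 - pve) * vx))
    return a * x + rng.standard_normal(len(x))


def _evaluate_subsets(panel, cache, x, y, drop_order, detection_p):
    """Detection flag per nested subset size (all pops .. 1 pop)."""
    names = panel.population_names()
    out = {}
    current = list(names)
    for step in range(len(names)):
        lines, K = cache.kinship(tuple(current))
        x_sub = x[lines]
        y_sub = y[lines]
        ok = ~np.isnan(x_sub)
        if np.var(x_sub[ok]) == 0:
            detected = False
        else:
            res = assoc.lmm_lrt(y_sub[ok], _dosage_to_codes(x_sub[ok]),
                                K[np.ix_(ok, ok)], detection_p)
            detected = res.detected
        out[len(current)] = detected
        if step < len(drop_order):
            current.remove(drop_order[step])
    return out


def _dosage_to_codes(x: np.ndarray) -> np.ndarray:
    c = np.full(len(x), codes.MISSING, dtype=np.int8)
    c[x == 0.0] = codes.REF
    c[x == 1.0] = codes.ALT
    c[x == 0.5] = codes.HET
    return c


def run_shared_qtl_power(
    panel: NAMPanel,
    pves=DEFAULT_PVES,
    n_reps: int = 100,
    seed=None,
    detection_p: float = assoc.DETECTION_P,
    kinship_snps: int = 800,
) -> PowerCurve:
    """Power grid for QTL segregating in every population.

    Per replicate: draw a universal SNP, simulate one panel-wide phenotype
    at the target PVE, draw one population drop order, and evaluate
    detection at the causal SNP on the full panel and every nested subset.
    """
    rng = np.random.default_rng(seed)
    cand = universal_snps(panel)
    cache = _KinshipCache(panel, kinship_snps)
    names = panel.population_names()
    rows = []
    for pve in pves:
        hits = {n: 0 for n in range(1, len(names) + 1)}
        for _ in range(n_reps):
            j = int(rng.choice(cand))
            x = assoc.snp_dosage(panel.merged.geno[:, j])
            miss = np.isnan(x)
            if miss.any():
                p_alt = np.nanmean(x)
                x[miss] = (rng.random(int(miss.sum())) < p_alt).astype(float)
            y = _phenotype_shared(x, pve, rng)
            drop_order = list(rng.permutation(names))[:-1]
            det = _evaluate_subsets(panel, cache, x, y, drop_order, detection_p)
            for n, d in det.items():
                hits[n] += int(d)
        for n in sorted(hits):
            rate = hits[n] / n_reps
            rows.append({
                "n_populations": n, "pve": pve, "detection_rate": rate,
                "n_reps": n_reps,
                "se": float(np.sqrt(rate * (1 - rate) / n_reps)),
            })
    return PowerCurve(pd.DataFrame(rows), "shared", n_reps, seed)


def run_private_qtl_power(
    panel: NAMPanel,
    pves=DEFAULT_PVES,
    n_reps: int = 100,
    seed=None,
    detection_p: float = assoc.DETECTION_P,
    kinship_snps: int = 800,
) -> PowerCurve:
    """Power grid for QTL segregating in a single population.

    The effect size realizes the target PVE within the segregating
    population only; other populations contribute noise lines, and the
    segregating population is never dropped.
    """
    rng = np.random.default_rng(seed)
    cand = private_snps(panel)
    cache = _KinshipCache(panel, kinship_snps)
    names = panel.population_names()
    fp = panel.founder_panel
    rows = []
    for pve in pves:
        hits = {n: 0 for n in range(1, len(names) + 1)}
        for _ in range(n_reps):
            j = int(rng.choice(cand))
            # the segregating population is the one whose alternate founder
            # carries ALT at this SNP
            chrom = panel.snp_chrom[j]
            ppos = fp.snp_positions[chrom]
            sj = int(np.searchsorted(ppos, panel.snp_bp[j]))
            seg_pop = None
            for pop in panel.populations:
                if fp.snp_alleles[chrom][fp.founder_row(pop.alt_parent)][sj] == 1:
                    seg_pop = pop.name
                    break
            seg_lines = panel.lines_of(seg_pop)
            x = assoc.snp_dosage(panel.merged.geno[:, j])
            x[np.setdiff1d(np.arange(panel.n_lines), seg_lines)] = 0.0
            xs = x[seg_lines]
            miss = np.isnan(xs)
            if miss.any():
                p_alt = np.nanmean(xs) if np.isfinite(np.nanmean(xs)) else 0.5
                xs[miss] = (rng.random(int(miss.sum())) < p_alt).astype(float)
                x[seg_lines] = xs
            v_seg = float(np.var(xs))
            if v_seg == 0:
                continue
            a = np.sqrt(pve / ((1 - pve) * v_seg))
            y = a * x + rng.standard_normal(panel.n_lines)
            droppable = [nm for nm in names if nm != seg_pop]
            drop_order = list(rng.permutation(droppable))
            det = _evaluate_subsets(panel, cache, x, y, drop_order, detection_p)
            for n, d in det.items():
                hits[n] += int(d)
        for n in sorted(hits):
            rate = hits[n] / n_reps
            rows.append({
                "n_populations": n, "pve": pve, "detection_rate": rate,
                "n_reps": n_reps,
                "se": float(np.sqrt(rate * (1 - rate) / n_reps)),
            })
    return PowerCurve(pd.DataFrame(rows), "private", n_reps, seed)


# ---------------------------------------------------------------------------
# marker-density comparison
# ---------------------------------------------------------------------------

def run_density_comparison(
    pop: RILPopulation,
    sparse_markers,
    pves=(0.10, 0.30),
    n_reps: int = 100,
    n_perm: int = 200,
    seed=None,
    method: str = "hk",
) -> DensityComparison:
    """Dense-versus-sparse mapping of simulated QTL in one population.

    Per replicate: simulate a QTL at a random dense marker, scan with the
    full (dense) marker set and with the sparse subset, record detection
    (genome-wide permutation threshold at 5% plus correct chromosome),
    estimated PVE and 1.5-LOD interval width.  ``sparse_markers`` must be a
    subset of the population's markers.
    """
    rng = np.random.default_rng(seed)
    sparse_markers = np.asarray(sparse_markers, dtype=object)
    all_ids = pd.Index(pop.genotypes.marker_ids)
    sp_idx = all_ids.get_indexer(sparse_markers)
    if np.any(sp_idx < 0):
        raise ValueError("sparse markers must be a subset of the dense set")
    dense_probs = impute.genotype_probabilities(
        pop.genotypes, pop.genetic_map, generation=pop.generation)
    sparse_geno = pop.genotypes.take_markers(sp_idx)
    sparse_map_t = pop.genetic_map.table.set_index("marker").loc[
        sparse_markers].reset_index()
    from .types import GeneticMap
    sparse_map = GeneticMap(sparse_map_t[["chrom", "marker", "bp", "cM"]])
    sparse_probs = impute.genotype_probabilities(
        sparse_geno, sparse_map, generation=pop.generation)
    n = pop.n_lines
    seg = _is_segregating(pop.genotypes.geno)
    cand = np.flatnonzero(seg)
    recs = []
    for pve in pves:
        for rep in range(n_reps):
            j = int(rng.choice(cand))
            true_chrom = pop.genetic_map.table["chrom"].iloc[j]
            spec = qtl.QTLSimSpec(pop.genotypes.marker_ids[j], pve,
                                  seed=int(rng.integers(2**31)))
            y = qtl.simulate_qtl_phenotype(pop.genotypes, spec)
            rec = {"pve": pve, "rep": rep, "marker": spec.marker,
                   "chrom": true_chrom}
            for label, probs, gmap in (
                ("dense", dense_probs, pop.genetic_map),
                ("sparse", sparse_probs, sparse_map),
            ):
                res = qtl.run_scan(probs, gmap, y, n_perm=n_perm,
                                   seed=int(rng.integers(2**31)),
                                   method=method)
                det = res.detected and res.peak_chrom == true_chrom
                _, lo, hi = res.support_interval
                rec[f"detected_{label}"] = det
                rec[f"pve_{label}"] = res.est_pve
                rec[f"interval_{label}"] = hi - lo
            recs.append(rec)
    records = pd.DataFrame(recs)
    summary = summarize_density(records)
    return DensityComparison(records, summary, n_reps)


def summarize_density(records: pd.DataFrame) -> dict:
    """Per-PVE aggregates: detection rates, mean estimated PVE at detected
    QTL, mean interval sizes and percent interval reduction (over replicates
    detected by both marker sets)."""
    out = {}
    for pve, sub in records.groupby("pve"):
        both = sub[sub["detected_dense"] & sub["detected_sparse"]]
        mean_d = float(both["interval_dense"].mean()) if len(both) else float("nan")
        mean_s = float(both["interval_sparse"].mean()) if len(both) else float("nan")
        out[pve] = {
            "detected_dense_pct": 100 * float(sub["detected_dense"].mean()),
            "detected_sparse_pct": 100 * float(sub["detected_sparse"].mean()),
            "mean_pve_dense_pct": 100 * float(
                sub.loc[sub["detected_dense"], "pve_dense"].mean()),
            "mean_interval_dense_cM": mean_d,
            "mean_interval_sparse_cM": mean_s,
            "interval_reduction_pct": 100 * (1 - mean_d / mean_s)
            if mean_s and np.isfinite(mean_s) and mean_s > 0 else float("nan"),
        }
    return out


# ---------------------------------------------------------------------------
# power-curve summaries
# ---------------------------------------------------------------------------

def summarize_power(curve: PowerCurve, epsilon: float = 0.02) -> dict:
    """Marginal power gain per added population and the smallest panel size
    beyond which every incremental gain is at most ``epsilon``."""
    out = {}
    for pve, sub in curve.grid.groupby("pve"):
        sub = sub.sort_values("n_populations")
        rates = sub["detection_rate"].to_numpy()
        gains = np.diff(rates)
        knee = 1
        for i in range(len(gains) - 1, -1, -1):
            if gains[i] > epsilon:
                knee = i + 2
                break
        out[pve] = {
            "rates": rates.tolist(),
            "marginal_gains": gains.tolist(),
            "diminishing_after": int(knee),
        }
    return out
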
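"""Genetic-map estimation for selfing RIL populations.

Marker order is fixed by physical position; genetic distances are estimated
from adjacent-marker recombinant fractions, corrected for the accumulation of
recombination over generations of selfing (Haldane-Waddington: an observed
RIL recombinant fraction R corresponds to a per-meiosis fraction
r = R / (2(1-R))), and converted to centimorgans with a map function
(Kosambi by default, matching standard practice for these populations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes
from .types import GeneticMap, GenotypeMatrix, RILPopulation

#: Observed RIL recombinant fractions at or above 0.5 are clamped here and
#: flagged rather than rejected: on short chromosomes sampling noise can push
#: R_hat past the theoretical ceiling.
RF_CLAMP = 0.4999


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_d_from_r(r):
    """Kosambi map distance (cM) from recombination fraction.

    d = 25 * ln((1 + 2r) / (1 - 2r)); requires 0 <= r < 0.5.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r_from_d(d):
    """Inverse Kosambi: r = tanh(d / 50) / 2 for d in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane_d_from_r(r):
    """Haldane map distance (cM): d = -50 * ln(1 - 2r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1 - 2 * r)
    return float(d) if d.ndim == 0 else d


def haldane_r_from_d(d):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


_D_FROM_R = {"kosambi": kosambi_d_from_r, "haldane": haldane_d_from_r}
_R_FROM_D = {"kosambi": kosambi_r_from_d, "haldane": haldane_r_from_d}


def d_from_r(r, map_function: str = "kosambi"):
    return _D_FROM_R[map_function](r)


def r_from_d(d, map_function: str = "kosambi"):
    return _R_FROM_D[map_function](d)


# ---------------------------------------------------------------------------
# selfing-RIL correction
# ---------------------------------------------------------------------------

def ril_R_from_r(r):
    """Expected RIL (selfing, single-seed descent) recombinant fraction
    R = 2r / (1 + 2r) for per-meiosis fraction r."""
    r = np.asarray(r, dtype=float)
    R = 2 * r / (1 + 2 * r)
    return float(R) if R.ndim == 0 else R


def rf_from_ril_R(R):
    """Per-meiosis recombination fraction from an observed RIL recombinant
    fraction: r = R / (2(1-R)).  R >= 0.5 must be clamped by the caller."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("recombinant fraction must be non-negative")
    if np.any(R >= 0.5):
        raise ValueError(
            "RIL recombinant fraction >= 0.5 maps to r >= infinity; "
            "clamp to RF_CLAMP first"
        )
    r = R / (2 * (1 - R))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# recombinant-fraction estimation
# ---------------------------------------------------------------------------

def estimate_adjacent_rf(geno: GenotypeMatrix, marker_a, marker_b):
    """Observed recombinant fraction between two markers.

    Only lines homozygous and non-missing at both markers are informative;
    heterozygous calls are excluded (RILs are expected near-homozygous).
    Returns ``(R_hat, n_informative)``; ``R_hat`` is ``nan`` when no line is
    informative.
    """
    a = geno.marker_column(marker_a)
    b = geno.marker_column(marker_b)
    return _pair_rf(a, b)


def _pair_rf(a: np.ndarray, b: np.ndarray):
    informative = codes.is_homozygous(a) & codes.is_homozygous(b)
    n = int(informative.sum())
    if n == 0:
        return float("nan"), 0
    rec = int(np.sum(a[informative] != b[informative]))
    return rec / n, n


def _adjacent_rf_all(geno_codes: np.ndarray):
    """Vectorized R_hat over all adjacent marker pairs of a code matrix.

    Returns (R_hat, n_informative) arrays of length n_markers - 1.
    """
    hom = codes.is_homozygous(geno_codes)
    both = hom[:, :-1] & hom[:, 1:]
    diff = (geno_codes[:, :-1] != geno_codes[:, 1:]) & both
    n = both.sum(axis=0)
    with np.errstate(invalid="ignore"):
        R = np.where(n > 0, diff.sum(axis=0) / np.maximum(n, 1), np.nan)
    return R, n


# ---------------------------------------------------------------------------
# map estimation
# ---------------------------------------------------------------------------

def mask_singletons(geno_codes: np.ndarray) -> np.ndarray:
    """Mask apparent single-marker double crossovers (map-order columns).

    For each line, a homozygous call whose nearest non-missing neighbors on
    both sides are homozygous, equal to each other and different from it is
    set MISSING: at typical GBS marker spacing a genuine double crossover
    within one marker is far rarer than a genotyping error, and such
    singletons otherwise inflate the estimated map.
    """
    g = geno_codes.copy()
    for i in range(g.shape[0]):
        row = g[i]
        obs = np.flatnonzero(codes.is_homozygous(row))
        if len(obs) < 3:
            continue
        mid = row[obs[1:-1]]
        left = row[obs[:-2]]
        right = row[obs[2:]]
        bad = (left == right) & (left != mid)
        row[obs[1:-1][bad]] = codes.MISSING
    return g


def estimate_intervals(pop: RILPopulation, mask_errors: bool = True) -> pd.DataFrame:
    """Adjacent-interval recombination estimates for every marker interval.

    Columns: chrom, left, right, bp_gap, R_hat, n_informative, flagged.
    ``flagged`` marks intervals clamped at R >= 0.5 or with no informative
    line (R_hat is nan there).
    """
    geno = pop.genotypes
    gmap = pop.genetic_map
    marker_pos = {m: i for i, m in enumerate(geno.marker_ids)}
    rows = []
    for chrom in gmap.chromosomes():
        sub = gmap.chrom_table(chrom)
        markers = sub["marker"].to_numpy()
        bp = sub["bp"].to_numpy()
        cols = np.array([marker_pos[m] for m in markers])
        gsub = geno.geno[:, cols]
        if mask_errors:
            gsub = mask_singletons(gsub)
        R, n = _adjacent_rf_all(gsub)
        for i in range(len(markers) - 1):
            rows.append({
                "chrom": chrom, "left": markers[i], "right": markers[i + 1],
                "bp_gap": int(bp[i + 1] - bp[i]),
                "R_hat": R[i], "n_informative": int(n[i]),
                "flagged": bool(n[i] == 0 or (n[i] > 0 and R[i] >= 0.5)),
            })
    return pd.DataFrame(rows, columns=[
        "chrom", "left", "right", "bp_gap", "R_hat", "n_informative",
        "flagged"])


def estimate_map(pop: RILPopulation, map_function: str = "kosambi",
                 mask_errors: bool = True) -> GeneticMap:
    """Estimate a genetic map from RIL genotypes ordered by physical position.

    Estimation should run on observed (pre-imputation) genotypes: missing
    calls drop a line from an interval symmetrically, whereas run-filled
    calls would re-admit only non-recombinant lines and shrink the map.
    Each adjacent interval's cM length is ``d(r(R_hat))``; chromosome
    origins are at 0.  ``mask_errors`` removes single-marker apparent double
    crossovers first (see :func:`mask_singletons`).  Intervals with no
    informative line fall back to the chromosome's mean cM-per-bp rate
    applied to the physical gap (0 when the whole chromosome is
    uninformative).
    """
    intervals = estimate_intervals(pop, mask_errors=mask_errors)
    gmap = pop.genetic_map
    out_rows = []
    for chrom in gmap.chromosomes():
        sub = gmap.chrom_table(chrom)
        ivl = intervals[intervals["chrom"] == chrom]
        R = ivl["R_hat"].to_numpy(dtype=float)
        R = np.minimum(R, RF_CLAMP)
        ok = ~np.isnan(R)
        d = np.zeros(len(R))
        if ok.any():
            d[ok] = d_from_r(rf_from_ril_R(R[ok]), map_function)
            # physical-rate fallback for intervals with no informative line
            gaps = ivl["bp_gap"].to_numpy(dtype=float)
            total_ok_bp = gaps[ok].sum()
            rate = d[ok].sum() / total_ok_bp if total_ok_bp > 0 else 0.0
            d[~ok] = rate * gaps[~ok]
        cm = np.concatenate([[0.0], np.cumsum(d)])
        for marker, bp, c in zip(sub["marker"], sub["bp"], cm):
            out_rows.append({"chrom": chrom, "marker": marker, "bp": bp, "cM": c})
    return GeneticMap(pd.DataFrame(out_rows))


# ---------------------------------------------------------------------------
# map metrics
# ---------------------------------------------------------------------------

@dataclass
class MapMetrics:
    overall_length_cM: float
    avg_interval_cM: float
    max_interval_cM: float
    n_markers: int


def map_metrics(gmap: GeneticMap) -> MapMetrics:
    """Overall length, mean and max adjacent-interval size across chromosomes.

    Single-marker chromosomes contribute to ``n_markers`` but have no
    intervals.
    """
    intervals = []
    total = 0.0
    for chrom in gmap.chromosomes():
        cm = gmap.chrom_table(chrom)["cM"].to_numpy(dtype=float)
        if len(cm) >= 2:
            d = np.diff(cm)
            intervals.append(d)
            total += cm[-1] - cm[0]
    if not intervals:
        raise ValueError("no chromosome with >= 2 markers")
    allint = np.concatenate(intervals)
    return MapMetrics(
        overall_length_cM=float(total),
        avg_interval_cM=float(allint.mean()),
        max_interval_cM=float(allint.max()),
        n_markers=gmap.n_markers,
    )
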
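"""Synthetic NAM panel generator.

Simulates founder haplotypes, F8 RIL populations derived by selfing with
single-seed descent, and a GBS-style observation layer (marker subsetting,
missing calls, genotyping errors).  Meioses place crossovers as a Poisson
process on the genetic scale (no interference); genetic and physical
coordinates are related by a constant per-chromosome recombination rate.

Every stochastic entry point takes an explicit seed or ``numpy`` Generator;
identical seeds give byte-identical populations.
"""

from __future__ import annotations

import numpy as np

from . import codes, datasets
from .types import (
    Chromosome,
    CrossoverModel,
    FounderPanel,
    GeneticMap,
    GenotypeMatrix,
    HaplotypeMosaic,
    RILPopulation,
)

import pandas as pd

#: Arabidopsis-like genome used by default: five chromosomes, ~119 Mb and
#: ~510 cM in total.
DEFAULT_CHROMOSOMES = [
    Chromosome("chr1", 30_400_000, 121.0),
    Chromosome("chr2", 19_700_000, 92.0),
    Chromosome("chr3", 23_500_000, 99.0),
    Chromosome("chr4", 18_600_000, 88.0),
    Chromosome("chr5", 27_000_000, 110.0),
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------

def build_founder_panel(
    k_alternates: int,
    chromosomes=None,
    snp_density: float = 50.0,
    alt_sharing_profile=None,
    seed=None,
) -> FounderPanel:
    """Simulate a dense parental SNP panel.

    Parameters
    ----------
    k_alternates
        Number of alternate founders (the recurrent parent is added as
        founder 0 and is REF at every SNP).
    chromosomes
        List of :class:`Chromosome`; defaults to an Arabidopsis-like genome.
    snp_density
        Dense SNPs per Mb (uniformly placed positions).
    alt_sharing_profile
        Probabilities for the number of alternates sharing the ALT state,
        indexed q = 1..k; defaults to uniform.  Which alternates share is
        drawn uniformly per SNP, so founder alleles carry no haplotype
        structure of their own.
    """
    if k_alternates < 1:
        raise ValueError("need at least one alternate founder")
    if snp_density <= 0:
        raise ValueError("snp_density must be positive")
    chromosomes = list(DEFAULT_CHROMOSOMES if chromosomes is None else chromosomes)
    for c in chromosomes:
        if c.length_bp <= 0 or c.length_cM < 0:
            raise ValueError(f"invalid chromosome spec: {c}")
    k = k_alternates
    if alt_sharing_profile is None:
        profile = np.full(k, 1.0 / k)
    else:
        profile = np.asarray(alt_sharing_profile, dtype=float)
        if len(profile) != k or np.any(profile < 0):
            raise ValueError("alt_sharing_profile must be k non-negative weights")
        profile = profile / profile.sum()
    rng = _rng(seed)
    founder_ids = ["recurrent"] + [f"alt{i+1:02d}" for i in range(k)]
    positions, alleles = {}, {}
    for c in chromosomes:
        n_snps = max(1, int(round(snp_density * c.length_bp / 1e6)))
        pos = np.sort(rng.choice(c.length_bp, size=n_snps, replace=False)) + 1
        q = rng.choice(np.arange(1, k + 1), size=n_snps, p=profile)
        al = np.zeros((k + 1, n_snps), dtype=np.uint8)
        for j in range(n_snps):
            carriers = rng.choice(k, size=q[j], replace=False)
            al[carriers + 1, j] = 1
        positions[c.name] = pos.astype(np.int64)
        alleles[c.name] = al
    panel = FounderPanel(founder_ids, chromosomes, positions, alleles)
    panel.validate()
    return panel


def linear_map_for_positions(chrom: Chromosome, positions: np.ndarray) -> np.ndarray:
    """cM positions under the constant-rate cM/bp relation of the simulator."""
    return np.asarray(positions, dtype=float) / chrom.length_bp * chrom.length_cM


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _recombine(hap_a: HaplotypeMosaic, hap_b: HaplotypeMosaic,
               xo_bp: np.ndarray, start: int, length_bp: float) -> HaplotypeMosaic:
    """Compose a gamete mosaic from two parental mosaics and crossover
    positions (bp, sorted); ``start`` selects the haplotype at the left end."""
    haps = (hap_a, hap_b)
    bounds = np.concatenate([[0.0], np.asarray(xo_bp, dtype=float), [float(length_bp)]])
    ends_out: list = []
    orig_out: list = []
    cur = start
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            cur ^= 1
            continue
        h = haps[cur]
        i = int(np.searchsorted(h.ends, lo, side="right"))
        while i < len(h.ends):
            seg_end = min(float(h.ends[i]), hi)
            ends_out.append(seg_end)
            orig_out.append(h.origins[i])
            if h.ends[i] >= hi:
                break
            i += 1
        cur ^= 1
    mosaic = HaplotypeMosaic(np.asarray(ends_out), np.asarray(orig_out, dtype=np.int8))
    return mosaic.simplify()


def simulate_gamete(parent: dict, chromosomes, model: CrossoverModel, seed) -> dict:
    """One gamete from a parent's paired haplotype mosaics.

    ``parent`` maps chromosome name to ``(hap_a, hap_b)``; the crossover
    count per chromosome is Poisson with mean length_cM / 100.
    """
    rng = _rng(seed)
    out = {}
    for c in chromosomes:
        hap_a, hap_b = parent[c.name]
        out[c.name] = _gamete_one_chrom(hap_a, hap_b, c, rng)
    return out


def _gamete_one_chrom(hap_a, hap_b, chrom: Chromosome, rng) -> HaplotypeMosaic:
    n_xo = rng.poisson(chrom.length_cM / 100.0)
    xo_cm = np.sort(rng.uniform(0, chrom.length_cM, size=n_xo)) if n_xo else np.empty(0)
    xo_bp = xo_cm / chrom.length_cM * chrom.length_bp if chrom.length_cM > 0 else np.empty(0)
    start = int(rng.integers(2))
    return _recombine(hap_a, hap_b, xo_bp, start, chrom.length_bp)


# ---------------------------------------------------------------------------
# breeding
# ---------------------------------------------------------------------------

def breed_ril_population(
    panel: FounderPanel,
    alt_parent: str,
    n_lines: int,
    generations: int = 8,
    model: CrossoverModel | None = None,
    seed=None,
    name: str | None = None,
) -> RILPopulation:
    """Breed an F_t RIL population (F1 self, then single-seed descent).

    Genotypes are emitted at every dense SNP polymorphic in the cross
    (i.e., where the alternate parent carries ALT), coded as founder-origin
    symbols; the map is the generating (true) linear map at those positions.
    Truth mosaics are retained for oracle comparisons.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    if generations < 2:
        raise ValueError("generations must be >= 2")
    if alt_parent not in panel.alternates:
        raise ValueError(f"{alt_parent!r} is not an alternate founder of the panel")
    model = model or CrossoverModel()
    rng = _rng(seed)
    alt_row = panel.founder_row(alt_parent)

    poly_pos = {}
    for c in panel.chromosomes:
        mask = panel.snp_alleles[c.name][alt_row] == 1
        poly_pos[c.name] = panel.snp_positions[c.name][mask]

    truth = []
    for _ in range(n_lines):
        # F1: one recurrent-origin copy, one alternate-origin copy
        indiv = {
            c.name: (
                HaplotypeMosaic(np.array([float(c.length_bp)]), np.array([0], dtype=np.int8)),
                HaplotypeMosaic(np.array([float(c.length_bp)]), np.array([1], dtype=np.int8)),
            )
            for c in panel.chromosomes
        }
        for _gen in range(generations - 1):
            child = {}
            for c in panel.chromosomes:
                hap_a, hap_b = indiv[c.name]
                g1 = _gamete_one_chrom(hap_a, hap_b, c, rng)
                g2 = _gamete_one_chrom(hap_a, hap_b, c, rng)
                child[c.name] = (g1, g2)
            indiv = child
        truth.append(indiv)

    line_ids = np.array([f"L{i+1:04d}" for i in range(n_lines)], dtype=object)
    marker_ids, chrom_col, bp_col, cm_col = [], [], [], []
    geno_blocks = []
    pop = RILPopulation(
        name=name or f"{alt_parent}xrecurrent",
        alt_parent=alt_parent,
        generation=generations,
        genotypes=GenotypeMatrix(line_ids, np.empty(0, dtype=object),
                                 np.empty((n_lines, 0), dtype=np.int8)),
        genetic_map=GeneticMap(pd.DataFrame(
            {"chrom": [], "marker": [], "bp": [], "cM": []})),
        truth=truth,
    )
    for c in panel.chromosomes:
        pos = poly_pos[c.name]
        if len(pos) == 0:
            continue
        geno_blocks.append(pop.truth_genotypes(c.name, pos))
        marker_ids.extend(f"{c.name}_{p}" for p in pos)
        chrom_col.extend([c.name] * len(pos))
        bp_col.extend(pos.tolist())
        cm_col.extend(linear_map_for_positions(c, pos).tolist())
    geno = (np.concatenate(geno_blocks, axis=1)
            if geno_blocks else np.empty((n_lines, 0), dtype=np.int8))
    pop.genotypes = GenotypeMatrix(line_ids, np.array(marker_ids, dtype=object), geno)
    pop.genetic_map = GeneticMap(pd.DataFrame(
        {"chrom": chrom_col, "marker": marker_ids, "bp": bp_col, "cM": cm_col}))
    return pop


# ---------------------------------------------------------------------------
# GBS observation model
# ---------------------------------------------------------------------------

def sample_gbs_markers(pop: RILPopulation, n_markers: int, seed=None) -> np.ndarray:
    """Uniformly sample marker ids (without replacement) to act as the
    population's GBS marker set.  Sampling is independent per population, so
    GBS sets rarely overlap across populations."""
    rng = _rng(seed)
    n_markers = min(n_markers, pop.genotypes.n_markers)
    idx = np.sort(rng.choice(pop.genotypes.n_markers, size=n_markers, replace=False))
    return pop.genotypes.marker_ids[idx]


def apply_gbs_observation_model(
    pop: RILPopulation,
    marker_subset,
    missing_rate: float,
    geno_error_rate: float = 0.0,
    seed=None,
) -> RILPopulation:
    """Restrict to a marker subset and add GBS-style observation noise.

    Each retained call is independently set to MISSING with ``missing_rate``
    and (if still observed and homozygous) flipped to the opposite homozygote
    with ``geno_error_rate``.  Truth mosaics are untouched.
    """
    if not (0 <= missing_rate < 1 and 0 <= geno_error_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    marker_subset = np.asarray(marker_subset, dtype=object)
    if marker_subset.size == 0:
        raise ValueError("marker subset is empty")
    rng = _rng(seed)
    keep = pd.Index(pop.genotypes.marker_ids).get_indexer(marker_subset)
    if np.any(keep < 0):
        raise ValueError("marker subset contains unknown markers")
    geno = pop.genotypes.geno[:, keep].copy()
    if geno_error_rate > 0:
        hom = codes.is_homozygous(geno)
        flip = hom & (rng.random(geno.shape) < geno_error_rate)
        geno[flip] = 1 - geno[flip]
    miss = rng.random(geno.shape) < missing_rate
    geno[miss] = codes.MISSING
    sub_map = pop.genetic_map.table.set_index("marker").loc[marker_subset].reset_index()
    sub_map = sub_map[["chrom", "marker", "bp", "cM"]]
    return RILPopulation(
        name=pop.name,
        alt_parent=pop.alt_parent,
        generation=pop.generation,
        genotypes=GenotypeMatrix(pop.genotypes.line_ids.copy(), marker_subset, geno),
        genetic_map=GeneticMap(sub_map),
        truth=pop.truth,
    )


# ---------------------------------------------------------------------------
# informative-line selection
# ---------------------------------------------------------------------------

def count_breakpoints(pop: RILPopulation) -> np.ndarray:
    """Observed recombination breakpoints per line: transitions between
    consecutive non-missing homozygous calls of different state, summed over
    chromosomes."""
    geno = pop.genotypes
    gmap = pop.genetic_map
    pos = {m: i for i, m in enumerate(geno.marker_ids)}
    counts = np.zeros(geno.n_lines, dtype=int)
    for chrom in gmap.chromosomes():
        markers = gmap.chrom_table(chrom)["marker"].to_numpy()
        cols = np.array([pos[m] for m in markers])
        g = geno.geno[:, cols]
        for i in range(geno.n_lines):
            row = g[i]
            hom = row[codes.is_homozygous(row)]
            if len(hom) >= 2:
                counts[i] += int(np.sum(hom[:-1] != hom[1:]))
    return counts


def select_informative_lines(pop: RILPopulation, k: int) -> RILPopulation:
    """Keep the k most informative lines: more observed breakpoints first,
    fewer heterozygous calls as tie-break (then input order)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > pop.n_lines:
        raise ValueError("k exceeds the number of lines")
    breaks = count_breakpoints(pop)
    hets = (pop.genotypes.geno == codes.HET).sum(axis=1)
    order = np.lexsort((np.arange(pop.n_lines), hets, -breaks))
    keep = np.sort(order[:k])
    return RILPopulation(
        name=pop.name,
        alt_parent=pop.alt_parent,
        generation=pop.generation,
        genotypes=pop.genotypes.take_lines(keep),
        genetic_map=pop.genetic_map,
        truth=[pop.truth[i] for i in keep] if pop.truth is not None else None,
    )


# ---------------------------------------------------------------------------
# study-scale convenience
# ---------------------------------------------------------------------------

def simulate_study_populations(
    panel: FounderPanel,
    seed,
    lines_per_population=None,
    gbs_markers_per_population=None,
    missing_rates=None,
    geno_error_rate: float = 0.001,
    generations: int = 8,
):
    """Simulate one GBS-observed RIL population per alternate founder.

    Defaults reproduce the study conditions of the 14-population panel:
    population sizes, GBS marker counts and missing-data rates follow the
    per-population summary in :mod:`nampanel.datasets` (recycled if the
    panel has a different number of alternates).  Returns a list of
    populations carrying truth mosaics.
    """
    summary = datasets.ril_population_summary()
    k = len(panel.alternates)
    idx = np.arange(k) % len(summary)
    if lines_per_population is None:
        lines_per_population = summary["population_size"].to_numpy()[idx]
    else:
        lines_per_population = np.broadcast_to(
            np.asarray(lines_per_population), (k,))
    if gbs_markers_per_population is None:
        gbs_markers_per_population = summary["gbs_markers"].to_numpy()[idx]
    else:
        gbs_markers_per_population = np.broadcast_to(
            np.asarray(gbs_markers_per_population), (k,))
    if missing_rates is None:
        missing_rates = summary["missing_gbs_pct"].to_numpy()[idx] / 100.0
    else:
        missing_rates = np.broadcast_to(np.asarray(missing_rates, dtype=float), (k,))
    root = _rng(seed)
    pops = []
    for i, alt in enumerate(panel.alternates):
        sub = np.random.default_rng(root.integers(2**31))
        pop = breed_ril_population(
            panel, alt, int(lines_per_population[i]),
            generations=generations, seed=sub,
            name=f"pop{i+1:02d}_{alt}",
        )
        markers = sample_gbs_markers(pop, int(gbs_markers_per_population[i]), seed=sub)
        pops.append(apply_gbs_observation_model(
            pop, markers, float(missing_rates[i]), geno_error_rate, seed=sub))
    return pops
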
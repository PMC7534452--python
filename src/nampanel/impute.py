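"""Genotype imputation for RIL populations.

Three procedures:

* conservative "fill in" of missing GBS calls between flanking markers with
  identical homozygous genotypes (runs touching chromosome ends or spanning
  a state change -- i.e., recombination breakpoint regions -- stay missing);
* multipoint genotype probabilities from a per-chromosome Markov chain with
  states {REF, ALT, HET} (forward-backward), used to revert low-confidence
  filled calls;
* projection of dense parental SNPs into intervals anchored at both ends by
  like-state GBS calls, with an error model for double crossovers inside an
  anchored interval: a d-cM interval has error probability (d/100)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import codes, linkage
from .types import FounderPanel, GeneticMap, GenotypeMatrix, RILPopulation

_STATES = (codes.REF, codes.ALT, codes.HET)  # posterior column order


@dataclass
class GenotypeProbabilities:
    """Posterior state probabilities per line x marker.

    ``probs[:, :, s]`` is the posterior of state ``_STATES[s]``; columns are
    aligned with the genotype matrix the posteriors were computed from.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    probs: np.ndarray  # (n_lines, n_markers, 3)
    epsilon: float

    def state_probability(self, state_codes: np.ndarray) -> np.ndarray:
        """Posterior probability of the given state code per cell (cells with
        an invalid code get 0)."""
        out = np.zeros(state_codes.shape)
        for s_idx, s in enumerate(_STATES):
            mask = state_codes == s
            out[mask] = self.probs[..., s_idx][mask]
        return out


@dataclass
class ImputationReport:
    n_filled: int = 0
    n_projected: int = 0
    n_removed_low_confidence: int = 0
    missing_fraction_before: float = 0.0
    missing_fraction_after: float = 0.0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _chrom_column_order(geno: GenotypeMatrix, gmap: GeneticMap):
    """Yield (chrom, column indices in map order, cM positions)."""
    pos = {m: i for i, m in enumerate(geno.marker_ids)}
    for chrom in gmap.chromosomes():
        sub = gmap.chrom_table(chrom)
        cols = np.array([pos[m] for m in sub["marker"]])
        yield chrom, cols, sub["cM"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# fill in
# ---------------------------------------------------------------------------

def fill_in_missing(geno: GenotypeMatrix, gmap: GeneticMap):
    """Fill missing runs flanked on both sides by the same homozygous call.

    Runs touching a chromosome end, flanked by differing states, or flanked
    by a heterozygous call are left missing (these are chromosome ends and
    recombination breakpoint regions).  Observed calls are never altered.
    Returns ``(filled_matrix, report)``.
    """
    out = geno.copy()
    before = geno.missing_fraction()
    n_filled = 0
    for _, cols, _cm in _chrom_column_order(geno, gmap):
        g = out.geno[:, cols]
        o = out.origin[:, cols]
        for i in range(g.shape[0]):
            row = g[i]
            obs = np.flatnonzero(row != codes.MISSING)
            if len(obs) < 2:
                continue
            left = obs[:-1]
            right = obs[1:]
            gapped = right - left > 1
            for lo, hi in zip(left[gapped], right[gapped]):
                a, b = row[lo], row[hi]
                if a == b and a in (codes.REF, codes.ALT):
                    row[lo + 1:hi] = a
                    o[i, lo + 1:hi] = codes.ORIGIN_FILLED
                    n_filled += hi - lo - 1
        out.geno[:, cols] = g
        out.origin[:, cols] = o
    report = ImputationReport(
        n_filled=n_filled,
        missing_fraction_before=before,
        missing_fraction_after=out.missing_fraction(),
    )
    return out, report


# ---------------------------------------------------------------------------
# multipoint genotype probabilities
# ---------------------------------------------------------------------------

def _transition_matrix(d_cm: float, h: float, map_function: str) -> np.ndarray:
    """Markov transition across an interval of d cM.

    The chain jumps to its stationary distribution pi = ((1-h)/2, (1-h)/2, h)
    with probability rho, chosen so the homozygote-to-opposite-homozygote
    probability equals the RIL recombinant fraction R(d) of the interval.
    """
    r = linkage.r_from_d(d_cm, map_function)
    R = linkage.ril_R_from_r(r)
    pi = np.array([(1 - h) / 2, (1 - h) / 2, h])
    rho = min(1.0, 2 * R / (1 - h)) if h < 1 else 1.0
    return (1 - rho) * np.eye(3) + rho * np.tile(pi, (3, 1))


def _emissions(calls: np.ndarray, eps: float) -> np.ndarray:
    """(n_lines, n_markers, 3) emission likelihoods for observed calls."""
    e = np.ones(calls.shape + (3,))
    for s_idx, s in enumerate(_STATES):
        match = calls == s
        for t_idx in range(3):
            e[..., t_idx][match] = (1 - eps) if t_idx == s_idx else eps / 2
    e[calls == codes.MISSING] = 1.0
    return e


def genotype_probabilities(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    epsilon: float = 0.01,
    generation: int = 8,
    map_function: str = "kosambi",
) -> GenotypeProbabilities:
    """Forward-backward posterior over {REF, ALT, HET} per line and marker.

    The stationary distribution reflects residual F_t heterozygosity
    h = (1/2)^(t-1); transition probabilities follow the interval's RIL
    recombinant fraction; a matching call is emitted with probability
    1 - epsilon (epsilon split over the two other states); missing calls are
    uninformative.
    """
    if not (0 <= epsilon < 0.5):
        raise ValueError("epsilon must lie in [0, 0.5)")
    bad = ~np.isin(geno.geno, [codes.REF, codes.ALT, codes.HET, codes.MISSING])
    if bad.any():
        raise ValueError("unknown genotype code in matrix")
    h = 0.5 ** (generation - 1)
    pi = np.array([(1 - h) / 2, (1 - h) / 2, h])
    probs = np.empty((geno.n_lines, geno.n_markers, 3))
    for _, cols, cm in _chrom_column_order(geno, gmap):
        calls = geno.geno[:, cols]
        n_l, n_m = calls.shape
        E = _emissions(calls, epsilon)
        Ts = [_transition_matrix(cm[j + 1] - cm[j], h, map_function)
              for j in range(n_m - 1)]
        # scaled forward-backward, vectorized over lines
        alpha = np.empty((n_l, n_m, 3))
        scale = np.empty((n_l, n_m))
        a = pi[None, :] * E[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / scale[:, 0, None]
        for j in range(1, n_m):
            a = (alpha[:, j - 1] @ Ts[j - 1]) * E[:, j, :]
            scale[:, j] = a.sum(axis=1)
            alpha[:, j] = a / scale[:, j, None]
        beta = np.empty((n_l, n_m, 3))
        beta[:, -1] = 1.0
        for j in range(n_m - 2, -1, -1):
            b = (beta[:, j + 1] * E[:, j + 1, :]) @ Ts[j].T
            beta[:, j] = b / scale[:, j + 1, None]
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        probs[:, cols, :] = post
    return GenotypeProbabilities(geno.line_ids, geno.marker_ids, probs, epsilon)


def filter_low_confidence(
    filled: GenotypeMatrix,
    probs: GenotypeProbabilities,
    threshold: float = 0.99,
):
    """Revert filled calls whose posterior falls below ``threshold``.

    Observed calls are untouched.  Returns ``(matrix, n_removed)``.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    if filled.geno.shape != probs.probs.shape[:2]:
        raise ValueError("genotype matrix and probabilities differ in shape")
    out = filled.copy()
    filled_mask = out.origin == codes.ORIGIN_FILLED
    post = probs.state_probability(out.geno)
    revert = filled_mask & (post < threshold)
    out.geno[revert] = codes.MISSING
    out.origin[revert] = codes.ORIGIN_OBSERVED
    return out, int(revert.sum())


def conservative_impute(
    pop: RILPopulation,
    epsilon: float = 0.01,
    threshold: float = 0.99,
    map_function: str = "kosambi",
):
    """Fill-in followed by the multipoint low-confidence filter.

    Returns ``(population with imputed genotypes, ImputationReport)``.
    """
    filled, report = fill_in_missing(pop.genotypes, pop.genetic_map)
    probs = genotype_probabilities(
        filled, pop.genetic_map, epsilon,
        generation=pop.generation, map_function=map_function)
    kept, n_removed = filter_low_confidence(filled, probs, threshold)
    report.n_removed_low_confidence = n_removed
    report.missing_fraction_after = kept.missing_fraction()
    new_pop = RILPopulation(
        name=pop.name, alt_parent=pop.alt_parent, generation=pop.generation,
        genotypes=kept, genetic_map=pop.genetic_map, truth=pop.truth,
    )
    return new_pop, report


# ---------------------------------------------------------------------------
# dense parental SNP projection
# ---------------------------------------------------------------------------

def impute_parental_snps(pop: RILPopulation, panel: FounderPanel) -> GenotypeMatrix:
    """Project dense parental SNP alleles into like-anchored intervals.

    For each line and chromosome, consecutive non-missing homozygous GBS
    calls (anchors) with the same state define an interval; every dense SNP
    strictly inside receives that parent's allele (REF anchors -> the
    recurrent allele REF; ALT anchors -> the alternate parent's allele at
    that SNP, which is REF wherever the alternate carries the reference
    base).  Dense SNPs colocated with an anchor take the anchor's implied
    state.  Intervals with differing anchors, heterozygous calls, and
    chromosome-end overhangs stay MISSING.
    """
    geno = pop.genotypes
    gmap = pop.genetic_map
    alt_row = panel.founder_row(pop.alt_parent)
    chroms = [c.name for c in panel.chromosomes]
    for chrom in chroms:
        if chrom not in set(gmap.chromosomes()) and len(panel.snp_positions[chrom]):
            raise ValueError(f"dense SNPs on {chrom} but chromosome absent from map")
    marker_ids, out_blocks = [], []
    mpos = {m: i for i, m in enumerate(geno.marker_ids)}
    for chrom in chroms:
        dense_pos = panel.snp_positions[chrom]
        if len(dense_pos) == 0:
            continue
        alt_allele = panel.snp_alleles[chrom][alt_row].astype(np.int8)
        sub = gmap.chrom_table(chrom)
        cols = np.array([mpos[m] for m in sub["marker"]])
        gbs_bp = sub["bp"].to_numpy(dtype=np.int64)
        calls = geno.geno[:, cols]
        block = np.full((geno.n_lines, len(dense_pos)), codes.MISSING, dtype=np.int8)
        origin = np.full(block.shape, codes.ORIGIN_PROJECTED, dtype=np.uint8)
        for i in range(geno.n_lines):
            row = calls[i]
            anchor = codes.is_homozygous(row)
            a_idx = np.flatnonzero(anchor)
            if len(a_idx) == 0:
                continue
            a_bp = gbs_bp[a_idx]
            a_state = row[a_idx]
            # interval index for each dense SNP: between anchors k-1 and k
            k = np.searchsorted(a_bp, dense_pos, side="left")
            colocated = np.zeros(len(dense_pos), dtype=bool)
            inb = k < len(a_bp)
            colocated[inb] = a_bp[np.minimum(k, len(a_bp) - 1)][inb] == dense_pos[inb]
            interior = (~colocated) & (k > 0) & (k < len(a_bp))
            like = interior.copy()
            like[interior] = a_state[k[interior] - 1] == a_state[k[interior]]
            state = np.full(len(dense_pos), codes.MISSING, dtype=np.int8)
            src = np.empty(len(dense_pos), dtype=np.int8)
            src[like] = a_state[k[like]]
            src[colocated] = a_state[np.minimum(k, len(a_bp) - 1)[colocated]]
            assign = like | colocated
            alt_anchor = assign & (src == codes.ALT)
            ref_anchor = assign & (src == codes.REF)
            state[ref_anchor] = codes.REF
            state[alt_anchor] = alt_allele[alt_anchor]
            block[i] = state
            origin[i, colocated] = codes.ORIGIN_OBSERVED
            origin[i, state == codes.MISSING] = codes.ORIGIN_OBSERVED
        marker_ids.extend(f"{chrom}_{p}" for p in dense_pos)
        out_blocks.append((block, origin))
    genoM = np.concatenate([b for b, _ in out_blocks], axis=1)
    originM = np.concatenate([o for _, o in out_blocks], axis=1)
    return GenotypeMatrix(geno.line_ids.copy(),
                          np.array(marker_ids, dtype=object), genoM, originM)


def double_crossover_error_rate(d_cm, method: str = "linear"):
    """Probability that projection into a like-anchored d-cM interval is
    wrong because of a double crossover.

    ``linear`` (default): (d/100)^2.  ``kosambi``: (tanh(2 d/100)/2)^2, the
    Kosambi recombination fraction of the full interval squared.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("interval length must be non-negative")
    if method == "linear":
        rate = (d / 100.0) ** 2
    elif method == "kosambi":
        rate = (0.5 * np.tanh(2 * d / 100.0)) ** 2
    else:
        raise ValueError("method must be 'linear' or 'kosambi'")
    return float(rate) if rate.ndim == 0 else rate
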
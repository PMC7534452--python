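"""Core containers: founder panels, genetic maps, genotype matrices, RIL
populations and merged NAM panels.

Coordinates are 1-based base pairs on a shared reference coordinate system;
genetic positions are centimorgans with each chromosome starting at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import codes


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker map: identifiers with physical (bp) and genetic (cM) positions.

    Backed by a DataFrame with columns ``chrom``, ``marker``, ``bp``, ``cM``;
    rows are sorted by (chrom, bp) and each chromosome's cM origin is 0.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "marker", "bp", "cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)

    def validate(self) -> None:
        for chrom, sub in self.table.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            cm = sub["cM"].to_numpy(dtype=float)
            if not np.all(np.diff(bp) >= 0):
                raise ValueError(f"{chrom}: physical positions not sorted")
            if not np.all(np.diff(cm) >= -1e-9):
                raise ValueError(f"{chrom}: cM not non-decreasing")
            if not np.all(np.isfinite(cm)):
                raise ValueError(f"{chrom}: non-finite cM")

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_table(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def marker_index(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker": str}))


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Lines x markers genotype codes plus per-cell origin flags."""

    line_ids: np.ndarray
    marker_ids: np.ndarray
    geno: np.ndarray  # int8, (n_lines, n_markers)
    origin: np.ndarray = None  # uint8, same shape

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.origin is None:
            self.origin = np.zeros_like(self.geno, dtype=np.uint8)
        else:
            self.origin = np.asarray(self.origin, dtype=np.uint8)
        if self.geno.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("genotype matrix shape inconsistent with ids")
        if self.origin.shape != self.geno.shape:
            raise ValueError("origin flag shape inconsistent")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_fraction(self) -> float:
        return codes.missing_fraction(self.geno)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.line_ids.copy(), self.marker_ids.copy(),
            self.geno.copy(), self.origin.copy(),
        )

    def marker_column(self, marker_id) -> np.ndarray:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size != 1:
            raise KeyError(f"marker {marker_id!r} not found (or duplicated)")
        return self.geno[:, idx[0]]

    def take_lines(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.line_ids[idx], self.marker_ids,
            self.geno[idx], self.origin[idx],
        )

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.line_ids, self.marker_ids[idx],
            self.geno[:, idx], self.origin[:, idx],
        )


# ---------------------------------------------------------------------------
# haplotype mosaics (truth tracking for the simulator)
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMosaic:
    """Piecewise-constant founder origin along one chromosome copy.

    Segment ``i`` covers physical positions ``(ends[i-1], ends[i]]`` (1-based,
    ``ends[-1]`` equals the chromosome length); ``origins[i]`` is 0 for the
    recurrent parent and 1 for the alternate parent.
    """

    ends: np.ndarray
    origins: np.ndarray

    def origin_at(self, positions: np.ndarray) -> np.ndarray:
        seg = np.searchsorted(self.ends, np.asarray(positions), side="left")
        return self.origins[np.minimum(seg, len(self.origins) - 1)]

    def simplify(self) -> "HaplotypeMosaic":
        """Merge adjacent segments with equal origin."""
        keep = np.ones(len(self.origins), dtype=bool)
        keep[:-1] = self.origins[:-1] != self.origins[1:]
        return HaplotypeMosaic(self.ends[keep], self.origins[keep])

    def n_breakpoints(self) -> int:
        return int(np.sum(self.origins[:-1] != self.origins[1:]))


#: Truth for one line: chrom -> (maternal mosaic, paternal mosaic).
LineTruth = dict


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------

@dataclass
class Chromosome:
    name: str
    length_bp: int
    length_cM: float


@dataclass
class FounderPanel:
    """Dense parental SNP panel: one recurrent parent plus k alternates.

    ``snp_alleles[chrom]`` is founders x SNPs in {0 (REF), 1 (ALT)}; the
    recurrent parent (row 0) is REF everywhere by construction and every SNP
    is ALT in at least one alternate.
    """

    founder_ids: list
    chromosomes: list
    snp_positions: dict  # chrom -> int64 positions, strictly increasing
    snp_alleles: dict    # chrom -> uint8 (n_founders, n_snps)

    @property
    def recurrent(self) -> str:
        return self.founder_ids[0]

    @property
    def alternates(self) -> list:
        return self.founder_ids[1:]

    def chromosome(self, name) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def founder_row(self, founder_id) -> int:
        return self.founder_ids.index(founder_id)

    def n_snps(self) -> int:
        return int(sum(len(p) for p in self.snp_positions.values()))

    def alt_share_counts(self, chrom) -> np.ndarray:
        """Per SNP: number of alternate founders carrying the ALT state."""
        return self.snp_alleles[chrom][1:].sum(axis=0)

    def validate(self) -> None:
        for c in self.chromosomes:
            pos = self.snp_positions[c.name]
            al = self.snp_alleles[c.name]
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{c.name}: SNP positions not strictly increasing")
            if np.any(al[0] != 0):
                raise ValueError("recurrent parent must be REF at every SNP")
            if len(pos) and np.any(al[1:].sum(axis=0) == 0):
                raise ValueError("every SNP must be ALT in at least one alternate")


@dataclass
class CrossoverModel:
    """Meiosis model: crossovers as a Poisson process on the genetic scale
    (no interference); ``map_function`` governs distance<->fraction conversion
    on the estimation side."""

    map_function: str = "kosambi"

    def __post_init__(self) -> None:
        if self.map_function not in ("kosambi", "haldane"):
            raise ValueError("map_function must be 'kosambi' or 'haldane'")


# ---------------------------------------------------------------------------
# populations and panels
# ---------------------------------------------------------------------------

@dataclass
class RILPopulation:
    """One biparental RIL population derived by selfing with single-seed
    descent from recurrent x alternate."""

    name: str
    alt_parent: str
    generation: int
    genotypes: GenotypeMatrix
    genetic_map: GeneticMap
    truth: Optional[list] = None  # per line: chrom -> (hapA, hapB)

    def __post_init__(self) -> None:
        if self.generation < 2:
            raise ValueError("generation must be >= 2")

    @property
    def n_lines(self) -> int:
        return self.genotypes.n_lines

    def truth_genotypes(self, chrom, positions: np.ndarray) -> np.ndarray:
        """True founder-origin genotype codes at arbitrary positions."""
        if self.truth is None:
            raise ValueError("population carries no truth mosaics")
        out = np.empty((self.n_lines, len(positions)), dtype=np.int8)
        for i, line in enumerate(self.truth):
            hap_a, hap_b = line[chrom]
            a = hap_a.origin_at(positions)
            b = hap_b.origin_at(positions)
            g = np.where(a == b, a, codes.HET).astype(np.int8)
            out[i] = g
        return out


@dataclass
class NAMPanel:
    """Populations sharing a recurrent parent, merged on a common dense SNP
    index sorted by (chrom, bp)."""

    populations: list
    merged: GenotypeMatrix
    snp_chrom: np.ndarray
    snp_bp: np.ndarray
    population_of_line: np.ndarray  # population name per merged line
    founder_panel: Optional[FounderPanel] = None
    kinship: Optional[np.ndarray] = None

    @property
    def n_lines(self) -> int:
        return self.merged.n_lines

    @property
    def n_snps(self) -> int:
        return self.merged.n_markers

    def population_names(self) -> list:
        return [p.name for p in self.populations]

    def lines_of(self, pop_name) -> np.ndarray:
        return np.flatnonzero(self.population_of_line == pop_name)

    def subset_populations(self, names: Sequence) -> "NAMPanel":
        """Panel restricted to the given populations (kinship dropped)."""
        names = list(names)
        keep = np.isin(self.population_of_line, names)
        pops = [p for p in self.populations if p.name in names]
        return NAMPanel(
            populations=pops,
            merged=self.merged.take_lines(np.flatnonzero(keep)),
            snp_chrom=self.snp_chrom,
            snp_bp=self.snp_bp,
            population_of_line=self.population_of_line[keep],
            founder_panel=self.founder_panel,
            kinship=None,
        )
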
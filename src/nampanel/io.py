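"""File formats.

* Genotype CSV dialect: row 1 marker ids, row 2 chromosome, row 3 cM,
  optional row 4 bp; subsequent rows are line id plus one-letter codes
  A/B/H/- for REF/ALT/HET/MISSING.  Lossless round trip with the writer.
* Map TSV: chrom, marker, bp, cM (see :class:`nampanel.types.GeneticMap`).
* Parental SNPs as VCF (one sample per founder, GT 0/0 or 1/1, REF=A ALT=T)
  and dense imputed RIL genotypes as VCF (one sample per line, ./. allowed),
  both through pysam.
* Truth mosaics as a TSV sidecar (line, chrom, haplotype, segment end, origin).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import codes
from .types import (
    Chromosome,
    FounderPanel,
    GeneticMap,
    GenotypeMatrix,
    HaplotypeMosaic,
    RILPopulation,
)


class FormatError(ValueError):
    """Malformed input file; the message carries row/column coordinates."""


# ---------------------------------------------------------------------------
# genotype CSV dialect
# ---------------------------------------------------------------------------

def write_genotype_csv(pop: RILPopulation, path) -> None:
    geno = pop.genotypes
    t = pop.genetic_map.table.set_index("marker")
    order = [str(m) for m in geno.marker_ids]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + order)
        w.writerow(["chrom"] + [str(t.loc[m, "chrom"]) for m in order])
        w.writerow(["cM"] + [repr(float(t.loc[m, "cM"])) for m in order])
        w.writerow(["bp"] + [str(int(t.loc[m, "bp"])) for m in order])
        for i, line in enumerate(geno.line_ids):
            w.writerow([str(line)] +
                       [codes.CODE_TO_LETTER[int(c)] for c in geno.geno[i]])


def read_genotype_csv(path, generation: int = 8, name: str | None = None,
                      alt_parent: str = "alt") -> RILPopulation:
    """Parse the genotype CSV dialect; malformed cells are reported with
    1-based row/column coordinates."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise FormatError("need marker, chromosome and cM header rows plus data")
    header = rows[0]
    n_markers = len(header) - 1
    if n_markers < 1:
        raise FormatError("row 1: no marker columns")
    for r, row in enumerate(rows, start=1):
        if len(row) != n_markers + 1:
            raise FormatError(
                f"row {r}: expected {n_markers + 1} columns, got {len(row)}")
    markers = np.array(header[1:], dtype=object)
    chroms = np.array(rows[1][1:], dtype=object)
    try:
        cm = np.array([float(v) for v in rows[2][1:]])
    except ValueError as e:
        raise FormatError(f"row 3: bad cM value ({e})") from None
    data_start = 3
    bp = None
    if rows[3][0].strip().lower() == "bp":
        try:
            bp = np.array([int(v) for v in rows[3][1:]], dtype=np.int64)
        except ValueError as e:
            raise FormatError(f"row 4: bad bp value ({e})") from None
        data_start = 4
    if bp is None:
        # synthesize physical positions from cM order (1 bp per 0.0001 cM)
        bp = np.arange(1, n_markers + 1, dtype=np.int64)
    geno = np.empty((len(rows) - data_start, n_markers), dtype=np.int8)
    line_ids = []
    for i, row in enumerate(rows[data_start:]):
        line_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            try:
                geno[i, j] = codes.LETTER_TO_CODE[cell.strip()]
            except KeyError:
                raise FormatError(
                    f"row {data_start + i + 1}, column {j + 2}: "
                    f"unknown genotype code {cell!r}") from None
    table = pd.DataFrame({"chrom": chroms, "marker": markers, "bp": bp, "cM": cm})
    for chrom, sub in table.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["bp"].to_numpy()) >= 0):
            raise FormatError(f"chromosome {chrom}: physical positions unsorted")
        if not np.all(np.diff(sub["cM"].to_numpy()) >= -1e-12):
            raise FormatError(f"chromosome {chrom}: cM positions unsorted")
    return RILPopulation(
        name=name or Path(path).stem,
        alt_parent=alt_parent,
        generation=generation,
        genotypes=GenotypeMatrix(np.array(line_ids, dtype=object), markers, geno),
        genetic_map=GeneticMap(table),
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(contigs, samples) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs:
        h.contigs.add(name, length=int(length))
    h.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        h.add_sample(str(s))
    return h


def write_parental_vcf(panel: FounderPanel, path) -> None:
    """Founder panel as VCF: one sample per founder, REF=A, ALT=T."""
    contigs = [(c.name, c.length_bp) for c in panel.chromosomes]
    header = _vcf_header(contigs, panel.founder_ids)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in panel.chromosomes:
            pos = panel.snp_positions[c.name]
            al = panel.snp_alleles[c.name]
            for j, p in enumerate(pos):
                rec = out.new_record(
                    contig=c.name, start=int(p) - 1, stop=int(p),
                    alleles=("A", "T"), id=f"{c.name}_{p}")
                for f_idx, fid in enumerate(panel.founder_ids):
                    g = int(al[f_idx, j])
                    rec.samples[str(fid)]["GT"] = (g, g)
                out.write(rec)


def read_parental_vcf(path, recurrent_id: str = "recurrent",
                      cm_per_mb: float = 4.0) -> FounderPanel:
    """Founder panel from VCF.

    Only biallelic SNPs with homozygous or missing GT are accepted;
    heterozygous or multiallelic records are skipped.  Founders with
    missing calls at a SNP are treated as REF there (excluded from the ALT
    sharing count); SNPs left with no ALT alternate are dropped.  Genetic
    lengths are assigned at ``cm_per_mb``.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if recurrent_id not in samples:
            raise FormatError(f"recurrent parent sample {recurrent_id!r} missing")
        founder_ids = [recurrent_id] + [s for s in samples if s != recurrent_id]
        contig_len = {name: (c.length or 0)
                      for name, c in vf.header.contigs.items()}
        pos: dict = {}
        alleles: dict = {}
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multiallelic or ALT-less: skip
            states = []
            ok = True
            for s in founder_ids:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    states.append(0)
                elif gt[0] == gt[1] and gt[0] in (0, 1):
                    states.append(int(gt[0]))
                else:
                    ok = False  # heterozygous call: skip record
                    break
            if not ok or states[0] != 0 or sum(states[1:]) == 0:
                continue
            pos.setdefault(rec.chrom, []).append(rec.pos)
            alleles.setdefault(rec.chrom, []).append(states)
    chromosomes, positions, allele_mats = [], {}, {}
    for chrom in pos:
        p = np.array(pos[chrom], dtype=np.int64)
        a = np.array(alleles[chrom], dtype=np.uint8).T
        order = np.argsort(p)
        length = int(contig_len.get(chrom) or p.max())
        chromosomes.append(Chromosome(chrom, length, length / 1e6 * cm_per_mb))
        positions[chrom] = p[order]
        allele_mats[chrom] = a[:, order]
    panel = FounderPanel(founder_ids, chromosomes, positions, allele_mats)
    panel.validate()
    return panel


def write_dense_vcf(geno: GenotypeMatrix, snp_chrom: np.ndarray,
                    snp_bp: np.ndarray, path) -> None:
    """Dense (imputed) RIL genotypes as VCF, one sample per line."""
    contigs = [(c, int(snp_bp[snp_chrom == c].max()))
               for c in pd.unique(snp_chrom)]
    header = _vcf_header(contigs, geno.line_ids)
    gt_of = {codes.REF: (0, 0), codes.ALT: (1, 1),
             codes.HET: (0, 1), codes.MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(geno.n_markers):
            rec = out.new_record(
                contig=str(snp_chrom[j]), start=int(snp_bp[j]) - 1,
                stop=int(snp_bp[j]), alleles=("A", "T"),
                id=str(geno.marker_ids[j]))
            for i, line in enumerate(geno.line_ids):
                rec.samples[str(line)]["GT"] = gt_of[int(geno.geno[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# truth mosaics
# ---------------------------------------------------------------------------

def write_truth_tsv(pop: RILPopulation, path) -> None:
    if pop.truth is None:
        raise ValueError("population carries no truth mosaics")
    rows = []
    for line_id, line in zip(pop.genotypes.line_ids, pop.truth):
        for chrom, (hap_a, hap_b) in line.items():
            for h_idx, hap in enumerate((hap_a, hap_b)):
                for end, orig in zip(hap.ends, hap.origins):
                    rows.append((line_id, chrom, h_idx, float(end), int(orig)))
    pd.DataFrame(rows, columns=["line", "chrom", "hap", "end_bp", "origin"]) \
        .to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> dict:
    """Truth mosaics keyed by line id: {line: {chrom: (hapA, hapB)}}."""
    t = pd.read_csv(path, sep="\t")
    out: dict = {}
    for (line, chrom, hap), sub in t.groupby(["line", "chrom", "hap"]):
        mosaic = HaplotypeMosaic(sub["end_bp"].to_numpy(),
                                 sub["origin"].to_numpy(dtype=np.int8))
        slot = out.setdefault(line, {}).setdefault(chrom, [None, None])
        slot[int(hap)] = mosaic
    for line in out:
        for chrom in out[line]:
            out[line][chrom] = tuple(out[line][chrom])
    return out


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
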
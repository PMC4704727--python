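"""Reading and writing crosses in the R/qtl "csvr" (rotated CSV) dialect.

One row per variable: phenotype rows first (name, two empty cells, then one
value per line), then marker rows (name, chromosome, cM position, then one
genotype string per line).  Phenotype rows whose name parses as a number
define the time vector; other phenotype rows (typically "id") are kept as
line identifiers.  Genotype strings and the missing code are configurable,
defaulting to the QTL Archive conventions AA/BB (and AB for intercrosses)
with "-" for missing.
"""

from __future__ import annotations

import csv
import logging

import numpy as np

from .genetics import MISSING, Chromosome, CrossData, GeneticMap

logger = logging.getLogger("curveqtl")

DEFAULT_GENOTYPE_CODES = ("AA", "AB", "BB")
DEFAULT_NA_STRINGS = ("-", "NA", "")


def _is_number(s):
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_cross_csvr(path, cross_type="ril_self", genotype_codes=DEFAULT_GENOTYPE_CODES, na_strings=DEFAULT_NA_STRINGS):
    """Parse a csvr cross file into a :class:`~curveqtl.genetics.CrossData`."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]

    if cross_type == "ril_self":
        code_of = {genotype_codes[0]: 0, genotype_codes[-1]: 1}
    else:
        code_of = {genotype_codes[0]: 0, genotype_codes[1]: 1, genotype_codes[2]: 2}

    pheno_rows, marker_rows = [], []
    for r in rows:
        if len(r) < 4:
            raise ValueError(f"row {r[0]!r} has fewer than 4 columns")
        if r[1].strip() == "" and r[2].strip() == "":
            pheno_rows.append(r)
        else:
            marker_rows.append(r)
    if not marker_rows:
        raise ValueError("no marker rows (rows with chromosome and position) found")

    n = len(rows[0]) - 3
    times, pheno_vals, line_ids = [], [], None
    for r in pheno_rows:
        if _is_number(r[0]):
            times.append(float(r[0]))
            pheno_vals.append([float(v) if v.strip() not in na_strings else np.nan for v in r[3:]])
        else:
            line_ids = [v.strip() for v in r[3:]]

    chrom_order, by_chrom = [], {}
    geno_cols = []
    for r in marker_rows:
        name, chrom, pos = r[0].strip(), r[1].strip(), r[2].strip()
        if not _is_number(pos):
            raise ValueError(f"marker {name!r}: position {pos!r} is not numeric")
        if chrom not in by_chrom:
            chrom_order.append(chrom)
            by_chrom[chrom] = []
        by_chrom[chrom].append((name, float(pos)))
        col = np.empty(n, dtype=np.int8)
        for i, v in enumerate(r[3:]):
            v = v.strip()
            if v in na_strings:
                col[i] = MISSING
            elif v in code_of:
                col[i] = code_of[v]
            else:
                raise ValueError(f"unknown genotype code {v!r} at marker {name!r}, line {i + 1}")
        geno_cols.append(col)

    chroms = []
    col_order = []
    flat_idx = 0
    idx_of = {}
    for r in marker_rows:
        idx_of[r[0].strip()] = flat_idx
        flat_idx += 1
    for c in chrom_order:
        entries = by_chrom[c]
        pos = np.array([p for _, p in entries])
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"non-monotone map on chromosome {c!r}")
        chroms.append(Chromosome(c, tuple(m for m, _ in entries), pos))
        col_order.extend(idx_of[m] for m, _ in entries)
    genmap = GeneticMap(tuple(chroms))
    genotypes = np.column_stack([geno_cols[j] for j in col_order])

    phenotypes = times_arr = None
    if times:
        order = np.argsort(times, kind="stable")
        times_arr = np.array(times)[order]
        phenotypes = np.array(pheno_vals).T[:, order]

    cross = CrossData(
        cross_type,
        genmap,
        genotypes,
        phenotypes=phenotypes,
        times=times_arr,
        line_ids=line_ids or [],
    )
    n_missing = int(np.sum(~np.isfinite(phenotypes))) if phenotypes is not None else 0
    logger.info(
        "read %s: %d lines, %d markers on %d chromosomes, %d time points, %d missing phenotype cells",
        path,
        cross.n_lines,
        genmap.n_markers,
        len(genmap.chromosomes),
        0 if times_arr is None else times_arr.size,
        n_missing,
    )
    return cross


def write_cross_csvr(cross, path, genotype_codes=DEFAULT_GENOTYPE_CODES, na_string="-"):
    """Write a cross in csvr layout (phenotype rows, then marker rows)."""
    if cross.cross_type == "ril_self":
        code_str = {0: genotype_codes[0], 1: genotype_codes[-1], MISSING: na_string}
    else:
        code_str = {0: genotype_codes[0], 1: genotype_codes[1], 2: genotype_codes[2], MISSING: na_string}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "", ""] + list(cross.line_ids))
        if cross.phenotypes is not None:
            for j, t in enumerate(cross.times):
                w.writerow([repr(float(t)), "", ""] + [repr(float(v)) for v in cross.phenotypes[:, j]])
        col = 0
        for chrom in cross.genmap.chromosomes:
            for m, p in zip(chrom.markers, chrom.positions):
                w.writerow([m, chrom.name, repr(float(p))] + [code_str[int(g)] for g in cross.genotypes[:, col]])
                col += 1
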
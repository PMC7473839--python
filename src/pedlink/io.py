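"""Readers and writers for the external formats the pipeline touches.

PED/MAP (PLINK text dialect), VCF v4.2 (read via cyvcf2), and GMT gene-set
collections.  Readers validate and reject malformed input rather than
repairing it; every writer emits files its paired reader accepts.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (MISSING, UNKNOWN, GenotypeTable, Individual, MarkerPanel,
                    Pedigree)


class FormatError(ValueError):
    """Malformed input file; message names file, line and field."""


# ----------------------------------------------------------------------
# PED / MAP

_AFFECTION_OUT = {0: "0", 1: "1", 2: "2"}
_AFFECTION_IN = {"0": 0, "-9": 0, "1": 1, "2": 2}


def write_ped_map(pedigree: Pedigree, panel: MarkerPanel, table: GenotypeTable,
                  ped_path, map_path) -> None:
    """Write PLINK-style PED/MAP text files (alleles as letters, 0=missing)."""
    tab = panel.table
    with open(map_path, "w") as fh:
        for _, r in tab.iterrows():
            fh.write(f"{r['chrom']}\t{r['marker']}\t{r['cm']:g}\t{int(r['bp'])}\n")
    a1 = tab["a1"].to_numpy()
    a2 = tab["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for iid in table.ids:
            ind = pedigree[iid]
            fields = [pedigree.family_id, iid, ind.father or "0",
                      ind.mother or "0", str(ind.sex),
                      _AFFECTION_OUT[ind.affection]]
            row = table.alleles[table.row(iid)]
            for m in range(table.n_markers):
                for a in row[m]:
                    fields.append("0" if a == MISSING else
                                  (a1[m] if a == 0 else a2[m]))
            fh.write(" ".join(fields) + "\n")


def _parse_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(
                    f"{map_path}: line {lineno}: expected 4 fields "
                    f"(chrom marker cm bp), got {len(parts)}")
            chrom, marker, cm, bp = parts
            try:
                rows.append({"chrom": int(chrom) if chrom.isdigit() else chrom,
                             "marker": marker, "cm": float(cm), "bp": int(bp)})
            except ValueError as exc:
                raise FormatError(
                    f"{map_path}: line {lineno}: bad numeric field ({exc})")
    return pd.DataFrame(rows)


def read_ped_map(ped_path, map_path,
                 founder_freq_smoothing: float = 1.0
                 ) -> tuple[Pedigree, MarkerPanel, GenotypeTable]:
    """Read PED/MAP into (Pedigree, MarkerPanel, GenotypeTable).

    Allele labels per marker are taken from the data (lexicographic order);
    founder allele frequencies are estimated from founder genotypes with
    add-``founder_freq_smoothing`` smoothing.  0-coded genotypes become
    missing.  Unsorted MAP positions raise, naming the offending marker.
    """
    mp = _parse_map(map_path)
    if mp.empty:
        raise FormatError(f"{map_path}: no markers")
    n_markers = len(mp)

    inds, geno_rows, ids = [], [], []
    fam_id = None
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise FormatError(
                    f"{ped_path}: line {lineno}: fewer than 6 leading fields")
            n_allele = len(parts) - 6
            if n_allele != 2 * n_markers:
                raise FormatError(
                    f"{ped_path}: line {lineno}: {n_allele} allele fields, "
                    f"expected {2 * n_markers} for {n_markers} markers")
            fid, iid, father, mother, sex, aff = parts[:6]
            fam_id = fam_id or fid
            if aff not in _AFFECTION_IN:
                raise FormatError(
                    f"{ped_path}: line {lineno}: bad affection code {aff!r}")
            try:
                sex_i = int(sex)
            except ValueError:
                raise FormatError(
                    f"{ped_path}: line {lineno}: bad sex code {sex!r}")
            inds.append(Individual(iid, None if father == "0" else father,
                                   None if mother == "0" else mother,
                                   sex_i, _AFFECTION_IN[aff]))
            ids.append(iid)
            geno_rows.append(parts[6:])

    pedigree = Pedigree(inds, family_id=fam_id or "FAM")

    # collect observed allele labels per marker
    raw = np.array(geno_rows, dtype=object).reshape(len(ids), n_markers, 2)
    a1s, a2s = [], []
    codes = np.full((len(ids), n_markers, 2), MISSING, dtype=np.int8)
    for m in range(n_markers):
        obs = sorted({a for a in raw[:, m, :].ravel() if a != "0"})
        if len(obs) > 2:
            raise FormatError(
                f"{ped_path}: marker {mp['marker'][m]!r}: more than two alleles "
                f"observed ({obs})")
        labels = (obs + ["A", "C"])[:2] if len(obs) < 2 else obs
        a1s.append(labels[0])
        a2s.append(labels[1])
        lut = {labels[0]: 0, labels[1]: 1, "0": MISSING}
        for i in range(len(ids)):
            codes[i, m, 0] = lut[raw[i, m, 0]]
            codes[i, m, 1] = lut[raw[i, m, 1]]
        half = (codes[:, m, 0] == MISSING) != (codes[:, m, 1] == MISSING)
        if half.any():
            bad = ids[int(np.flatnonzero(half)[0])]
            raise FormatError(
                f"{ped_path}: marker {mp['marker'][m]!r}, individual {bad!r}: "
                "half-missing genotype")

    table = GenotypeTable(ids, mp["marker"].tolist(), codes)

    # founder-based allele-frequency estimate (add-one smoothing by default)
    founder_rows = [table.row(i) for i in pedigree.founders if i in table._row]
    s = founder_freq_smoothing
    freqs = []
    for m in range(n_markers):
        alle = codes[founder_rows, m, :].ravel() if founder_rows else np.array([])
        alle = alle[alle != MISSING]
        freqs.append((float((alle == 1).sum()) + s) / (len(alle) + 2 * s))
    mp = mp.assign(a1=a1s, a2=a2s, freq=freqs)
    try:
        panel = MarkerPanel(mp)
    except ValueError as exc:
        raise FormatError(f"{map_path}: {exc}")
    return pedigree, panel, table


# ----------------------------------------------------------------------
# VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=MAF,Number=1,Type=Float,Description="Population minor allele frequency">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Predicted effect">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(variants: pd.DataFrame, path) -> None:
    """Write per-(variant, sample) records as a VCF v4.2 text file.

    Expects columns chrom, pos, ref, alt, gene, effect, maf, sample, depth,
    genotype.  A NaN ``maf`` is omitted from INFO (variant absent from the
    population reference).
    """
    samples = sorted(variants["sample"].unique())
    keys = ["chrom", "pos", "ref", "alt"]
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("##contig=<ID=%s>\n" % ">\n##contig=<ID=".join(
            str(c) for c in sorted(variants["chrom"].unique())))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        grouped = variants.sort_values(["chrom", "pos"], kind="stable").groupby(
            keys, sort=True)
        for (chrom, pos, ref, alt), sub in grouped:
            first = sub.iloc[0]
            info = []
            if not (isinstance(first["maf"], float) and math.isnan(first["maf"])):
                info.append(f"MAF={first['maf']:.6g}")
            info.append(f"GENE={first['gene']}")
            info.append(f"EFFECT={first['effect']}")
            per_sample = {r["sample"]: r for _, r in sub.iterrows()}
            cols = []
            for s in samples:
                if s in per_sample:
                    r = per_sample[s]
                    dp = "." if pd.isna(r["depth"]) else str(int(r["depth"]))
                    cols.append(f"{r['genotype']}:{dp}")
                else:
                    cols.append("./.:.")
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                     f"{';'.join(info)}\tGT:DP\t" + "\t".join(cols) + "\n")


def read_vcf_variants(path) -> pd.DataFrame:
    """Read a VCF into per-(variant, sample) records.

    Returns columns chrom, pos, ref, alt, gene, effect, maf, sample, depth,
    genotype, depth_missing.  Samples without a called genotype for a
    variant are dropped; a called genotype whose DP is missing is kept with
    ``depth_missing=True`` (never silently discarded).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for rec in vcf:
        maf = rec.INFO.get("MAF")
        gene = rec.INFO.get("GENE")
        effect = rec.INFO.get("EFFECT")
        depths = rec.format("DP")
        gts = rec.genotypes
        for k, s in enumerate(samples):
            a, b = gts[k][0], gts[k][1]
            if a < 0 and b < 0:
                continue
            dp = None
            if depths is not None:
                d = int(depths[k][0])
                dp = None if d < 0 else d
            rows.append({
                "chrom": (int(rec.CHROM) if str(rec.CHROM).isdigit()
                          else rec.CHROM),
                "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0],
                "gene": gene, "effect": effect,
                "maf": math.nan if maf is None else float(maf),
                "sample": s,
                "depth": math.nan if dp is None else float(dp),
                "genotype": f"{a}/{b}",
                "depth_missing": dp is None,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name -> member genes.

    Duplicate genes within a set are stored once (order preserved); an
    empty set or a duplicated set name raises.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and "
                    "at least one gene")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene set {name!r}")
            if name in sets:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
    return sets


def write_gmt(sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")
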
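"""Genotype dosage container and VCF input/output.

Dosages are stored per sample and variant on the 0..2 scale (alternate-allele
copies); imputed data give fractional values, hard calls give 0/1/2.  Missing
genotypes are NaN.  Variant metadata carries a reference allele frequency of
the alternate allele, used to backfill missing dosages during scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "af"]


@dataclass
class GenotypeMatrix:
    """Per-sample alternate-allele dosages with variant metadata.

    Parameters
    ----------
    sample_ids : list of str
    variants : DataFrame with columns chrom, pos (1-based), ref, alt, af
        (reference allele frequency of the alt allele; NaN when unknown).
    dosages : float ndarray of shape (n_samples, n_variants), NaN = missing.
    """

    sample_ids: list = field(default_factory=list)
    variants: pd.DataFrame = None
    dosages: np.ndarray = None

    def __post_init__(self):
        if self.variants is None:
            self.variants = pd.DataFrame(columns=VARIANT_COLUMNS)
        if self.dosages is None:
            self.dosages = np.zeros((len(self.sample_ids), 0))
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise ValueError("dosages must lie in [0, 2] or be NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> pd.DataFrame:
        """(chrom, pos, ref, alt) tuples in variant order."""
        return self.variants[["chrom", "pos", "ref", "alt"]]


def read_vcf(path: str) -> GenotypeMatrix:
    """Read dosages from a VCF, preferring the DS FORMAT field over GT.

    GT calls are converted to alternate-allele counts 0/1/2; half-missing
    calls become NaN.  The INFO AF field, when present, populates the
    reference allele frequency column.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    cols = []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(len(samples))
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            d = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(float)
        af = var.INFO.get("AF")
        if isinstance(af, tuple):
            af = af[0]
        alts = var.ALT
        if len(alts) != 1:
            # keep multi-allelic records as one row per alt so harmonization
            # can detect and exclude the site
            for alt in alts:
                rows.append((str(var.CHROM), int(var.POS), var.REF, alt,
                             float(af) if af is not None else np.nan))
                cols.append(d)
            continue
        rows.append((str(var.CHROM), int(var.POS), var.REF, alts[0],
                     float(af) if af is not None else np.nan))
        cols.append(d)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(cols) if cols else np.zeros((len(samples), 0))
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosages)


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCFv4.2 with a DS FORMAT field and INFO AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = pd.unique(gm.variants["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            af = "." if pd.isna(row.af) else f"{row.af:.6g}"
            ds = ["." if np.isnan(d) else f"{d:g}" for d in gm.dosages[:, j]]
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                     f"AF={af}\tDS\t" + "\t".join(ds) + "\n")


def read_dosage_matrix(path: str) -> GenotypeMatrix:
    """Read a plain tab-separated dosage matrix.

    Expected layout: columns chrom, pos, ref, alt, af then one column per
    sample; one row per variant.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"dosage matrix missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(
        sample_ids=sample_cols,
        variants=df[VARIANT_COLUMNS].reset_index(drop=True),
        dosages=dosages,
    )
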
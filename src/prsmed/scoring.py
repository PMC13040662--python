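"""PRS scoring-file parsing, variant harmonization, and score computation.

A polygenic risk score is a weighted sum of effect-allele dosages,
raw_i = sum_j w_j * d'_ij, where w_j are per-variant effect weights from a
scoring file and d'_ij is the effect-allele dosage of sample i at variant j.
Harmonization decides, for every scoring-file variant, whether it can be
matched to a genotyped variant (possibly with an allele flip), must be
excluded (strand-ambiguous, multi-allelic, duplicated, non-autosomal), or is
absent from the genotype data and has its dosage backfilled with twice a
reference allele frequency.  Scores are only evaluated for scoring files
whose variant match rate exceeds a threshold (default 75%), and raw scores
are Z-standardized before any downstream modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, HarmonizationError, ScoringError
from .genotypes import GenotypeMatrix

REQUIRED_COLUMNS = [
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
]

AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

AUTOSOMES = {str(i) for i in range(1, 23)}

# per-variant dispositions assigned by harmonize()
MATCHED = "matched"
BACKFILL = "backfill"
AMBIGUOUS = "excluded_ambiguous"
MULTIALLELIC = "excluded_multiallelic"
DUPLICATED = "excluded_duplicated"
NONAUTOSOMAL = "excluded_nonautosomal"


@dataclass
class ScoringFile:
    """Variant effect weights in the PGS-Catalog scoring dialect."""

    score_id: str
    variants: pd.DataFrame  # chr_name, chr_position, effect_allele, other_allele, effect_weight

    def __post_init__(self):
        w = self.variants["effect_weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise FormatError(f"{self.score_id}: non-finite effect weights")
        pos = self.variants["chr_position"].to_numpy()
        if np.any(pos <= 0):
            raise FormatError(f"{self.score_id}: non-positive variant positions")

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class HarmonizationReport:
    """Per-variant dispositions and aggregate counts for one scoring file.

    ``match_rate`` counts only variants positively matched to a genotyped
    variant; backfilled variants still contribute allele-frequency dosage to
    scores but do not count toward the match-rate gate.
    """

    score_id: str
    table: pd.DataFrame  # disposition, flip, geno_index, effect_is_alt
    n_total: int = 0
    n_matched: int = 0
    n_missing_backfilled: int = 0
    n_excluded_ambiguous: int = 0
    n_excluded_multiallelic: int = 0
    n_excluded_duplicated: int = 0
    n_excluded_nonautosomal: int = 0

    def __post_init__(self):
        counts = self.table["disposition"].value_counts()
        self.n_total = len(self.table)
        self.n_matched = int(counts.get(MATCHED, 0))
        self.n_missing_backfilled = int(counts.get(BACKFILL, 0))
        self.n_excluded_ambiguous = int(counts.get(AMBIGUOUS, 0))
        self.n_excluded_multiallelic = int(counts.get(MULTIALLELIC, 0))
        self.n_excluded_duplicated = int(counts.get(DUPLICATED, 0))
        self.n_excluded_nonautosomal = int(counts.get(NONAUTOSOMAL, 0))

    @property
    def match_rate(self) -> float:
        return self.n_matched / self.n_total if self.n_total else 0.0


@dataclass
class PRSVector:
    """Raw and Z-standardized polygenic scores for a sample set."""

    score_id: str
    sample_ids: list
    raw: np.ndarray
    z: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score_id": self.score_id,
             "raw": self.raw, "z": self.z}
        )


def read_scoring_file(path: str, score_id: str | None = None) -> ScoringFile:
    """Parse a tab-separated scoring file.

    Metadata lines are prefixed ``#`` (``#pgs_id=...`` sets the score id);
    the first unprefixed line is the header.  Malformed data rows are
    reported with their 1-based line numbers.
    """
    meta = {}
    header = None
    records = []
    bad_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                bad_lines.append(lineno)
                continue
            records.append(fields)
    if header is None or not records:
        raise FormatError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if bad_lines:
        raise FormatError(f"{path}: malformed rows at lines {bad_lines}")
    df = pd.DataFrame(records, columns=header)[REQUIRED_COLUMNS]
    try:
        df["chr_position"] = df["chr_position"].astype(int)
        df["effect_weight"] = df["effect_weight"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric position or weight ({exc})") from exc
    df["chr_name"] = df["chr_name"].astype(str)
    if score_id is None:
        score_id = meta.get("pgs_id") or path.rsplit("/", 1)[-1].split(".")[0]
    return ScoringFile(score_id=score_id, variants=df.reset_index(drop=True))


def write_scoring_file(sf: ScoringFile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#pgs_id={sf.score_id}\n")
        fh.write("\t".join(REQUIRED_COLUMNS) + "\n")
        for row in sf.variants.itertuples(index=False):
            fh.write(f"{row.chr_name}\t{row.chr_position}\t{row.effect_allele}\t"
                     f"{row.other_allele}\t{row.effect_weight!r}\n")


def _is_autosomal(chrom: str) -> bool:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c in AUTOSOMES


def harmonize(scoring: ScoringFile, genotypes: GenotypeMatrix) -> HarmonizationReport:
    """Assign a disposition to every scoring-file variant.

    A variant is *matched* when its (chrom, pos) is genotyped and its
    unordered allele pair equals the genotyped {ref, alt}; when the effect
    allele is the genotype ref allele the flip flag is set and the dosage
    contribution becomes ``2 - d``.  Exclusions (never scored): strand
    ambiguous pairs A/T and C/G, genotype positions carrying more than one
    variant record, scoring positions occurring more than once in the file,
    and non-autosomal variants.  Remaining variants are marked for
    allele-frequency backfill.  All problems become dispositions; this
    function does not raise on content.
    """
    if scoring.n_variants == 0 or genotypes.n_variants == 0:
        raise HarmonizationError("harmonize requires nonempty scoring and genotype sets")

    geno = genotypes.variants.copy()
    geno["chrom"] = geno["chrom"].astype(str)
    geno["pos"] = geno["pos"].astype(int)
    pos_counts = geno.groupby(["chrom", "pos"], sort=False).size()
    geno_index = {}
    for j, row in enumerate(geno.itertuples(index=False)):
        geno_index.setdefault((str(row.chrom), int(row.pos)), j)

    sc = scoring.variants
    dup_mask = sc.duplicated(subset=["chr_name", "chr_position"], keep=False)

    dispositions = []
    flips = []
    gidx = []
    eff_is_alt = []
    for i, row in enumerate(sc.itertuples(index=False)):
        key = (str(row.chr_name), int(row.chr_position))
        pair = {row.effect_allele, row.other_allele}
        flip = False
        j = -1
        e_alt = True
        if not _is_autosomal(row.chr_name):
            disp = NONAUTOSOMAL
        elif dup_mask.iloc[i]:
            disp = DUPLICATED
        elif pair in AMBIGUOUS_PAIRS:
            disp = AMBIGUOUS
        elif key in geno_index and pos_counts.get(key, 0) > 1:
            disp = MULTIALLELIC
        elif key in geno_index:
            j = geno_index[key]
            ref, alt = geno.iloc[j]["ref"], geno.iloc[j]["alt"]
            if pair == {ref, alt}:
                disp = MATCHED
                flip = row.effect_allele == ref
                e_alt = not flip
            else:
                disp = BACKFILL  # position present, alleles incompatible
                j = -1
        else:
            disp = BACKFILL
        dispositions.append(disp)
        flips.append(flip)
        gidx.append(j)
        eff_is_alt.append(e_alt)

    table = sc.copy()
    table["disposition"] = dispositions
    table["flip"] = flips
    table["geno_index"] = gidx
    table["effect_is_alt"] = eff_is_alt
    return HarmonizationReport(score_id=scoring.score_id, table=table)


def check_match_rate(report: HarmonizationReport, threshold: float = 0.75) -> bool:
    """Gate a score on its variant match rate; passes only if strictly above
    the threshold."""
    return report.match_rate > threshold


def compute_raw_score(
    scoring: ScoringFile,
    genotypes: GenotypeMatrix,
    report: HarmonizationReport,
    reference_af: dict | None = None,
) -> PRSVector:
    """Weighted sum of flip-resolved effect-allele dosages.

    Backfilled variants, and sample-level missing dosages at matched
    variants, contribute ``w * 2 * af`` where af is the effect-allele
    reference frequency: the genotype metadata AF for matched variants,
    ``reference_af[(chrom, pos, effect_allele)]`` for backfilled ones.
    """
    n = genotypes.n_samples
    raw = np.zeros(n)
    af_col = genotypes.variants["af"].to_numpy(dtype=float)
    for row in report.table.itertuples(index=False):
        w = row.effect_weight
        if row.disposition == MATCHED:
            d = genotypes.dosages[:, row.geno_index]
            if row.flip:
                d = 2.0 - d
            miss = np.isnan(d)
            if miss.any():
                af_alt = af_col[row.geno_index]
                if np.isnan(af_alt):
                    raise ScoringError(
                        f"{report.score_id}: missing dosages at "
                        f"{row.chr_name}:{row.chr_position} with no reference AF"
                    )
                af_eff = 1.0 - af_alt if row.flip else af_alt
                d = np.where(miss, 2.0 * af_eff, d)
            raw += w * d
        elif row.disposition == BACKFILL:
            key = (str(row.chr_name), int(row.chr_position), row.effect_allele)
            af = (reference_af or {}).get(key)
            if af is None:
                raise ScoringError(
                    f"{report.score_id}: no reference allele frequency for "
                    f"backfilled variant {row.chr_name}:{row.chr_position} "
                    f"{row.effect_allele}"
                )
            raw += w * 2.0 * af
        # excluded dispositions contribute nothing
    return PRSVector(score_id=report.score_id, sample_ids=list(genotypes.sample_ids), raw=raw)


def standardize_scores(prs: PRSVector) -> PRSVector:
    """Z-score the raw values ((x - mean)/sd, sd with n-1 denominator)."""
    raw = np.asarray(prs.raw, dtype=float)
    if raw.size < 2:
        raise ScoringError(f"{prs.score_id}: need at least 2 samples to standardize")
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ScoringError(f"{prs.score_id}: degenerate score (zero variance)")
    prs.z = (raw - raw.mean()) / sd
    return prs


def score_pipeline(
    scoring: ScoringFile,
    genotypes: GenotypeMatrix,
    reference_af: dict | None = None,
    min_match_rate: float = 0.75,
) -> tuple[HarmonizationReport, PRSVector | None]:
    """Harmonize, gate on match rate, and score in one call.

    Returns the report and the standardized score, or ``None`` for the
    score when the match-rate gate fails.
    """
    report = harmonize(scoring, genotypes)
    if not check_match_rate(report, min_match_rate):
        return report, None
    prs = compute_raw_score(scoring, genotypes, report, reference_af)
    return report, standardize_scores(prs)
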
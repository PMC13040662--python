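"""Scoring-file parsing, harmonization dispositions, and PRS arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import prsmed as pm
from prsmed.errors import FormatError, ScoringError
from prsmed.scoring import (
    AMBIGUOUS, BACKFILL, DUPLICATED, MATCHED, MULTIALLELIC, NONAUTOSOMAL,
)
from conftest import make_scoring


# --- scoring-file IO -------------------------------------------------------

def test_read_scoring_file_parses_rows(tmp_path):
    p = tmp_path / "score.txt"
    p.write_text(
        "#pgs_id=PGS_TEST\n"
        "chr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
        "1\t100\tA\tG\t0.1\n"
        "2\t200\tC\tT\t-0.2\n"
        "3\t300\tG\tA\t0.05\n"
    )
    sf = pm.read_scoring_file(str(p))
    assert sf.score_id == "PGS_TEST"
    assert sf.n_variants == 3
    assert sf.variants["effect_weight"].tolist() == [0.1, -0.2, 0.05]


def test_read_scoring_file_all_comments_is_format_error(tmp_path):
    p = tmp_path / "empty.txt"
    p.write_text("#pgs_id=X\n#note=only metadata\n")
    with pytest.raises(FormatError):
        pm.read_scoring_file(str(p))


def test_read_scoring_file_missing_column_is_format_error(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("chr_name\tchr_position\teffect_allele\teffect_weight\n"
                 "1\t100\tA\t0.1\n")
    with pytest.raises(FormatError):
        pm.read_scoring_file(str(p))


def test_read_scoring_file_nonnumeric_weight_is_format_error(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("chr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
                 "1\t100\tA\tG\tnot_a_number\n")
    with pytest.raises(FormatError):
        pm.read_scoring_file(str(p))


def test_scoring_file_roundtrip_full_precision(tmp_path):
    params = pm.SimulationParams(n_samples=5, n_variants=30, seed=13)
    g = pm.simulate_genotypes(params)
    sf = pm.simulate_scoring_file(g, params)
    p = tmp_path / "rt.txt"
    pm.write_scoring_file(sf, str(p))
    back = pm.read_scoring_file(str(p))
    assert back.score_id == sf.score_id
    pd.testing.assert_frame_equal(back.variants, sf.variants)
    # byte-identical on rewrite
    p2 = tmp_path / "rt2.txt"
    pm.write_scoring_file(back, str(p2))
    assert p.read_bytes() == p2.read_bytes()


# --- harmonization ---------------------------------------------------------

def test_harmonize_dispositions_partition_fixture(toy_genotypes):
    """4 scoring variants: 3 matched (one flipped), 1 backfilled; counts
    partition the file."""
    sf = make_scoring([
        ("1", 100, "G", "A", 0.5),    # matched, effect=alt
        ("1", 200, "C", "T", -0.1),   # matched, effect=ref -> flip
        ("2", 400, "C", "T", 0.4),    # matched
        ("3", 999, "A", "G", 0.2),    # not genotyped -> backfill
    ])
    rep = pm.harmonize(sf, toy_genotypes)
    assert rep.n_total == 4
    assert rep.n_matched == 3
    assert rep.n_missing_backfilled == 1
    assert (rep.n_matched + rep.n_missing_backfilled + rep.n_excluded_ambiguous
            + rep.n_excluded_multiallelic + rep.n_excluded_duplicated
            + rep.n_excluded_nonautosomal) == rep.n_total
    flips = rep.table.set_index("chr_position")["flip"]
    assert not flips[100] and flips[200] and not flips[400]
    assert rep.match_rate == 0.75


def test_harmonize_strand_ambiguous_never_matched(toy_genotypes):
    sf = make_scoring([("1", 100, "A", "T", 0.3), ("1", 200, "G", "C", 0.3)])
    rep = pm.harmonize(sf, toy_genotypes)
    assert (rep.table["disposition"] == AMBIGUOUS).all()


def test_harmonize_duplicated_and_nonautosomal(toy_genotypes):
    sf = make_scoring([
        ("1", 100, "G", "A", 0.1),
        ("1", 100, "G", "A", 0.1),   # duplicate position -> both excluded
        ("X", 500, "A", "G", 0.2),   # non-autosomal
    ])
    rep = pm.harmonize(sf, toy_genotypes)
    d = rep.table["disposition"].tolist()
    assert d == [DUPLICATED, DUPLICATED, NONAUTOSOMAL]


def test_harmonize_multiallelic_site_excluded():
    variants = pd.DataFrame({
        "chrom": ["1", "1"], "pos": [100, 100],
        "ref": ["A", "A"], "alt": ["G", "C"], "af": [0.3, 0.1],
    })
    g = pm.GenotypeMatrix(sample_ids=["s1"], variants=variants,
                          dosages=np.array([[1.0, 0.0]]))
    sf = make_scoring([("1", 100, "G", "A", 0.5)])
    rep = pm.harmonize(sf, g)
    assert rep.table["disposition"].iloc[0] == MULTIALLELIC


def test_allele_mismatch_at_known_position_backfills(toy_genotypes):
    sf = make_scoring([("1", 100, "C", "T", 0.5)])  # position exists, alleles differ
    rep = pm.harmonize(sf, toy_genotypes)
    assert rep.table["disposition"].iloc[0] == BACKFILL


@pytest.mark.parametrize("rate,expected", [(0.74, False), (0.75, False), (1.0, True)])
def test_match_rate_gate_is_strict(toy_genotypes, rate, expected):
    """The gate uses strictly-greater-than: a 75% match rate fails."""
    n_total = 100
    n_matched = int(round(rate * n_total))
    table = pd.DataFrame({
        "chr_name": "1", "chr_position": np.arange(1, n_total + 1),
        "effect_allele": "A", "other_allele": "G", "effect_weight": 0.0,
        "disposition": [MATCHED] * n_matched + [BACKFILL] * (n_total - n_matched),
        "flip": False, "geno_index": -1, "effect_is_alt": True,
    })
    rep = pm.HarmonizationReport(score_id="X", table=table)
    assert pm.check_match_rate(rep, 0.75) is expected


# --- score computation -----------------------------------------------------

def test_raw_score_hand_arithmetic(toy_genotypes):
    """One variant, w=0.5, effect=alt, d=2 -> 1.0; flipped -> 0.0."""
    sf = make_scoring([("1", 300, "A", "G", 0.5)])  # effect = alt allele A
    rep = pm.harmonize(sf, toy_genotypes)
    prs = pm.compute_raw_score(sf, toy_genotypes, rep)
    # dosages at variant 3: [2, 0, 1]
    assert prs.raw.tolist() == [1.0, 0.0, 0.5]
    sf_flip = make_scoring([("1", 300, "G", "A", 0.5)])  # effect = ref allele
    rep = pm.harmonize(sf_flip, toy_genotypes)
    prs = pm.compute_raw_score(sf_flip, toy_genotypes, rep)
    assert prs.raw.tolist() == [0.0, 1.0, 0.5]


def test_raw_score_with_missing_dosage_and_backfill():
    """3-variant toy: w=(0.2,-0.1,0.4), d=(1,2,missing), af(missing)=0.25
    -> 0.2 - 0.2 + 0.4*0.5 = 0.2.  Verified by hand dot product."""
    variants = pd.DataFrame({
        "chrom": ["1", "1", "1"], "pos": [10, 20, 30],
        "ref": ["A", "A", "A"], "alt": ["G", "G", "G"],
        "af": [0.5, 0.5, 0.25],
    })
    g = pm.GenotypeMatrix(sample_ids=["s1"], variants=variants,
                          dosages=np.array([[1.0, 2.0, np.nan]]))
    sf = make_scoring([
        ("1", 10, "G", "A", 0.2),
        ("1", 20, "G", "A", -0.1),
        ("1", 30, "G", "A", 0.4),
    ])
    rep = pm.harmonize(sf, g)
    prs = pm.compute_raw_score(sf, g, rep)
    assert prs.raw[0] == pytest.approx(0.2)


def test_all_zero_weights_give_zero_scores(toy_genotypes, toy_scoring):
    toy_scoring.variants["effect_weight"] = 0.0
    rep = pm.harmonize(toy_scoring, toy_genotypes)
    prs = pm.compute_raw_score(toy_scoring, toy_genotypes, rep)
    assert np.all(prs.raw == 0.0)


def test_backfill_without_reference_af_is_scoring_error(toy_genotypes):
    sf = make_scoring([("3", 999, "A", "G", 0.2)])
    rep = pm.harmonize(sf, toy_genotypes)
    with pytest.raises(ScoringError, match="3:999"):
        pm.compute_raw_score(sf, toy_genotypes, rep)
    prs = pm.compute_raw_score(sf, toy_genotypes, rep,
                               reference_af={("3", 999, "A"): 0.25})
    assert np.allclose(prs.raw, 0.2 * 2 * 0.25)


def test_score_invariant_under_ref_alt_swap(toy_genotypes, toy_scoring):
    """Swapping ref/alt with dosage complement 2-d leaves scores unchanged."""
    rep = pm.harmonize(toy_scoring, toy_genotypes)
    base = pm.compute_raw_score(toy_scoring, toy_genotypes, rep).raw
    swapped = pm.GenotypeMatrix(
        sample_ids=toy_genotypes.sample_ids,
        variants=toy_genotypes.variants.assign(
            ref=toy_genotypes.variants["alt"],
            alt=toy_genotypes.variants["ref"],
            af=1 - toy_genotypes.variants["af"],
        ),
        dosages=2.0 - toy_genotypes.dosages,
    )
    rep2 = pm.harmonize(toy_scoring, swapped)
    other = pm.compute_raw_score(toy_scoring, swapped, rep2).raw
    assert np.allclose(base, other)


def test_brute_force_oracle_matches_on_random_fixtures():
    """compute_raw_score equals an explicit per-sample loop, bit-exact."""
    for seed in range(5):
        params = pm.SimulationParams(n_samples=8, n_variants=10, seed=seed)
        g = pm.simulate_genotypes(params)
        sf = pm.simulate_scoring_file(g, params)
        rep = pm.harmonize(sf, g)
        got = pm.compute_raw_score(sf, g, rep).raw
        expected = np.zeros(g.n_samples)
        for i in range(g.n_samples):
            acc = 0.0
            for r in sf.variants.itertuples(index=False):
                gj = g.variants[(g.variants["chrom"] == r.chr_name)
                                & (g.variants["pos"] == r.chr_position)]
                j = gj.index[0]
                d = g.dosages[i, j]
                if r.effect_allele == gj["ref"].iloc[0]:
                    d = 2 - d
                acc += r.effect_weight * d
            expected[i] = acc
        assert np.array_equal(got, expected)


# --- standardization -------------------------------------------------------

def test_standardize_symmetric_triple():
    prs = pm.PRSVector(score_id="X", sample_ids=list("abc"),
                       raw=np.array([1.0, 2.0, 3.0]))
    z = pm.standardize_scores(prs).z
    assert np.allclose(z, [-1.0, 0.0, 1.0])


def test_standardize_constant_raw_is_error():
    prs = pm.PRSVector(score_id="X", sample_ids=list("ab"),
                       raw=np.array([1.0, 1.0]))
    with pytest.raises(ScoringError):
        pm.standardize_scores(prs)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=3, max_size=40).filter(
    lambda v: max(v) - min(v) > 1e-6))
def test_standardized_scores_have_mean0_sd1(values):
    prs = pm.PRSVector(score_id="X", sample_ids=list(range(len(values))),
                       raw=np.array(values))
    z = pm.standardize_scores(prs).z
    assert abs(z.mean()) < 1e-9
    assert z.std(ddof=1) == pytest.approx(1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(-5, 5).filter(lambda k: abs(k) > 1e-3))
def test_standardization_affine_invariance(k):
    """Scaling every weight by k scales Z by sign(k) only."""
    params = pm.SimulationParams(n_samples=12, n_variants=6, seed=21)
    g = pm.simulate_genotypes(params)
    sf = pm.simulate_scoring_file(g, params)
    rep = pm.harmonize(sf, g)
    z0 = pm.standardize_scores(pm.compute_raw_score(sf, g, rep)).z
    scaled = make_scoring(
        sf.variants.assign(
            effect_weight=sf.variants["effect_weight"] * k
        ).values.tolist())
    repk = pm.harmonize(scaled, g)
    zk = pm.standardize_scores(pm.compute_raw_score(scaled, g, repk)).z
    assert np.allclose(zk, np.sign(k) * z0)
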
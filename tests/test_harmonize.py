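"""Variant merge/filter behavior: allele normalization against a
brute-force oracle, threshold boundaries, filter algebra, and callset
concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bap1sig import ConfigError
from bap1sig import harmonize as hz


# ---------------------------------------------------------------- normalization

def oracle_canonical(pos, ref, alt):
    """Independent minimal representation: enumerate every prefix/suffix
    trim that keeps the alleles consistent and return the shortest
    (breaking ties toward the largest position, i.e. maximal prefix trim)."""
    r = "" if ref == "-" else ref
    a = "" if alt == "-" else alt
    candidates = []
    for npre in range(min(len(r), len(a)) + 1):
        if r[:npre] != a[:npre]:
            continue
        r1, a1 = r[npre:], a[npre:]
        for nsuf in range(min(len(r1), len(a1)) + 1):
            if nsuf and (r1[-nsuf:] != a1[-nsuf:]):
                continue
            r2 = r1[:len(r1) - nsuf] if nsuf else r1
            a2 = a1[:len(a1) - nsuf] if nsuf else a1
            candidates.append((len(r2) + len(a2), -(pos + npre),
                               pos + npre, r2 or "-", a2 or "-"))
    _, _, p, rr, aa = min(candidates)
    return p, rr, aa


ALLELE = st.text(alphabet="ACGT", min_size=0, max_size=6)


@settings(max_examples=300, derandomize=True)
@given(pos=st.integers(1, 1000), ref=ALLELE, alt=ALLELE)
def test_normalize_matches_trim_oracle(pos, ref, alt):
    if ref == alt:  # not a variant
        return
    got = hz.normalize_allele(pos, ref or "-", alt or "-")
    assert got == oracle_canonical(pos, ref or "-", alt or "-")
    # idempotence
    assert hz.normalize_allele(*got) == got


@pytest.mark.parametrize("anchor", list("ACGT"))
def test_padded_and_minimal_deletion_collapse(anchor):
    """VCF-padded (anchor base, pos-1) and minimal MAF representations of
    one deletion normalize to the same key."""
    minimal = hz.normalize_allele(100, "TTA", "-")
    padded = hz.normalize_allele(99, anchor + "TTA", anchor)
    assert minimal == padded == (100, "TTA", "-")
    ins_min = hz.normalize_allele(100, "-", "GGC")
    ins_pad = hz.normalize_allele(99, anchor, anchor + "GGC")
    assert ins_min == ins_pad == (100, "GGC", "-")[0:1] + ("-", "GGC")


def test_left_align_with_context():
    # deletion of "AG" in context ...AGAGAG... shifts to the leftmost copy
    ctx = "TTAGAGAGCC"  # positions 1..10
    pos, ref, alt = hz.normalize_allele(7, "AG", "-", context=ctx, context_start=1)
    assert (pos, ref, alt) == (3, "AG", "-")


def test_indel_length_boundaries():
    assert hz.indel_length("A", "T") == 0
    assert hz.indel_length("A" * 40, "-") == 39
    assert hz.indel_length("A" * 41, "-") == 40
    assert hz.indel_length("-", "G" * 12) == 11


# ---------------------------------------------------------------------- merging

def _call(sample="S1", pos=100, ref="A", alt="T", caller="A", depth=50, altc=25,
          classification="Missense_Mutation", flt="PASS"):
    return dict(sample_id=sample, tumor_type="TT1", chrom="chr3", pos=pos,
                ref=ref, alt=alt, classification=classification,
                t_depth=depth, t_alt_count=altc, filter=flt, caller=caller)


def test_merge_collapses_same_snv_from_two_callers():
    a = pd.DataFrame([_call(caller="A", depth=50)])
    b = pd.DataFrame([_call(caller="B", depth=70, altc=30)])
    merged = hz.merge_callsets([a, b])
    assert len(merged) == 1
    assert merged.loc[0, "callers"] == "A,B"
    assert merged.loc[0, "t_depth"] == 70  # highest-depth caller wins numerics
    assert merged.loc[0, "t_alt_count"] == 30


def test_merge_empty_input():
    assert len(hz.merge_callsets([])) == 0
    assert len(hz.merge_callsets([pd.DataFrame()])) == 0


def test_merge_idempotent_and_order_invariant():
    a = pd.DataFrame([_call(pos=100, caller="A"), _call(pos=200, caller="A")])
    b = pd.DataFrame([_call(pos=100, caller="B"), _call(pos=300, caller="B")])
    m1 = hz.merge_callsets([a, b])
    m2 = hz.merge_callsets([b, a])
    pd.testing.assert_frame_equal(m1, m2)
    again = hz.merge_callsets([m1])
    pd.testing.assert_frame_equal(
        again[["sample_id", "pos", "ref", "alt", "callers"]],
        m1[["sample_id", "pos", "ref", "alt", "callers"]])


def test_merge_conflicting_classification_keeps_most_deleterious(caplog):
    a = pd.DataFrame([_call(classification="Missense_Mutation", caller="A")])
    b = pd.DataFrame([_call(classification="Nonsense_Mutation", caller="B")])
    with caplog.at_level("WARNING"):
        merged = hz.merge_callsets([a, b])
    assert merged.loc[0, "classification"] == "Nonsense_Mutation"
    assert any("conflicting" in r.message for r in caplog.records)


def test_merge_collapses_padded_representation():
    a = pd.DataFrame([_call(pos=100, ref="TTA", alt="-", caller="A",
                            classification="Frame_Shift_Del")])
    b = pd.DataFrame([_call(pos=99, ref="GTTA", alt="G", caller="B",
                            classification="Frame_Shift_Del")])
    merged = hz.merge_callsets([a, b])
    assert len(merged) == 1
    assert merged.loc[0, "pos"] == 100 and merged.loc[0, "ref"] == "TTA"


# -------------------------------------------------------------------- filtering

def test_quality_filter_boundaries(toy_variants):
    kept, drops = hz.apply_quality_filters(toy_variants)
    ids = set(kept["sample_id"])
    assert "S1" not in ids and "S2" in ids        # VAF 0.19 out, 0.20 in
    assert "S4" not in ids and "S5" in ids        # t_alt_count 1 out, 2 in
    assert "S6" not in ids                        # Intron
    assert "S7" not in ids                        # non-PASS
    assert {"S3", "S8", "S9"} <= ids
    assert drops["vaf"] >= 1 and drops["alt_count"] >= 1


def test_quality_filter_invalid_threshold(toy_variants):
    with pytest.raises(ConfigError):
        hz.apply_quality_filters(toy_variants, vaf_min=1.2)


def test_filters_commute_and_are_monotone(toy_variants):
    """Applying the sub-filters in any order yields the same retained set,
    and tightening a threshold never adds records."""
    base, _ = hz.apply_quality_filters(toy_variants)
    # commute: quality filter composed of one-at-a-time passes
    step = toy_variants
    for kwargs in (dict(vaf_min=0.2, alt_min=0, require_pass=False, drop_classes=frozenset()),
                   dict(vaf_min=0.0, alt_min=2, require_pass=False, drop_classes=frozenset()),
                   dict(vaf_min=0.0, alt_min=0, require_pass=True, drop_classes=frozenset()),
                   dict(vaf_min=0.0, alt_min=0, require_pass=False)):
        step, _ = hz.apply_quality_filters(step, **kwargs)
    assert set(step["sample_id"]) == set(base["sample_id"])
    tight, _ = hz.apply_quality_filters(toy_variants, vaf_min=0.4)
    assert set(tight["sample_id"]) <= set(base["sample_id"])


@settings(max_examples=60, derandomize=True)
@given(vaf_lo=st.floats(0.05, 0.45), delta=st.floats(0.01, 0.4))
def test_tightening_vaf_threshold_is_monotone(vaf_lo, delta):
    rng = np.random.default_rng(7)
    depths = rng.integers(10, 120, size=30)
    table = pd.DataFrame([_call(sample=f"S{i}", pos=100 + i, depth=int(d),
                                altc=int(rng.integers(0, d + 1)))
                          for i, d in enumerate(depths)])
    table = table.rename(columns={"caller": "callers"})
    loose, _ = hz.apply_quality_filters(table, vaf_min=vaf_lo)
    tight, _ = hz.apply_quality_filters(table, vaf_min=min(vaf_lo + delta, 1.0))
    assert set(tight["sample_id"]) <= set(loose["sample_id"])


def test_expression_filter_rank_extremes():
    rng = np.random.default_rng(0)
    samples = [f"S{i}" for i in range(100)]
    expr = pd.DataFrame({s: [10.0 + rng.normal(0, 0.01)] for s in samples},
                        index=["BAP1"])
    expr.loc["BAP1", "S0"] = 1.0     # rank 1 / 100
    expr.loc["BAP1", "S1"] = 20.0    # rank 100 / 100
    types = pd.Series("TT1", index=samples)
    variants = pd.DataFrame([
        dict(sample_id="S0", tumor_type="TT1", chrom="chr3", pos=1, ref="A",
             alt="T", classification="Missense_Mutation", t_depth=50,
             t_alt_count=25, filter="PASS", callers="A"),
        dict(sample_id="S1", tumor_type="TT1", chrom="chr3", pos=2, ref="A",
             alt="T", classification="Missense_Mutation", t_depth=50,
             t_alt_count=25, filter="PASS", callers="A"),
    ])
    kept, review = hz.apply_expression_filter(variants, expr, types)
    assert set(kept["sample_id"]) == {"S0"}
    rv = review.set_index("sample_id")
    assert rv.loc["S0", "rank"] == 1 and rv.loc["S1", "rank"] == 100


def test_expression_filter_skipped_for_tiny_types(caplog):
    expr = pd.DataFrame({"S0": [5.0], "S1": [9.0]}, index=["BAP1"])
    types = pd.Series("TT1", index=["S0", "S1"])
    variants = pd.DataFrame([dict(sample_id="S1", tumor_type="TT1", chrom="chr3",
                                  pos=1, ref="A", alt="T",
                                  classification="Missense_Mutation", t_depth=50,
                                  t_alt_count=25, filter="PASS", callers="A")])
    with caplog.at_level("WARNING"):
        kept, _ = hz.apply_expression_filter(variants, expr, types)
    assert len(kept) == 1  # filter skipped, record retained
    assert any("skipped" in r.message for r in caplog.records)


# ------------------------------------------------------------------- summaries

def test_summarize_empty():
    summ = hz.summarize_variants(pd.DataFrame(columns=["sample_id", "tumor_type",
                                                       "ref", "alt",
                                                       "classification"]))
    assert summ["n_variants"] == 0 and summ["n_long_indels"] == 0


def test_summarize_deleterious_fraction_and_long_indels():
    classes = (["Nonsense_Mutation"] * 3 + ["Frame_Shift_Del"] * 3
               + ["Missense_Mutation"] * 4)
    rows = [_call(sample=f"S{i}", pos=100 + i, classification=c)
            for i, c in enumerate(classes)]
    ten = pd.DataFrame(rows).rename(columns={"caller": "callers"})
    ten.loc[0, ["ref", "alt"]] = ["A" * 41, "-"]   # indel length 40
    ten.loc[1, ["ref", "alt"]] = ["A" * 40, "-"]   # indel length 39
    summ = hz.summarize_variants(ten)
    assert summ["n_variants"] == 10
    assert summ["deleterious_fraction"] == pytest.approx(0.6)
    assert summ["n_long_indels"] == 1     # length 40 counts, 39 does not


# ----------------------------------------------------------------- concordance

def _keyed(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])


def test_concordance_identical_and_disjoint():
    a = _keyed([("S1", "chr3", 100, "A", "T"), ("S2", "chr3", 200, "C", "G")])
    rep = hz.compare_callsets(a, a.copy())
    assert (rep.n_new_only, rep.n_concordant, rep.n_legacy_only) == (0, 2, 0)
    b = _keyed([("S9", "chr3", 900, "A", "T"), ("S8", "chr3", 800, "C", "G")])
    three = _keyed([("S1", "chr3", 1, "A", "T"), ("S2", "chr3", 2, "A", "T"),
                    ("S3", "chr3", 3, "A", "T")])
    rep = hz.compare_callsets(three, b)
    assert (rep.n_new_only, rep.n_concordant, rep.n_legacy_only) == (3, 0, 2)
    # the three classes partition the union
    assert len(rep.assignment) == 5


def test_concordance_near_miss_window():
    new = _keyed([("S1", "chr3", 100, "A", "T")])
    legacy = _keyed([("S1", "chr3", 105, "C", "G")])
    rep = hz.compare_callsets(new, legacy, window=10)
    assert rep.n_concordant == 0
    assert len(rep.near_miss) == 1
    assert rep.near_miss.loc[0, "distance"] == 5
    far = _keyed([("S1", "chr3", 150, "C", "G")])
    assert len(hz.compare_callsets(new, far, window=10).near_miss) == 0


def test_filter_chain_recall_on_clean_cohort(clean_sim):
    """With caller noise off, the quality + expression chain keeps exactly
    the truly mutant samples."""
    from bap1sig import diffexp

    truth, meta = clean_sim["truth"], clean_sim["meta"]
    merged = hz.merge_callsets(clean_sim["callsets"])
    filt, _ = hz.apply_quality_filters(merged)
    norm = diffexp.normalized_log2(clean_sim["counts"])
    kept, _ = hz.apply_expression_filter(filt, norm, meta["tumor_type"])
    assert set(kept["sample_id"]) == set(truth.mutant_samples)
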
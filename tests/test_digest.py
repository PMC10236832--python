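"""Per-sample digestion: filter cascade, wild-type matching, merging,
constant-region error tallies and count-table accumulation."""

import numpy as np
import pandas as pd
import pytest

from mavekit import (
    DigestParams,
    DigestResult,
    MergeOptions,
    check_constant,
    contains_adapter,
    digest_sample,
    estimate_error_rates,
    match_to_wildtype,
    merge_pair,
    name_variant,
    parse_element_spec,
)
from mavekit.digest import (
    ErrorTally,
    F_FORBIDDEN_CODON,
    F_MUT_QUAL,
    F_NO_WILDTYPE,
    F_TOO_MANY_MUT,
    MatchResult,
    phred_from_string,
    reverse_complement,
)
from mavekit.layout import ComponentSet
from mavekit.digest import quality_filters

from conftest import WT_FOS, random_dna

Q30 = np.full(200, 30)


def write_fastq(path, records):
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path


# --------------------------------------------------------------- adapters


def test_adapter_exact_containment_detected():
    ad = "CTGTCTCTTATACACATCT"
    assert contains_adapter("AAA" + ad + "GGG", None, ad, None)


def test_no_adapters_configured_never_matches():
    assert not contains_adapter("ACGTACGT", "ACGTACGT", None, None)


def test_partial_terminal_adapter_overlap_not_detected():
    ad = "CTGTCTCTTATACACATCT"
    read = "G" * 50 + ad[:5]  # only 5 of 19 bases at the read end
    assert not contains_adapter(read, None, ad, None)


# ---------------------------------------------------------------- merging


def merge_oracle(fwd, fq, rev, rq, opts):
    """Independent overlap scan with explicit loops."""
    hi = min(len(fwd), len(rev))
    if opts.max_overlap is not None:
        hi = min(hi, opts.max_overlap)
    for w in range(hi, opts.min_overlap - 1, -1):
        ml = len(fwd) + len(rev) - w
        if opts.min_merged_length is not None and ml < opts.min_merged_length:
            continue
        if opts.max_merged_length is not None and ml > opts.max_merged_length:
            continue
        a, b = fwd[len(fwd) - w:], rev[:w]
        mism = sum(x != y for x, y in zip(a, b))
        if mism / w > opts.max_mismatch_fraction:
            continue
        seq, qual = list(fwd[: len(fwd) - w]), list(fq[: len(fwd) - w])
        for i in range(w):
            qa, qb = fq[len(fwd) - w + i], rq[i]
            if a[i] == b[i]:
                seq.append(a[i]); qual.append(max(qa, qb))
            elif qb > qa:
                seq.append(b[i]); qual.append(qb)
            else:
                seq.append(a[i]); qual.append(qa)
        seq += list(rev[w:]); qual += list(rq[w:])
        return "".join(seq), qual
    return "mergeFailed"


def test_merge_prefers_longest_valid_overlap():
    out = merge_pair(
        "ACGTACGT", Q30[:8], "TACGTTTT", Q30[:8],
        MergeOptions(min_overlap=4, max_overlap=5),
    )
    assert out[0] == "ACGTACGTTTT"


def test_full_overlap_identity():
    out = merge_pair("ACGTACGA", Q30[:8], "ACGTACGA", Q30[:8],
                     MergeOptions(min_overlap=8, max_overlap=8))
    assert out[0] == "ACGTACGA"


def test_disjoint_sequences_fail_to_merge():
    out = merge_pair("AAAAAAAA", Q30[:8], "TTTTTTTT", Q30[:8],
                     MergeOptions(max_mismatch_fraction=0.0,
                                  min_merged_length=9))
    assert out == "mergeFailed"


def test_discordant_overlap_resolved_by_higher_quality():
    fq = np.array([30, 30, 30, 10])
    rq = np.array([40, 30, 30, 30])
    out = merge_pair("AAAT", fq, "CAAA", rq,
                     MergeOptions(min_overlap=4, max_mismatch_fraction=0.5))
    seq, qual = out
    assert seq == "CAAA" [0:1] + "AA" + "A"  # rev base wins at pos 0 and 3
    assert list(qual) == [40, 30, 30, 30]


@pytest.mark.parametrize("trial", range(40))
def test_merge_matches_bruteforce_oracle(trial):
    rng = np.random.default_rng(500 + trial)
    nf, nr = int(rng.integers(4, 12)), int(rng.integers(4, 12))
    fwd, rev = random_dna(rng, nf), random_dna(rng, nr)
    fq = rng.integers(2, 41, nf)
    rq = rng.integers(2, 41, nr)
    opts = MergeOptions(
        min_overlap=int(rng.integers(1, 4)),
        max_overlap=int(rng.integers(4, 12)),
        max_mismatch_fraction=float(rng.choice([0.0, 0.2, 0.5])),
    )
    got = merge_pair(fwd, fq, rev, rq, opts)
    want = merge_oracle(fwd, list(fq), rev, list(rq), opts)
    if isinstance(want, str):
        assert got == want
    else:
        assert got[0] == want[0]
        assert list(got[1]) == want[1]


# ----------------------------------------------------- wild-type matching


def match_oracle(var, wts, unit, max_mut):
    """Exhaustive Hamming scan with tie and budget filtering."""
    cands = {n: s for n, s in wts.items() if len(s) == len(var)}
    if not cands:
        return F_NO_WILDTYPE
    dists = {n: sum(a != b for a, b in zip(var, s)) for n, s in cands.items()}
    dmin = min(dists.values())
    winners = [n for n, d in dists.items() if d == dmin]
    budget = max_mut if unit == "base" else (3 * max_mut if max_mut is not None else None)
    if budget is not None and dmin > budget:
        return F_NO_WILDTYPE
    if len(winners) > 1:
        return F_NO_WILDTYPE
    name = winners[0]
    if unit == "codon" and max_mut is not None:
        ncod = len({i // 3 for i in range(len(var)) if var[i] != cands[name][i]})
        if ncod > max_mut:
            return F_TOO_MANY_MUT
    return name, dmin


def test_exact_match_names_bare_wildtype():
    res = match_to_wildtype("ACGTAA", Q30[:6], {"GENEX": "ACGTAA"},
                            DigestParams())
    assert res.wt_name == "GENEX" and res.mutations == []
    assert name_variant(res, "base") == "GENEX"


def test_single_base_deviation_identifier():
    wt = "ACGTACGTACGT"
    var = wt[:9] + "A" + wt[10:]
    res = match_to_wildtype(var, Q30[:12], {"GENEX": wt}, DigestParams())
    assert res.mutations == [(10, wt[9], "A")]
    assert name_variant(res, "base") == "GENEX.10.A"


def test_equally_good_wildtypes_filter_the_read():
    wts = {"A": "AACC", "B": "AAGG"}
    out = match_to_wildtype("AACG", Q30[:4], wts, DigestParams())
    assert out == F_NO_WILDTYPE


def test_codon_unit_naming_with_separator():
    wt = "ATG" * 8
    var = "ATG" * 3 + "TTG" + "ATG" * 2 + "AAC" + "ATG"
    params = DigestParams(unit="codon", max_mutations=2)
    res = match_to_wildtype(var, Q30[:24], {"GENEX": wt}, params)
    assert name_variant(res, "codon") == "GENEX.4.TTG_GENEX.7.AAC"


def test_low_quality_mutation_filtered():
    wt = "ACGTACGT"
    var = "ACGAACGT"
    quals = np.full(8, 30); quals[3] = 10
    out = match_to_wildtype(var, quals, {"G": wt},
                            DigestParams(min_mutation_quality=20))
    assert out == F_MUT_QUAL


def test_forbidden_codon_iupac_pattern():
    wt = "ATGGCTAAA"
    var = "ATGGCAAAA"  # codon 2 GCT->GCA, ends in A: matches NNW
    out = match_to_wildtype(var, Q30[:9], {"G": wt},
                            DigestParams(unit="codon", forbidden_codons="NNW"))
    assert out == F_FORBIDDEN_CODON
    ok = match_to_wildtype(var, Q30[:9], {"G": wt},
                           DigestParams(unit="codon", forbidden_codons="NNS"))
    assert isinstance(ok, MatchResult)


@pytest.mark.parametrize("trial", range(50))
def test_matching_agrees_with_exhaustive_scan(trial):
    rng = np.random.default_rng(9000 + trial)
    L = int(rng.integers(6, 16)) * 3
    k = int(rng.integers(1, 5))
    wts = {f"W{i}": random_dna(rng, L) for i in range(k)}
    base = wts[f"W{rng.integers(0, k)}"]
    var = list(base)
    for _ in range(int(rng.integers(0, 5))):
        var[rng.integers(0, L)] = "ACGT"[rng.integers(0, 4)]
    var = "".join(var)
    unit = "base" if trial % 2 else "codon"
    max_mut = int(rng.integers(0, 4))
    got = match_to_wildtype(var, Q30[:L], wts,
                            DigestParams(unit=unit, max_mutations=max_mut))
    want = match_oracle(var, wts, unit, max_mut)
    if isinstance(want, str):
        assert got == want
    else:
        assert isinstance(got, MatchResult)
        assert (got.wt_name, got.n_mut_bases) == want


# ---------------------------------------------------------- constant check


def test_constant_identity_tallies_matches_at_observed_qualities():
    ok, match, mism = check_constant("ACGT", np.array([30, 30, 30, 30]),
                                     ["ACGT"], 1)
    assert ok and match[30] == 4 and mism.sum() == 0


def test_constant_mismatch_threshold():
    ok, *_ = check_constant("ACGA", np.full(4, 30), ["TCGT"], 1)
    assert not ok  # 2 mismatches > 1


def test_constant_positionwise_quality_tallies():
    ok, match, mism = check_constant(
        "ACGA", np.array([30, 30, 30, 20]), ["ACGT"], 2
    )
    assert ok
    assert mism[20] == 1 and match[30] == 3


def test_constant_reference_tie_fails():
    ok, *_ = check_constant("AAAT", np.full(4, 30), ["AAAA", "AATT"], 3)
    assert not ok


# ---------------------------------------------------------- quality filters


def comp(var, quals, umi=""):
    c = ComponentSet()
    c.variable, c.variable_qual, c.umi = var, np.asarray(quals), umi
    return c


def test_average_quality_uses_arithmetic_mean():
    p = DigestParams(avg_qual_min=21)
    assert quality_filters(comp("ACGT", [10, 10, 10, 50]), p) == "fAvgQualTooLow"
    assert quality_filters(comp("ACGT", [21, 21, 21, 21]), p) is None


def test_n_content_thresholds():
    p = DigestParams(max_n_variable=1, max_n_umi=1)
    assert quality_filters(comp("ACNN", [30] * 4), p) == "fTooManyNinVar"
    assert quality_filters(comp("ACGT", [30] * 4, "ACGNNT"), p) == "fTooManyNinUmi"


# ------------------------------------------------------------ digest runs


LAY_UV = parse_element_spec("UV", [6, 48])


def lib_records(rng, n, wt=WT_FOS, mutate=None):
    recs = []
    for i in range(n):
        seq = wt if mutate is None else mutate(i, wt)
        umi = random_dna(rng, 6)
        recs.append((f"r{i}", umi + seq, "?" * (6 + len(seq))))  # Q30
    return recs


def test_empty_fastq_yields_empty_result(tmp_path):
    path = tmp_path / "empty.fastq"
    path.write_text("")
    res = digest_sample(path, LAY_UV, DigestParams(wildtypes={"FOS": WT_FOS}))
    assert res.filter_tally.n_total == 0
    assert res.count_table == {}


def test_max_reads_caps_processing(tmp_path, rng):
    path = write_fastq(tmp_path / "a.fastq", lib_records(rng, 50))
    res = digest_sample(path, LAY_UV,
                        DigestParams(wildtypes={"FOS": WT_FOS}, max_n_reads=20))
    assert res.filter_tally.n_total == 20


def test_file_concatenation_equals_per_file_sum(tmp_path, rng):
    ra = lib_records(rng, 30)
    rb = lib_records(rng, 20)
    pa = write_fastq(tmp_path / "a.fastq", ra)
    pb = write_fastq(tmp_path / "b.fastq", rb)
    params = DigestParams(wildtypes={"FOS": WT_FOS})
    res_a = digest_sample(pa, LAY_UV, params)
    res_b = digest_sample(pb, LAY_UV, params)
    res_ab = digest_sample([pa, pb], LAY_UV, params)
    assert res_ab.filter_tally.n_total == 50
    for v, rec in res_ab.count_table.items():
        ca = res_a.count_table.get(v)
        cb = res_b.count_table.get(v)
        assert rec.read_count == (ca.read_count if ca else 0) + (
            cb.read_count if cb else 0
        )


def test_result_independent_of_read_order(tmp_path, rng):
    def mut(i, wt):
        if i % 3 == 0:
            return wt[:12] + "A" + wt[13:] if wt[12] != "A" else wt
        return wt

    recs = lib_records(rng, 60, mutate=mut)
    p1 = write_fastq(tmp_path / "fwd.fastq", recs)
    p2 = write_fastq(tmp_path / "shuf.fastq", list(reversed(recs)))
    params = DigestParams(wildtypes={"FOS": WT_FOS})
    r1 = digest_sample(p1, LAY_UV, params)
    r2 = digest_sample(p2, LAY_UV, params)
    assert r1.filter_tally.as_dict() == r2.filter_tally.as_dict()
    assert {v: (r.read_count, r.umi_count) for v, r in r1.count_table.items()} == {
        v: (r.read_count, r.umi_count) for v, r in r2.count_table.items()
    }


def test_excluded_reads_exported_with_reason(tmp_path, rng):
    ad = "CTGTCTCTTATACACATCT"
    recs = lib_records(rng, 10)
    bad = ("bad0", ad + "A" * (54 - len(ad)), "?" * 54)
    recs.insert(3, bad)
    path = write_fastq(tmp_path / "a.fastq", recs)
    out_prefix = str(tmp_path / "excluded")
    params = DigestParams(wildtypes={"FOS": WT_FOS}, adapter_fwd=ad,
                          excluded_path=out_prefix)
    res = digest_sample(path, LAY_UV, params)
    assert res.filter_tally.counts["fAdapter"] == 1
    lines = (tmp_path / "excluded.fastq").read_text().splitlines()
    assert len(lines) == 4 * res.filter_tally.n_filtered
    assert lines[0] == "@bad0 fAdapter"


def test_mismatched_pair_counts_raise(tmp_path, rng):
    p1 = write_fastq(tmp_path / "r1.fastq", lib_records(rng, 5))
    p2 = write_fastq(tmp_path / "r2.fastq", lib_records(rng, 4))
    lay2 = parse_element_spec("V", [-1])
    with pytest.raises(ValueError, match="unequal read counts"):
        digest_sample(p1, LAY_UV, DigestParams(), p2, lay2)


def test_sequence_mode_names_variants_by_sequence(tmp_path, rng):
    recs = lib_records(rng, 8)
    path = write_fastq(tmp_path / "a.fastq", recs)
    res = digest_sample(path, LAY_UV, DigestParams())
    assert set(res.count_table) == {WT_FOS}
    rec = res.count_table[WT_FOS]
    assert rec.read_count == 8 and rec.wildtype is None


def test_umi_count_bounded_by_read_count(tmp_path, rng):
    recs = lib_records(rng, 40)
    path = write_fastq(tmp_path / "a.fastq", recs)
    res = digest_sample(path, LAY_UV, DigestParams(wildtypes={"FOS": WT_FOS}))
    for rec in res.count_table.values():
        assert 1 <= rec.umi_count <= rec.read_count


def test_error_rate_table_from_tallies():
    tally = ErrorTally()
    tally.n_match[30] = 100
    tally.n_match[20] = 90
    tally.n_mismatch[20] = 10
    df = estimate_error_rates(tally).set_index("quality")
    assert df.loc[30, "rate"] == 0.0
    assert df.loc[20, "rate"] == pytest.approx(0.10)
    assert set(df.index) == {20, 30}


def test_digest_result_directory_round_trip(tmp_path, rng):
    recs = lib_records(rng, 25)
    path = write_fastq(tmp_path / "a.fastq", recs)
    res = digest_sample(
        path, LAY_UV, DigestParams(wildtypes={"FOS": WT_FOS}, unit="codon")
    )
    res.to_dir(tmp_path / "out")
    back = DigestResult.from_dir(tmp_path / "out")
    assert back.filter_tally.as_dict() == res.filter_tally.as_dict()
    assert set(back.count_table) == set(res.count_table)
    for v in res.count_table:
        a, b = res.count_table[v], back.count_table[v]
        assert (a.read_count, a.umi_count, a.n_mut_bases, a.sequence) == (
            b.read_count, b.umi_count, b.n_mut_bases, b.sequence
        )


def test_phred_and_revcomp_helpers():
    assert list(phred_from_string("!I")) == [0, 40]
    assert reverse_complement("ACGTN") == "NACGT"


def test_paired_merge_reconstructs_full_variable_region(tmp_path):
    """Overlapping read pairs merge into the full-length variable region
    (reverse mate reverse-complemented internally) and match the
    wild-type."""
    wt = WT_FOS  # 48 nt
    lay = parse_element_spec("V", [-1])
    fwd = wt[:30]
    rev = reverse_complement(wt[18:])  # 30 nt, overlap 12
    p1 = write_fastq(tmp_path / "r1.fastq", [("r0", fwd, "?" * 30)])
    p2 = write_fastq(tmp_path / "r2.fastq", [("r0", rev, "?" * 30)])
    params = DigestParams(
        wildtypes={"FOS": wt}, merge=True,
        merge_options=MergeOptions(min_overlap=10, max_overlap=20),
    )
    res = digest_sample(p1, lay, params, p2, lay)
    assert res.filter_tally.n_retained == 1
    assert set(res.count_table) == {"FOS"}
    assert res.count_table["FOS"].sequence == wt


def test_paired_merge_invalid_overlap_filtered(tmp_path):
    lay = parse_element_spec("V", [-1])
    p1 = write_fastq(tmp_path / "r1.fastq", [("r0", "A" * 20, "?" * 20)])
    p2 = write_fastq(tmp_path / "r2.fastq", [("r0", "C" * 20, "?" * 20)])
    params = DigestParams(
        merge=True,
        merge_options=MergeOptions(min_overlap=5, max_mismatch_fraction=0.0,
                                   min_merged_length=25),
    )
    res = digest_sample(p1, lay, params, p2, lay)
    assert res.filter_tally.counts["fMergeFailed"] == 1
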
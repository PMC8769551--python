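"""Alignment engine: offset search, scoring, ranking, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abseek.io import RepertoireRecord
from abseek.search import (
    SearchParams,
    StructuralQuery,
    align_segment,
    classify_light_chain,
    load_query,
    rank_hits,
    search_database,
    search_germline,
    search_record,
    write_query,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# -- independent oracle -------------------------------------------------------


def oracle_best_score(tree, codes, subject, max_shift):
    """Naive double-loop maximization over all registers, via raw member sets."""
    best = None
    for offset in range(-max_shift, max_shift + 1):
        score = 0.0
        for i, code in enumerate(codes):
            j = i + offset
            if 0 <= j < len(subject):
                members = tree.nodes[code].members
                if subject[j] in members:
                    score += 1.0 / len(members)
        if best is None or score > best:
            best = score
    return best


def _all_codes(tree):
    return sorted(tree.nodes)


# -- align_segment ------------------------------------------------------------


def test_exact_leaf_query_all_match(tree):
    subject = "ACDWY"
    aln = align_segment(tree, tuple(subject), subject, max_shift=0)
    assert aln.match_string == "+" * 5
    assert aln.score == pytest.approx(5.0)
    assert aln.offset == 0 and aln.overhang == 0


def test_mismatch_scores_zero(tree):
    # middle code excludes the subject residue
    aln = align_segment(tree, ("A", "SML", "D"), "AWD", max_shift=0)
    assert aln.match_string == "+-+"
    assert aln.n_mismatch == 1
    assert aln.score == pytest.approx(1.0 + 0.0 + 1.0)


def test_root_query_scores_one_twentieth_per_position(tree):
    codes = (tree.root_code,) * 8
    aln = align_segment(tree, codes, "ACDEFGHI", max_shift=0)
    assert aln.match_string == "+" * 8
    assert aln.score == pytest.approx(0.05 * 8)


def test_shift_recovers_register_after_leading_insertion(tree):
    planted = "WCDYKLMH"
    subject = "G" + planted  # one extra leading residue
    aln = align_segment(tree, tuple(planted), subject, max_shift=2)
    assert aln.offset == 1
    assert aln.score == pytest.approx(len(planted))
    assert aln.score == pytest.approx(
        oracle_best_score(tree, tuple(planted), subject, 2)
    )


def test_overhang_positions_excluded_from_match_string(tree):
    aln = align_segment(tree, tuple("ACDEF"), "ACD", max_shift=0)
    assert aln.match_string == "+++"
    assert aln.overhang == 2
    assert aln.n_match + aln.n_mismatch == len(aln.match_string)


def test_empty_codes_rejected(tree):
    with pytest.raises(ValueError):
        align_segment(tree, (), "ACD", max_shift=1)


def test_oracle_equivalence_random_cases(tree):
    """Engine max-score equals naive enumeration on 200 seeded random pairs."""
    rng = np.random.default_rng(42)
    codes_pool = _all_codes(tree)
    for _ in range(200):
        qlen = int(rng.integers(1, 15))
        slen = int(rng.integers(1, 20))
        codes = tuple(codes_pool[i] for i in rng.integers(len(codes_pool), size=qlen))
        subject = "".join((AA + "X")[i] for i in rng.integers(21, size=slen))
        max_shift = int(rng.integers(0, 4))
        aln = align_segment(tree, codes, subject, max_shift)
        assert aln.score == pytest.approx(
            oracle_best_score(tree, codes, subject, max_shift)
        )
        assert aln.n_match == aln.match_string.count("+")
        assert aln.n_mismatch == aln.match_string.count("-")
        assert abs(aln.offset) <= max_shift
        assert 0.0 <= aln.score <= 1.0 * aln.n_compared + 1e-12


@settings(max_examples=150, derandomize=True)
@given(
    codes=st.lists(
        st.sampled_from(sorted("ACDEFGHIKLMNPQRSTVWY") + ["ANY", "SML", "RNG", "LNG", "ARO"]),
        min_size=1,
        max_size=12,
    ),
    subject=st.text(alphabet=AA + "X", min_size=1, max_size=18),
    max_shift=st.integers(min_value=0, max_value=3),
)
def test_align_segment_property(tree, codes, subject, max_shift):
    aln = align_segment(tree, tuple(codes), subject, max_shift)
    assert aln.score == pytest.approx(
        oracle_best_score(tree, tuple(codes), subject, max_shift)
    )
    # per matched position the contribution lies in [0.05, 1.00]
    if aln.n_match:
        assert 0.05 * aln.n_match - 1e-12 <= aln.score <= 1.0 * aln.n_match + 1e-12


def test_monotonic_refinement(tree):
    """Descendant codes containing the residue never lower the score;
    non-containing replacements never raise it."""
    subject = "WKDSA"
    base = tuple(tree.root_code for _ in subject)
    base_score = align_segment(tree, base, subject, 0).score
    for i, residue in enumerate(subject):
        leaf = tree.leaves_for(residue)[0]
        refined = base[:i] + (leaf,) + base[i + 1 :]
        assert align_segment(tree, refined, subject, 0).score >= base_score
        non_containing = next(
            c for c in sorted(tree.nodes) if not tree.contains(c, residue)
        )
        worse = base[:i] + (non_containing,) + base[i + 1 :]
        assert align_segment(tree, worse, subject, 0).score <= base_score


# -- search_record / search_database -------------------------------------------


def _query_from(regions, chain_class="kappa"):
    return StructuralQuery(
        chain_class=chain_class,
        segments={r: tuple(seq) for r, seq in regions.items()},
    )


REGIONS_FIX = {
    "FW1": "QSVLTQPPS", "CDR1": "SGSSSNI", "FW2": "WYQQLPG",
    "CDR2": "DNN", "FW3": "RPSGVPDRF", "CDR3": "AAWDDSLNG",
}


def _record(rid, regions, **kw):
    return RepertoireRecord(record_id=rid, regions=regions, productive=True, **kw)


def test_search_record_perfect_match(tree):
    query = _query_from(REGIONS_FIX)
    hit = search_record(tree, query, _record("r1", REGIONS_FIX))
    total_len = sum(len(s) for s in REGIONS_FIX.values())
    assert hit.total_score == pytest.approx(total_len)
    assert hit.mismatch_total == 0
    assert hit.cdr_only_score == pytest.approx(
        sum(len(REGIONS_FIX[r]) for r in ("CDR1", "CDR2", "CDR3"))
    )
    assert hit.n_cdr_length_match == 3


def test_search_record_scrambled_cdr3_matches_positional_oracle(tree):
    regions = dict(REGIONS_FIX)
    regions["CDR3"] = "KKKKKKKKK"  # unrelated residues, same length
    query = _query_from(REGIONS_FIX)
    hit = search_record(tree, query, _record("r1", regions))
    # position-by-position recomputation of the CDR3 segment
    expected_cdr3 = oracle_best_score(
        tree, tuple(REGIONS_FIX["CDR3"]), regions["CDR3"], 2
    )
    assert hit.alignments["CDR3"].score == pytest.approx(expected_cdr3)
    assert hit.cdr_only_score == pytest.approx(
        len(REGIONS_FIX["CDR1"]) + len(REGIONS_FIX["CDR2"]) + expected_cdr3
    )


def test_search_record_missing_region_scores_zero(tree):
    regions = {r: s for r, s in REGIONS_FIX.items() if r != "CDR2"}
    query = _query_from(REGIONS_FIX)
    hit = search_record(tree, query, _record("r1", regions))
    aln = hit.alignments["CDR2"]
    assert aln.score == 0.0 and aln.match_string == ""
    assert aln.overhang == len(REGIONS_FIX["CDR2"])


def test_search_record_root_query_forces_floor_score(tree):
    query = StructuralQuery(
        chain_class="kappa",
        segments={r: (tree.root_code,) * len(s) for r, s in REGIONS_FIX.items()},
    )
    hit = search_record(tree, query, _record("r1", REGIONS_FIX))
    total_len = sum(len(s) for s in REGIONS_FIX.values())
    assert hit.total_score == pytest.approx(0.05 * total_len)


def test_mismatch_bookkeeping(tree):
    regions = dict(REGIONS_FIX)
    regions["FW2"] = "WYKKLPG"  # two substitutions
    regions["CDR1"] = "SGSWSNI"  # one substitution
    query = _query_from(REGIONS_FIX)
    hit = search_record(tree, query, _record("r1", regions))
    total_minus = sum(a.match_string.count("-") for a in hit.alignments.values())
    cdr_minus = sum(
        a.match_string.count("-")
        for r, a in hit.alignments.items()
        if r.startswith("CDR")
    )
    assert hit.mismatch_total == total_minus == 3
    assert hit.mismatch_cdr == cdr_minus == 1
    assert hit.total_score >= hit.cdr_only_score >= 0


def _mutated(rng, regions, rate=0.15):
    out = {}
    for r, seq in regions.items():
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < rate:
                chars[i] = AA[int(rng.integers(20))]
        out[r] = "".join(chars)
    return out


def test_search_database_planted_record_ranks_first(tree):
    rng = np.random.default_rng(5)
    records = [_record("planted", REGIONS_FIX)]
    records += [
        _record(f"decoy{i:03d}", _mutated(rng, REGIONS_FIX)) for i in range(99)
    ]
    query = _query_from(REGIONS_FIX)
    hits = search_database(tree, query, records)
    assert hits[0].record_id == "planted"
    assert hits[0].rank == 1
    # exhaustive rescoring: nothing scores above the planted record
    assert all(h.total_score <= hits[0].total_score for h in hits)
    assert [h.rank for h in hits] == list(range(1, len(hits) + 1))


def test_search_database_empty(tree, caplog):
    query = _query_from(REGIONS_FIX)
    with caplog.at_level("WARNING"):
        assert search_database(tree, query, []) == []


def test_search_database_run_log(tree):
    query = _query_from(REGIONS_FIX)
    log = {}
    search_database(tree, query, [_record("r1", REGIONS_FIX)], run_log=log)
    assert log["records_scanned"] == 1
    assert log["records_after_length_filter"] == 1
    assert log["max_shift"] == 2


def test_identical_records_tie_broken_by_id(tree):
    records = [_record("zzz", REGIONS_FIX), _record("aaa", REGIONS_FIX)]
    query = _query_from(REGIONS_FIX)
    hits = search_database(tree, query, records)
    assert [h.record_id for h in hits] == ["aaa", "zzz"]
    assert [h.rank for h in hits] == [1, 2]


def test_rank_hits_tiebreaks_and_determinism(tree):
    base = dict(REGIONS_FIX)
    fewer_cdr_mm = dict(base)
    fewer_cdr_mm["FW1"] = "KSVLTQPPS"  # FW mismatch only
    more_cdr_mm = dict(base)
    more_cdr_mm["CDR1"] = "KGSSSNI"  # CDR mismatch
    query = _query_from(REGIONS_FIX)
    h1 = search_record(tree, query, _record("fw_mm", fewer_cdr_mm))
    h2 = search_record(tree, query, _record("cdr_mm", more_cdr_mm))
    # equalize scores so only mismatch location separates them
    h1.total_score = h2.total_score = 100.0
    h1.cdr_only_score = h2.cdr_only_score = 20.0
    h1.mismatch_total = h2.mismatch_total = 1
    ordered = rank_hits([h2, h1])
    assert [h.record_id for h in ordered] == ["fw_mm", "cdr_mm"]

    single = rank_hits([h1])
    assert [h.record_id for h in single] == ["fw_mm"]

    rng = np.random.default_rng(0)
    records = [_record(f"r{i}", _mutated(rng, REGIONS_FIX)) for i in range(20)]
    hits = search_database(tree, query, records)
    for perm_seed in (1, 2):
        perm = list(np.random.default_rng(perm_seed).permutation(len(records)))
        shuffled = search_database(tree, query, [records[i] for i in perm])
        assert [h.record_id for h in shuffled] == [h.record_id for h in hits]


# -- light-chain classification -------------------------------------------------


def _decoy_db(seed, n=30):
    rng = np.random.default_rng(seed)
    return [
        _record(
            f"d{seed}_{i}",
            {r: "".join(AA[j] for j in rng.integers(20, size=len(s)))
             for r, s in REGIONS_FIX.items()},
        )
        for i in range(n)
    ]


def test_classify_planted_kappa(tree):
    kappa = [_record("planted", REGIONS_FIX)] + _decoy_db(1)
    lam = _decoy_db(2)
    query = _query_from(REGIONS_FIX)
    result = classify_light_chain(tree, query, kappa, lam)
    assert result.decision == "kappa"
    assert result.kappa_max >= result.kappa_mean
    assert result.lambda_max >= result.lambda_mean
    # swapping the databases flips the decision
    swapped = classify_light_chain(tree, query, lam, kappa)
    assert swapped.decision == "lambda"
    assert swapped.lambda_max == pytest.approx(result.kappa_max)
    assert swapped.lambda_mean == pytest.approx(result.kappa_mean)


def test_classify_identical_databases_ambiguous(tree):
    db = _decoy_db(3)
    query = _query_from(REGIONS_FIX)
    result = classify_light_chain(tree, query, db, db)
    assert result.decision == "ambiguous"


def test_classify_empty_database_ambiguous(tree, caplog):
    query = _query_from(REGIONS_FIX)
    with caplog.at_level("WARNING"):
        result = classify_light_chain(tree, query, _decoy_db(4), [])
    assert result.decision == "ambiguous"
    assert result.lambda_max is None


# -- germline / whole-sequence mode ---------------------------------------------


def test_germline_exact_allele_is_top_hit(tree):
    consensus = "".join(REGIONS_FIX.values())
    query = _query_from(REGIONS_FIX)
    alleles = [
        RepertoireRecord(record_id="IGKV1*01", full_sequence=consensus),
        RepertoireRecord(record_id="IGKV2*01", full_sequence="G" * len(consensus)),
    ]
    hits = search_germline(tree, query, alleles)
    assert hits[0].record_id == "IGKV1*01"
    assert hits[0].total_score == pytest.approx(len(consensus))
    assert hits[0].rank == 1


def test_germline_empty_fasta(tree, tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    query = _query_from(REGIONS_FIX)
    assert search_germline(tree, query, path) == []


def test_sliding_mode_matches_regions_mode_for_degenerate_split(tree):
    """One region holding the full query scores the same in both modes."""
    seq = "".join(REGIONS_FIX.values())
    query = StructuralQuery(chain_class="kappa", segments={"FW1": tuple(seq)})
    regions_hit = search_record(
        tree, query, _record("r", {"FW1": seq}), SearchParams(mode="regions")
    )
    sliding_hit = search_record(
        tree,
        query,
        RepertoireRecord(record_id="r", full_sequence=seq),
        SearchParams(mode="fasta"),
    )
    assert sliding_hit.total_score == pytest.approx(regions_hit.total_score)


def test_fasta_mode_finds_embedded_query(tree):
    seq = "".join(REGIONS_FIX.values())
    padded = "GGGGG" + seq + "WWWWW"
    query = _query_from(REGIONS_FIX)
    hit = search_record(
        tree,
        query,
        RepertoireRecord(record_id="r", full_sequence=padded),
        SearchParams(mode="fasta"),
    )
    assert hit.total_score == pytest.approx(len(seq))
    assert hit.mismatch_total == 0


# -- query file -----------------------------------------------------------------


def test_query_file_roundtrip(tree, tmp_path):
    query = _query_from(REGIONS_FIX, chain_class="lambda")
    path = tmp_path / "query.yaml"
    write_query(query, path)
    back = load_query(path)
    assert back.chain_class == "lambda"
    assert dict(back.segments) == dict(query.segments)
    back.validate(tree)


def test_query_file_errors(tmp_path):
    from abseek.io import FormatError

    bad = tmp_path / "bad.yaml"
    bad.write_text("segments:\n  NOPE: A C D\n")
    with pytest.raises(FormatError, match="NOPE"):
        load_query(bad)
    bad.write_text("chain_class: kappa\n")
    with pytest.raises(FormatError, match="segments"):
        load_query(bad)


def test_query_validate_rejects_unknown_code(tree):
    query = StructuralQuery(chain_class="kappa", segments={"CDR3": ("A", "ZZZ")})
    with pytest.raises(KeyError):
        query.validate(tree)
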
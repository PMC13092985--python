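"""Structural parsing and anticodon-stem classification."""

import numpy as np
import pytest

from conftest import lattice_specs
from stemscan.synthetic import TRNASpec, make_trna
from stemscan.trna_struct import (
    UNKNOWN,
    TRNARecord,
    annotate_arms,
    as_span,
    canonical_positions,
    classify,
    filter_records,
    format_ss_block,
    pair_map,
    parse_out_table,
    parse_ss_records,
)


# ---------------------------------------------------------------------------
# pair_map
# ---------------------------------------------------------------------------


def brute_force_pairs(s: str) -> set[tuple[int, int]]:
    """Independent recursive matcher: find the partner of the first '>' by
    depth counting, then recurse inside and after it."""

    def rec(lo: int, hi: int) -> set:
        pairs = set()
        i = lo
        while i <= hi:
            if s[i - 1] == ">":
                depth = 1
                j = i + 1
                while depth:
                    if s[j - 1] == ">":
                        depth += 1
                    elif s[j - 1] == "<":
                        depth -= 1
                    j += 1
                j -= 1
                pairs.add((i, j))
                pairs |= rec(i + 1, j - 1)
                i = j + 1
            else:
                i += 1
        return pairs

    return rec(1, len(s))


def random_structure(rng: np.random.Generator, n: int) -> str:
    """Random balanced nested structure of length <= n."""
    out = []
    depth = 0
    for _ in range(n):
        r = rng.random()
        if r < 0.35:
            out.append(">")
            depth += 1
        elif r < 0.7 and depth:
            out.append("<")
            depth -= 1
        else:
            out.append(".")
    out.extend("<" * depth)
    return "".join(out)


@pytest.mark.parametrize(
    "structure,expected",
    [
        (">>..<<", {(1, 6), (2, 5)}),
        ("......", set()),
        (">.<", {(1, 3)}),
    ],
)
def test_pair_map_hand_examples(structure, expected):
    assert pair_map(structure) == expected


def test_pair_map_matches_recursive_matcher():
    rng = np.random.default_rng(42)
    for _ in range(300):
        s = random_structure(rng, int(rng.integers(1, 41)))
        assert pair_map(s) == brute_force_pairs(s)


def test_pair_map_unbalanced_errors_name_offending_index():
    with pytest.raises(ValueError, match="position 1"):
        pair_map("<..")
    with pytest.raises(ValueError, match="position 2"):
        pair_map(".>.")


# ---------------------------------------------------------------------------
# "-ss" dialect parsing
# ---------------------------------------------------------------------------


def test_writer_parser_round_trip_over_seeded_lattice():
    for spec in lattice_specs(seeds=range(2)):
        sim = make_trna(spec)
        result = parse_ss_records(sim.ss_block)
        assert not result.errors
        assert result.records[0] == sim.record


def test_parser_flags_pseudogene_and_undetermined():
    sim = make_trna(TRNASpec(pseudogene=True, seed=3))
    rec = parse_ss_records(sim.ss_block).records[0]
    assert rec.pseudogene

    undet = sim.ss_block.replace("Type: Trp", "Type: Undet").replace(
        "Anticodon: CCA", "Anticodon: NNN"
    )
    # sequence check is skipped for undetermined anticodons
    rec = parse_ss_records(undet).records[0]
    assert rec.undetermined


def test_parser_collects_errors_and_continues():
    good = make_trna(TRNASpec(seed=1), record_id="g.trna1").ss_block
    bad = good.replace("g.trna1", "g.trna2").replace("Seq: ", "Seq: AAAA")
    result = parse_ss_records(bad + good)
    assert len(result.records) == 1
    assert result.records[0].record_id == "g.trna1"
    assert len(result.errors) == 1 and result.errors[0].record_id == "g.trna2"


def test_unpaired_structure_parses_to_empty_pair_map():
    rec = TRNARecord("x", "", "Gly", "GCC", "A" * 40, "." * 40, 20)
    block = format_ss_block(rec)
    parsed = parse_ss_records(block).records
    # anticodon mismatch is an error; use a matching sequence instead
    seq = "A" * 19 + "GCC" + "A" * 18
    rec = TRNARecord("x", "", "Gly", "GCC", seq, "." * 40, 20)
    parsed = parse_ss_records(format_ss_block(rec)).records
    assert pair_map(parsed[0].structure) == set()


def test_parse_out_table_dialect():
    text = (
        "Sequence\t\ttRNA\tBounds\n"
        "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n"
        "--------\t------\t-----\t----\t----\t-----\t-----\t---\t-----\t----\n"
        "chr1\t1\t100\t175\tTrp\tCCA\t0\t0\t72.5\t\n"
        "chr1\t2\t300\t380\tUndet\tNNN\t0\t0\t40.0\tpseudo\n"
    )
    rows = parse_out_table(text)
    assert len(rows) == 2
    assert rows[0]["isotype"] == "Trp" and rows[0]["score"] == 72.5
    assert rows[1]["anticodon"] == "NNN"


# ---------------------------------------------------------------------------
# arm annotation and classification
# ---------------------------------------------------------------------------


def test_planted_class_recovery_over_lattice():
    for spec in lattice_specs(seeds=range(2)):
        cls = classify(make_trna(spec).record)
        assert cls.as_bin == spec.expected_bin(), spec
        assert cls.flag_A9C == spec.plant_A9C, spec
        assert cls.flag_G24A == spec.plant_G24A, spec
        assert cls.blasto_like == spec.expected_blasto_like(), spec


def test_top_unpinning_keeps_loop_bottom_lengthens_it():
    top = classify(make_trna(TRNASpec(as_pairs=4, unpinned="top")).record)
    bottom = classify(make_trna(TRNASpec(as_pairs=4, unpinned="bottom")).record)
    assert (top.as_bin, top.al_length) == ("AS4_top", 7)
    assert (bottom.as_bin, bottom.al_length) == ("AS4_bottom", 9)
    # the engineered C27A substitution leaves an A:G mispair at the top
    assert top.unpinned_pair == "A:G"


def test_as_span_bulge_rule():
    # four pairs with one unpaired nucleotide in between spans five -> AS5
    bulged = make_trna(TRNASpec(as_pairs=4, bulge="five_prime")).record
    arm = annotate_arms(bulged)
    assert as_span(arm) == (5, 4, 5)
    assert classify(bulged).as_bin == "AS5"
    plain5 = annotate_arms(make_trna(TRNASpec(as_pairs=5)).record)
    assert as_span(plain5) == (5, 5, 5)
    plain4 = annotate_arms(make_trna(TRNASpec(as_pairs=4)).record)
    assert as_span(plain4) == (4, 4, 4)


def test_as_span_exceeds_pair_count_only_with_bulge():
    for spec in lattice_specs(seeds=[7]):
        arm = annotate_arms(make_trna(spec).record)
        _, _, bin_length = as_span(arm)
        assert bin_length >= len(arm.anticodon_stem)
        assert (bin_length == len(arm.anticodon_stem)) == (spec.bulge == "none")


def test_canonical_position_planting():
    a9c = classify(make_trna(TRNASpec(plant_A9C=True)).record)
    assert a9c.pos9 == "C" and a9c.flag_A9C is True
    g24a = classify(make_trna(TRNASpec(plant_G24A=True)).record)
    assert g24a.pos24 == "A" and g24a.flag_G24A is True


def test_single_nucleotide_linker_makes_position9_unknown():
    # hand-built miniature: acceptor 3 bp, 1-nt linker, D-stem 2 bp, AS 3 bp
    struct = ">>>.>>...<<.>>>.......<<<.<<<"
    seq = "A" * 16 + "AAA" + "A" * 10
    rec = TRNARecord("mini", "", "Gly", "AAA", seq, struct, 17)
    arm = annotate_arms(rec)
    assert canonical_positions(rec, arm)[9] is UNKNOWN


def test_filter_records_reason_codes():
    keep = make_trna(TRNASpec(seed=5), record_id="g.trna1").record
    pseudo = make_trna(TRNASpec(seed=6, pseudogene=True), record_id="g.trna2").record
    shifted = make_trna(TRNASpec(seed=7), record_id="g.trna3").record
    shifted.anticodon_start = 30
    shifted.sequence = shifted.sequence[:29] + "CCA" + shifted.sequence[32:]
    undet = make_trna(TRNASpec(seed=8), record_id="g.trna4").record
    undet.isotype, undet.anticodon, undet.undetermined = "Undet", "NNN", True
    badalpha = make_trna(TRNASpec(seed=9), record_id="g.trna5").record
    badalpha.anticodon = "NNA"

    kept, excluded = filter_records([keep, pseudo, shifted, undet, badalpha])
    assert [r.record_id for r in kept] == ["g.trna1"]
    reasons = {r.record_id: reason for r, reason in excluded}
    assert reasons == {
        "g.trna2": "pseudogene",
        "g.trna3": "anticodon_window",
        "g.trna4": "undetermined",
        "g.trna5": "anticodon_alphabet",
    }


def test_anticodon_window_boundaries():
    rec = make_trna(TRNASpec(seed=1)).record
    assert rec.anticodon_start == 34
    kept, _ = filter_records([rec])
    assert kept  # 34 is inside [33, 35]
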
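"""Conceptual translation, C-terminal extension detection, evidence summary."""

import numpy as np
import pytest

from stemscan.codes import get_code
from stemscan.inventory_stats import GenomeBundle, build_bundle
from stemscan.reassignment import (
    OrthogroupAlignment,
    center_star_msa,
    conserved_cterm_filter,
    cterm_extension,
    internal_stops,
    parse_orthogroup_fasta,
    summarize_evidence,
    suppressor_check,
    target_truncation,
    translate,
)
from stemscan.synthetic import (
    GenomeSpec,
    TRNASpec,
    make_genome,
    make_orthogroups,
    make_trna,
    orthogroup_fasta,
)
from stemscan.inventory_stats import ClassifiedTRNA
from stemscan.trna_struct import classify


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


def test_translate_standard_and_reassigned():
    assert translate("AUGUGGUAA", "standard") == "MW"
    assert translate("AUGUGAUAA", "trp_uga") == "MW"
    assert translate("AUGUGAUAA", "standard") == "M"  # halts at UGA
    assert translate("", "standard") == ""


def test_translate_dna_alphabet_and_frame_check():
    assert translate("ATGTGGTAA", "standard") == "MW"
    with pytest.raises(ValueError):
        translate("AUGU", "standard")


def test_trp_uga_translation_never_shorter_than_standard():
    rng = np.random.default_rng(3)
    sim = make_genome(GenomeSpec(genome_id="g", n_cds=50, seed=9))
    for cds in sim.cds:
        assert len(translate(cds, "trp_uga")) >= len(translate(cds, "standard"))


def test_internal_stop_positions_reported():
    assert internal_stops("AUGUGAUGGUAA", "standard") == [2]
    assert internal_stops("AUGUGAUGGUAA", "trp_uga") == []


# ---------------------------------------------------------------------------
# conserved C-terminus filter
# ---------------------------------------------------------------------------


def _aln(rows, codes=None):
    codes = codes or ["standard"] * len(rows)
    return OrthogroupAlignment(
        ids=[f"m{i}" for i in range(len(rows))], codes=codes, rows=rows
    )


def test_conserved_cterm_filter_cases():
    assert conserved_cterm_filter(_aln(["MKLYEAAAA", "MKLY-AAAA"]), k=4) is True
    assert conserved_cterm_filter(_aln(["MKLYEAAAA", "MKLYEAAA-"]), k=5) is False
    assert conserved_cterm_filter(_aln(["M-", "MA"]), k=0) is True
    with pytest.raises(ValueError):
        conserved_cterm_filter(_aln(["MK", "ML"]), k=5)


# ---------------------------------------------------------------------------
# extension measurement
# ---------------------------------------------------------------------------


def test_cterm_extension_coterminal_and_truncated():
    aln = _aln(
        ["MKLYE", "MKLYE", "MKLYE"], codes=["standard", "standard", "trp_uga"]
    )
    assert cterm_extension(aln) == 0
    short = _aln(
        ["MKLYE", "MKLYE", "MKL--"], codes=["standard", "standard", "trp_uga"]
    )
    assert cterm_extension(short) == 0  # truncations never count as extensions
    assert target_truncation(short) == 2


def test_cterm_extension_uses_max_reference_end():
    aln = _aln(
        ["MKLY---", "MKLYE--", "MKLYEQW"],
        codes=["standard", "standard", "trp_uga"],
    )
    # reference end = column of the longest standard row's last residue
    assert cterm_extension(aln) == 2


def test_planted_extension_recovery():
    fams = make_orthogroups(
        8, 4, extension_plan={0: 12, 3: 1, 5: 30}, seed=42, length=80
    )
    for fam in fams:
        std = [m for m in fam["members"] if m[1] == "standard"]
        assert conserved_cterm_filter(center_star_msa(std))
        full = center_star_msa(fam["members"])
        assert cterm_extension(full) == fam["planted_extension"]


def test_tail_gap_families_fail_conserved_filter():
    fams = make_orthogroups(3, 4, seed=1, tail_gap_plan={1}, length=60)
    results = []
    for fam in fams:
        std = [m for m in fam["members"] if m[1] == "standard"]
        results.append(conserved_cterm_filter(center_star_msa(std)))
    assert results == [True, False, True]


# ---------------------------------------------------------------------------
# center-star MSA
# ---------------------------------------------------------------------------


def test_center_star_identical_sequences_gapless():
    aln = center_star_msa([("a", "standard", "MKLYE")] * 3)
    assert aln.rows == ["MKLYE"] * 3


def test_center_star_two_sequences_reduces_to_pairwise():
    from stemscan.hypothesis_stats import nw_align

    a, b = "MKLYEQ", "MKYEQ"
    aln = center_star_msa([("a", "standard", a), ("b", "standard", b)])
    pw = nw_align(a, b, free_end_gaps=True)
    assert aln.rows == [pw.aligned_a, pw.aligned_b]


def test_center_star_degapping_restores_inputs():
    fams = make_orthogroups(2, 5, seed=6, length=50, extension_plan={0: 7})
    for fam in fams:
        aln = center_star_msa(fam["members"])
        assert len({len(r) for r in aln.rows}) == 1
        for row, (name, code, seq) in zip(aln.rows, fam["members"]):
            assert row.replace("-", "") == seq


def test_center_star_recovers_planted_single_indels():
    rng = np.random.default_rng(13)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    recovered = 0
    cases = 40
    for _ in range(cases):
        anc = "".join(rng.choice(aas, size=50))
        pos = int(rng.integers(5, 45))
        deleted = anc[:pos] + anc[pos + 1 :]
        aln = center_star_msa(
            [("a", "standard", anc), ("b", "standard", anc), ("c", "standard", deleted)]
        )
        row_c = aln.rows[2]
        recovered += row_c.count("-") == 1 and row_c.replace("-", "") == deleted
    assert recovered >= 0.95 * cases


def test_center_star_empty_errors():
    with pytest.raises(ValueError):
        center_star_msa([])


# ---------------------------------------------------------------------------
# suppressor + evidence
# ---------------------------------------------------------------------------


def _classified_trna(isotype, anticodon, seed=0):
    rec = make_trna(TRNASpec(isotype=isotype, anticodon=anticodon, seed=seed)).record
    return ClassifiedTRNA(rec, classify(rec))


def test_suppressor_check():
    assert suppressor_check([_classified_trna("Trp", "TCA")]) is True
    assert suppressor_check([_classified_trna("Trp", "CCA")]) is False
    assert suppressor_check([]) is False


def test_evidence_supported_for_clean_reassigned_genome():
    sim = make_genome(
        GenomeSpec(
            genome_id="g",
            species_plan=[("Trp", "CCA", "AS4_top"), ("Sup", "TCA", "AS5")],
            n_cds=50,
            uga_stop_fraction=0.0,
            code_label="trp_uga",
            seed=4,
        )
    )
    b = build_bundle("g", [t.record for t in sim.trnas], sim.cds,
                     code_label="trp_uga")
    ev = summarize_evidence(b)
    assert ev.verdict == "supported"
    assert ev.suppressor_uca_present


def test_evidence_contradicted_by_uga_ends():
    sim = make_genome(GenomeSpec(genome_id="g", n_cds=60,
                                 uga_stop_fraction=0.3, seed=5))
    b = build_bundle("g", [], sim.cds, code_label="standard")
    ev = summarize_evidence(b)
    assert ev.verdict == "contradicted"
    assert ev.pct_uga_at_cds_ends > 0


def test_evidence_supported_via_codon_inference_support():
    sim = make_genome(
        GenomeSpec(genome_id="g", species_plan=[("Trp", "CCA", "AS4_top")],
                   n_cds=40, uga_stop_fraction=0.0, code_label="trp_uga", seed=6)
    )
    b = build_bundle("g", [t.record for t in sim.trnas], sim.cds,
                     code_label="trp_uga")
    ev = summarize_evidence(b, codetta_support_columns=150)
    assert not ev.suppressor_uca_present
    assert ev.verdict == "supported"
    ev2 = summarize_evidence(b, codetta_support_columns=50)
    assert ev2.verdict == "inconclusive"


def test_evidence_contradicted_by_extensions():
    sim = make_genome(
        GenomeSpec(genome_id="g", species_plan=[("Sup", "TCA", "AS5")],
                   n_cds=40, uga_stop_fraction=0.0, code_label="trp_uga", seed=7)
    )
    b = build_bundle("g", [t.record for t in sim.trnas], sim.cds,
                     code_label="trp_uga")
    ev = summarize_evidence(b, extension_lengths=[12, 0, 3])
    assert ev.n_cterm_extensions == 2
    assert ev.verdict == "contradicted"


def test_orthogroup_fasta_round_trip():
    fam = make_orthogroups(1, 3, seed=8, length=40, extension_plan={0: 4})[0]
    parsed = parse_orthogroup_fasta(orthogroup_fasta(fam))
    assert parsed == fam["members"]
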
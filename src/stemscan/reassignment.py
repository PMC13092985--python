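"""Stop-to-tryptophan UGA reassignment validation.

The procedure mirrors how such reassignments are corroborated from genome data
alone: conceptually translate CDS under the candidate code, profile the stops
actually used at CDS ends, check protein families for artificial C-terminal
extensions (a genuine UGA stop mistranslated as Trp runs on to the next
UAA/UAG), look for a fully cognate suppressor tRNA (anticodon UCA), and fold
the pieces of evidence into a verdict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from stemscan.codes import GeneticCode, get_code
from stemscan.hypothesis_stats import nw_align
from stemscan.inventory_stats import ClassifiedTRNA, GenomeBundle, stop_usage

__all__ = [
    "OrthogroupAlignment",
    "EvidenceSummary",
    "translate",
    "conserved_cterm_filter",
    "cterm_extension",
    "center_star_msa",
    "suppressor_check",
    "summarize_evidence",
    "parse_orthogroup_fasta",
]


@dataclass
class OrthogroupAlignment:
    """Gapped protein rows with their member ids and code labels."""

    ids: list[str]
    codes: list[str]  # per-row genetic-code label (standard | trp_uga | ...)
    rows: list[str]  # gapped, equal length

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def standard_rows(self) -> list[str]:
        return [r for r, c in zip(self.rows, self.codes) if c == "standard"]

    def target_rows(self) -> list[str]:
        return [r for r, c in zip(self.rows, self.codes) if c != "standard"]


# ---------------------------------------------------------------------------
# Conceptual translation
# ---------------------------------------------------------------------------


def translate(cds: str, code: GeneticCode | str) -> str:
    """Translate an in-frame CDS, halting at the first stop of the code.

    Under the trp_uga code an internal UGA yields W; under the standard code
    it halts translation.  Length must be divisible by 3.
    """
    if isinstance(code, str):
        code = get_code(code)
    c = cds.upper().replace("T", "U")
    if len(c) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    out = []
    for k in range(0, len(c), 3):
        codon = c[k : k + 3]
        if code.is_stop(codon):
            break
        out.append(code.codon_map.get(codon, "X"))
    return "".join(out)


def internal_stops(cds: str, code: GeneticCode | str) -> list[int]:
    """1-based codon positions of stops before the final codon, under the code."""
    if isinstance(code, str):
        code = get_code(code)
    c = cds.upper().replace("T", "U")
    if len(c) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    n = len(c) // 3
    return [
        k // 3 + 1
        for k in range(0, len(c) - 3, 3)
        if code.is_stop(c[k : k + 3])
    ]


# ---------------------------------------------------------------------------
# C-terminal extension procedure
# ---------------------------------------------------------------------------


def conserved_cterm_filter(alignment: OrthogroupAlignment, k: int = 5) -> bool:
    """True iff no gap appears in any of the last ``k`` columns of the
    standard-code rows (a proxy for a conserved C-terminal region)."""
    rows = alignment.standard_rows()
    if len(rows) < 2:
        raise ValueError("need >= 2 standard-code rows")
    if k == 0:
        return True
    if alignment.n_cols < k:
        raise ValueError(f"alignment has fewer than k={k} columns")
    return all("-" not in r[-k:] for r in rows)


def cterm_extension(alignment: OrthogroupAlignment) -> int:
    """Residues by which the reassigned member overhangs the reference ends.

    The reference end column is the rightmost column holding any standard-code
    row's C-terminal residue (max over references: the most conservative
    choice against false extension calls); the extension is the number of
    non-gap target residues strictly after it.  A target shorter than the
    references scores 0 -- truncations are reported separately.
    """
    targets = alignment.target_rows()
    if len(targets) != 1:
        raise ValueError("expected exactly one reassigned (target) row")
    ref_end = -1
    for r in alignment.standard_rows():
        stripped = r.rstrip("-")
        if not stripped:
            raise ValueError("empty reference row")
        ref_end = max(ref_end, len(stripped) - 1)
    target = targets[0]
    return sum(1 for ch in target[ref_end + 1 :] if ch != "-")


def target_truncation(alignment: OrthogroupAlignment) -> int:
    """Residue columns by which the target stops short of the nearest reference end."""
    targets = alignment.target_rows()
    if len(targets) != 1:
        raise ValueError("expected exactly one reassigned (target) row")
    t_end = len(targets[0].rstrip("-")) - 1
    ref_min = min(len(r.rstrip("-")) - 1 for r in alignment.standard_rows())
    return max(0, ref_min - t_end)


# ---------------------------------------------------------------------------
# Center-star multiple alignment
# ---------------------------------------------------------------------------


def center_star_msa(
    proteins: Sequence[tuple[str, str, str]], **align_kwargs
) -> OrthogroupAlignment:
    """Center-star multiple alignment of (id, code_label, sequence) triples.

    The center is the sequence maximising the summed pairwise alignment
    scores; the others are merged against it under "once a gap, always a gap".
    Terminal gaps are free by default (semi-global pairwise alignments), so a
    member that genuinely overhangs the family -- e.g. a C-terminal extension
    from a mistranslated stop -- is laid out past the reference ends instead
    of being forced into spurious tail matches.
    """
    align_kwargs.setdefault("free_end_gaps", True)
    if not proteins:
        raise ValueError("empty orthogroup")
    if len(proteins) == 1:
        pid, code, seq = proteins[0]
        return OrthogroupAlignment([pid], [code], [seq])
    seqs = [p[2] for p in proteins]
    n = len(seqs)
    scores = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = nw_align(seqs[i], seqs[j], **align_kwargs).score
            scores[i][j] = scores[j][i] = s
    center = max(range(n), key=lambda i: (sum(scores[i]), -i))

    # master = gapped center; rows follow, re-padded as the master grows
    master = list(seqs[center])
    rows: dict[int, list[str]] = {center: list(seqs[center])}
    order = [center] + [i for i in range(n) if i != center]
    for i in order[1:]:
        aln = nw_align("".join(master).replace("-", ""), seqs[i], **align_kwargs)
        # re-express the pairwise alignment in master coordinates
        new_master: list[str] = []
        new_row: list[str] = []
        mi = 0  # index into master (which may already contain gaps)
        ai = 0  # index into aln.aligned_a (degapped master)
        a, b = aln.aligned_a, aln.aligned_b
        pos = 0
        while pos < len(a) or mi < len(master):
            if mi < len(master) and master[mi] == "-":
                new_master.append("-")
                new_row.append("-")
                mi += 1
                continue
            if pos < len(a) and a[pos] == "-":
                # insertion relative to the center: once a gap, always a gap
                new_master.append("-")
                new_row.append(b[pos])
                for r in rows.values():
                    r.insert(len(new_master) - 1, "-")
                pos += 1
                continue
            new_master.append(master[mi])
            new_row.append(b[pos] if pos < len(b) else "-")
            mi += 1
            pos += 1
        master = new_master
        rows[i] = new_row

    width = len(master)
    out_rows = []
    for i in range(n):
        r = rows[i]
        out_rows.append("".join(r) + "-" * (width - len(r)))
    return OrthogroupAlignment(
        ids=[p[0] for p in proteins],
        codes=[p[1] for p in proteins],
        rows=out_rows,
    )


# ---------------------------------------------------------------------------
# Suppressor tRNA and the evidence summary
# ---------------------------------------------------------------------------


def suppressor_check(trnas: Iterable[ClassifiedTRNA]) -> bool:
    """True iff any retained tRNA carries the UCA anticodon (fully cognate to UGA)."""
    return any(
        t.record.anticodon.upper().replace("T", "U") == "UCA" for t in trnas
    )


@dataclass
class EvidenceSummary:
    genome_id: str
    suppressor_uca_present: bool
    rf2_present: Optional[bool]
    pct_uga_at_cds_ends: float
    n_cterm_extensions: int
    n_truncations: int
    codetta_support_columns: int
    verdict: str
    reasons: list[str] = field(default_factory=list)


def summarize_evidence(
    bundle: GenomeBundle,
    extension_lengths: Sequence[int] = (),
    truncation_lengths: Sequence[int] = (),
    rf2_present: Optional[bool] = None,
    codetta_support_columns: int = 0,
    min_support_columns: int = 100,
    extension_threshold: int = 1,
) -> EvidenceSummary:
    """Fold the lines of evidence into a verdict on UGA -> Trp reassignment.

    ``supported`` requires no UGA at CDS ends, no C-terminal extensions, and
    either a suppressor tRNA(UCA) or codon-inference support of at least
    ``min_support_columns`` consensus columns.  UGA-terminated CDS or artificial
    extensions contradict the reassignment; anything else is inconclusive.
    RF2 presence is an input flag (from an external homology search) and is
    reported, not computed.
    """
    usage = stop_usage(bundle)
    if bundle.code_label == "trp_uga":
        # under the reassigned code UGA ends surface as warnings, not counts
        n_uga_ends = sum(
            1 for _, w in usage["warnings"] if w == "no_terminal_stop:UGA"
        )
        denom = usage["n_stops"] + n_uga_ends
        pct_uga = 100.0 * n_uga_ends / denom if denom else 0.0
    else:
        pct_uga = usage["pct_UGA"]
    n_ext = sum(1 for e in extension_lengths if e >= extension_threshold)
    suppressor = suppressor_check(bundle.trnas)

    reasons: list[str] = []
    if pct_uga > 0:
        reasons.append(f"UGA terminates {pct_uga:.1f}% of CDS")
    if n_ext > 0:
        reasons.append(f"{n_ext} artificial C-terminal extensions")
    if pct_uga > 0 or n_ext > 0:
        verdict = "contradicted"
    elif suppressor or codetta_support_columns >= min_support_columns:
        verdict = "supported"
        if suppressor:
            reasons.append("suppressor tRNA(UCA) present")
        if codetta_support_columns >= min_support_columns:
            reasons.append(
                f"codon inference support {codetta_support_columns} columns"
            )
    else:
        verdict = "inconclusive"
        reasons.append("no suppressor tRNA and insufficient codon-inference support")
    if rf2_present:
        reasons.append("RF2 reported present (weakens the reassignment case)")
    return EvidenceSummary(
        genome_id=bundle.genome_id,
        suppressor_uca_present=suppressor,
        rf2_present=rf2_present,
        pct_uga_at_cds_ends=float(pct_uga),
        n_cterm_extensions=n_ext,
        n_truncations=sum(1 for t in truncation_lengths if t > 0),
        codetta_support_columns=codetta_support_columns,
        verdict=verdict,
        reasons=reasons,
    )


_HEADER_CODE_RE = re.compile(r"code=(\S+)")


def parse_orthogroup_fasta(text: str) -> list[tuple[str, str, str]]:
    """Read one family FASTA with ``code=standard|trp_uga`` header tags."""
    out: list[tuple[str, str, str]] = []
    name = code = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                out.append((name, code, "".join(chunks)))
            header = line[1:].strip()
            name = header.split()[0]
            m = _HEADER_CODE_RE.search(header)
            code = m.group(1) if m else "standard"
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        out.append((name, code, "".join(chunks)))
    return out
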
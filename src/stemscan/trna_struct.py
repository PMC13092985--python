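"""Parsing and structural classification of tRNA genes.

Records are read from the tRNAscan-SE secondary-structure ("-ss") text dialect,
in which each tRNA is a block of header, ``Type:``/``Anticodon:`` line, and
paired ``Seq:``/``Str:`` lines where ``>`` and ``<`` mark the 5' and 3' partners
of a base pair and ``.`` an unpaired position.

Classification bins each tRNA by its anticodon-stem (AS) span:

* ``AS5`` -- canonical 5-bp stem (a 4-pair stem with a single-nucleotide bulge
  also spans 5 and is binned here);
* ``AS4_top`` -- 4-bp stem with a 7-nt anticodon loop (AL), i.e. the distal
  ("top") pair of the stem is unpinned;
* ``AS4_bottom`` -- 4-bp stem with a 9-nt AL (proximal pair unpinned);
* ``AS4_other`` -- 4-bp span with any other loop length;
* ``OTHER`` -- all remaining spans (2, 3, 6, 7 bp ...).

All coordinates are 1-based, fully closed, matching tRNAscan-SE's display
convention.  T is normalised to U for every sequence comparison; the input
alphabet is preserved on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

__all__ = [
    "UNKNOWN",
    "TRNARecord",
    "ArmAnnotation",
    "ASClassification",
    "SSParseError",
    "SSParseResult",
    "parse_ss_records",
    "format_ss_block",
    "parse_out_table",
    "pair_map",
    "helices",
    "annotate_arms",
    "as_span",
    "canonical_positions",
    "classify",
    "filter_records",
    "classification_row",
    "CLASSIFICATION_COLUMNS",
]


class UNKNOWN:
    """Sentinel for an undeterminable canonical position or flag."""

    def __repr__(self) -> str:  # pragma: no cover - repr only
        return "UNKNOWN"


UNKNOWN = UNKNOWN()

_RNA = {"A", "C", "G", "U"}


def _rna(s: str) -> str:
    return s.upper().replace("T", "U")


@dataclass
class TRNARecord:
    """One predicted tRNA gene with sequence and secondary structure."""

    record_id: str
    genome_id: str
    isotype: str
    anticodon: str
    sequence: str
    structure: str
    anticodon_start: int  # 1-based index of the first anticodon base
    pseudogene: bool = False
    undetermined: bool = False
    score: Optional[float] = None

    def rna_sequence(self) -> str:
        return _rna(self.sequence)

    def base(self, pos: int) -> str:
        """1-based nucleotide lookup, T normalised to U."""
        return _rna(self.sequence[pos - 1])


@dataclass
class ArmAnnotation:
    """Cloverleaf arm assignment: lists of (i, j) pairs, outermost to innermost."""

    acceptor: list[tuple[int, int]]
    d_stem: Optional[list[tuple[int, int]]]
    anticodon_stem: Optional[list[tuple[int, int]]]
    variable_stem: Optional[list[tuple[int, int]]]
    t_stem: Optional[list[tuple[int, int]]]
    al_length: Optional[int]
    as_span5: Optional[int]
    as_span3: Optional[int]


@dataclass
class ASClassification:
    """Structural verdict for one tRNA."""

    as_bin: str  # AS5 | AS4_top | AS4_bottom | AS4_other | OTHER
    as_paired_count: int
    al_length: Optional[int]
    pos9: object = UNKNOWN
    pos24: object = UNKNOWN
    pos27: object = UNKNOWN
    pos43: object = UNKNOWN
    flag_A9C: object = UNKNOWN
    flag_G24A: object = UNKNOWN
    unpinned_pair: Optional[str] = None
    blasto_like: bool = False


@dataclass
class SSParseError:
    record_id: str
    message: str


@dataclass
class SSParseResult:
    records: list[TRNARecord] = field(default_factory=list)
    errors: list[SSParseError] = field(default_factory=list)


# ---------------------------------------------------------------------------
# "-ss" dialect reader / writer
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^(\S+)\s+\((-?\d+)-(-?\d+)\)")
_TYPE_RE = re.compile(
    r"Type:\s*(\S+)\s+Anticodon:\s*(\S+)\s+at\s+(\d+)-(\d+)"
    r"(?:\s*\((-?\d+)-(-?\d+)\))?(?:\s+Score:\s*([\d.]+))?"
)


def _genome_of(record_id: str) -> str:
    m = re.match(r"^(.*)\.trna\d+$", record_id)
    return m.group(1) if m else ""


def parse_ss_records(stream: TextIO | str) -> SSParseResult:
    """Parse tRNAscan-SE "-ss"-style blocks into :class:`TRNARecord` objects.

    Malformed blocks (Seq/Str length mismatch, unbalanced pairing string,
    anticodon/sequence disagreement) are collected as record-level errors and
    parsing continues with the next block.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    result = SSParseResult()
    block: list[str] = []

    def flush(block: list[str]) -> None:
        if not any(line.strip() for line in block):
            return
        rec_id = "?"
        try:
            header = block[0]
            m = _HEADER_RE.match(header)
            if not m:
                raise ValueError(f"unparseable header: {header!r}")
            rec_id = m.group(1)
            isotype = anticodon = None
            ac_start = None
            score = None
            pseudo = False
            seq = struct = None
            for line in block[1:]:
                tm = _TYPE_RE.search(line)
                if tm:
                    isotype = tm.group(1)
                    anticodon = tm.group(2)
                    ac_start = int(tm.group(3))
                    if tm.group(7) is not None:
                        score = float(tm.group(7))
                    continue
                if "pseudogene" in line.lower():
                    pseudo = True
                    continue
                if line.startswith("Seq:"):
                    seq = line.split(":", 1)[1].strip()
                elif line.startswith("Str:"):
                    struct = line.split(":", 1)[1].strip()
            if isotype is None or seq is None or struct is None:
                raise ValueError("block missing Type:, Seq: or Str: line")
            if len(seq) != len(struct):
                raise ValueError(
                    f"Seq length {len(seq)} != Str length {len(struct)}"
                )
            if struct.count(">") != struct.count("<"):
                raise ValueError("unbalanced '>'/'<' in Str line")
            undet = isotype.lower() == "undet" or any(
                c not in _RNA for c in _rna(anticodon)
            )
            if not undet:
                found = _rna(seq[ac_start - 1 : ac_start + 2])
                if found != _rna(anticodon):
                    raise ValueError(
                        f"anticodon {anticodon} not at {ac_start} (found {found})"
                    )
            result.records.append(
                TRNARecord(
                    record_id=rec_id,
                    genome_id=_genome_of(rec_id),
                    isotype=isotype,
                    anticodon=anticodon,
                    sequence=seq,
                    structure=struct,
                    anticodon_start=ac_start,
                    pseudogene=pseudo,
                    undetermined=undet,
                    score=score,
                )
            )
        except ValueError as exc:
            result.errors.append(SSParseError(rec_id, str(exc)))

    for line in lines:
        if not line.strip():
            if block:
                flush(block)
                block = []
        else:
            block.append(line)
    if block:
        flush(block)
    return result


def format_ss_block(record: TRNARecord, begin: int = 1) -> str:
    """Render a record as one "-ss" dialect block (round-trips through the parser)."""
    n = len(record.sequence)
    end = begin + n - 1
    g1 = begin + record.anticodon_start - 1
    lines = [
        f"{record.record_id} ({begin}-{end})\tLength: {n} bp",
    ]
    type_line = (
        f"Type: {record.isotype}\tAnticodon: {record.anticodon} at "
        f"{record.anticodon_start}-{record.anticodon_start + 2} ({g1}-{g1 + 2})"
    )
    if record.score is not None:
        type_line += f"\tScore: {record.score:.1f}"
    lines.append(type_line)
    if record.pseudogene:
        lines.append("Possible pseudogene:  HMM Sc=0.00")
    lines.append(f"Seq: {record.sequence}")
    lines.append(f"Str: {record.structure}")
    return "\n".join(lines) + "\n\n"


def parse_out_table(stream: TextIO | str) -> list[dict]:
    """Parse the tabular tRNAscan-SE ".out" dialect.

    Columns: sequence name, tRNA#, begin, end, type, anticodon, intron begin,
    intron end, score, and an optional note column.  The three header lines
    (titles and the dashed rule) are skipped when present.
    """
    text = stream if isinstance(stream, str) else stream.read()
    rows: list[dict] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.lstrip().startswith(("Sequence", "Name", "--")):
            continue
        parts = re.split(r"\t|\s{2,}", line.strip())
        if len(parts) < 9:
            parts = line.split()
        if len(parts) < 9:
            continue
        rows.append(
            {
                "sequence_name": parts[0],
                "trna_number": int(parts[1]),
                "begin": int(parts[2]),
                "end": int(parts[3]),
                "isotype": parts[4],
                "anticodon": parts[5],
                "intron_begin": int(parts[6]),
                "intron_end": int(parts[7]),
                "score": float(parts[8]),
                "note": parts[9] if len(parts) > 9 else "",
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Pairing and arm annotation
# ---------------------------------------------------------------------------


def pair_map(structure: str) -> set[tuple[int, int]]:
    """Match ``>`` with ``<`` by stack pairing; 1-based, properly nested pairs.

    Raises ``ValueError`` naming the first offending index when unbalanced.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(structure, start=1):
        if ch == ">":
            stack.append(idx)
        elif ch == "<":
            if not stack:
                raise ValueError(f"unmatched '<' at position {idx}")
            pairs.add((stack.pop(), idx))
    if stack:
        raise ValueError(f"unmatched '>' at position {stack[0]}")
    return pairs


def helices(pairs: Iterable[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into helices, outermost pair first.

    Consecutive stacked pairs extend a helix; at most one single-nucleotide
    bulge per strand is tolerated within a helix, a second bulge on the same
    strand starts a new helix.
    """
    ordered = sorted(pairs)
    out: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    bulge5 = bulge3 = 0
    for p in ordered:
        if not cur:
            cur = [p]
            bulge5 = bulge3 = 0
            continue
        pi, pj = cur[-1]
        di, dj = p[0] - pi, pj - p[1]
        if (di, dj) == (1, 1):
            cur.append(p)
        elif (di, dj) == (2, 1) and bulge5 == 0:
            bulge5 += 1
            cur.append(p)
        elif (di, dj) == (1, 2) and bulge3 == 0:
            bulge3 += 1
            cur.append(p)
        else:
            out.append(cur)
            cur = [p]
            bulge5 = bulge3 = 0
    if cur:
        out.append(cur)
    return out


def annotate_arms(
    record: TRNARecord, pairs: Optional[set[tuple[int, int]]] = None
) -> ArmAnnotation:
    """Assign helices to cloverleaf arms.

    The acceptor is the outermost helix; the anticodon stem (AS) is the helix
    whose innermost pair most tightly encloses the anticodon triplet; the
    D-stem is the first helix 3' of the acceptor 5' strand that is not the AS;
    the T-stem is the last helix before the acceptor 3' strand; anything
    between AS and T-stem is the variable stem.
    """
    if pairs is None:
        pairs = pair_map(record.structure)
    hx = helices(pairs)
    if not hx:
        return ArmAnnotation([], None, None, None, None, None, None, None)

    acceptor = min(hx, key=lambda h: h[0][0])

    a0, a2 = record.anticodon_start, record.anticodon_start + 2
    enclosing = [
        h for h in hx if h[-1][0] < a0 and h[-1][1] > a2
    ]
    if not enclosing:
        return ArmAnnotation(acceptor, None, None, None, None, None, None, None)
    as_helix = min(enclosing, key=lambda h: h[-1][1] - h[-1][0])

    acc_5p_end = acceptor[-1][0]
    d_candidates = [
        h
        for h in hx
        if h is not acceptor
        and h is not as_helix
        and h[0][0] > acc_5p_end
        and h[0][0] < as_helix[0][0]
    ]
    d_stem = min(d_candidates, key=lambda h: h[0][0]) if d_candidates else None

    as_3p_end = max(j for _, j in as_helix)
    late = sorted(
        (
            h
            for h in hx
            if h not in (acceptor, as_helix, d_stem) and h[0][0] > as_3p_end
        ),
        key=lambda h: h[0][0],
    )
    t_stem = late[-1] if late else None
    variable = late[-2] if len(late) >= 2 else None

    i_in, j_in = as_helix[-1]
    al_length = j_in - i_in - 1
    i_vals = [i for i, _ in as_helix]
    j_vals = [j for _, j in as_helix]
    span5 = max(i_vals) - min(i_vals) + 1
    span3 = max(j_vals) - min(j_vals) + 1
    return ArmAnnotation(
        acceptor, d_stem, as_helix, variable, t_stem, al_length, span5, span3
    )


def as_span(arm: ArmAnnotation) -> tuple[int, int, int]:
    """Bulge-inclusive AS strand spans and the bin-defining length (their max)."""
    if arm.anticodon_stem is None:
        raise ValueError("no anticodon stem annotated")
    return arm.as_span5, arm.as_span3, max(arm.as_span5, arm.as_span3)


def canonical_positions(record: TRNARecord, arm: ArmAnnotation) -> dict[int, object]:
    """Map canonical tRNA positions 9, 24, 27 and 43 to sequence indices.

    Position 9 sits two nucleotides after the acceptor 5' strand (UNKNOWN when
    the acceptor-to-D-stem linker is a single nucleotide); 24 is the partner of
    the second D-stem 5' nucleotide; 27/43 flank the anticodon stem: its
    outermost paired bases for a 5-bp stem, the unpaired bases immediately
    outside the outermost pair for a top-unpinned 4-bp stem.
    """
    out: dict[int, object] = {9: UNKNOWN, 24: UNKNOWN, 27: UNKNOWN, 43: UNKNOWN}
    if arm.acceptor:
        acc_end = arm.acceptor[-1][0]
        if arm.d_stem is not None:
            d_start = arm.d_stem[0][0]
            if d_start - acc_end > 2:
                out[9] = acc_end + 2
        else:
            out[9] = acc_end + 2
    if arm.d_stem is not None and len(arm.d_stem) >= 2:
        d_start = arm.d_stem[0][0]
        partner = {i: j for i, j in arm.d_stem}
        if d_start + 1 in partner:
            out[24] = partner[d_start + 1]
    if arm.anticodon_stem is not None:
        s5, s3, bin_length = as_span(arm)
        i_out = min(i for i, _ in arm.anticodon_stem)
        j_out = max(j for _, j in arm.anticodon_stem)
        if bin_length == 5:
            out[27], out[43] = i_out, j_out
        elif bin_length == 4 and arm.al_length == 7:
            if i_out - 1 >= 1:
                out[27] = i_out - 1
            if j_out + 1 <= len(record.sequence):
                out[43] = j_out + 1
    return out


_BINS = {"AS5", "AS4_top", "AS4_bottom", "AS4_other", "OTHER"}


def classify(record: TRNARecord) -> ASClassification:
    """Full structural classification of one tRNA record.

    A 4-bp span with a 7-nt anticodon loop is a top-unpinned stem; with a 9-nt
    loop a bottom-unpinned one.  ``blasto_like`` marks the architecture
    associated with UGA readthrough: top-unpinned, with neither the A9C nor the
    Hirsh G24A substitution at the mapped canonical positions (an UNKNOWN
    position makes the flag conservatively false).
    """
    pairs = pair_map(record.structure)
    arm = annotate_arms(record, pairs)
    if arm.anticodon_stem is None:
        return ASClassification(as_bin="OTHER", as_paired_count=0, al_length=None)

    _, _, bin_length = as_span(arm)
    if bin_length == 5:
        as_bin = "AS5"
    elif bin_length == 4:
        if arm.al_length == 7:
            as_bin = "AS4_top"
        elif arm.al_length == 9:
            as_bin = "AS4_bottom"
        else:
            as_bin = "AS4_other"
    else:
        as_bin = "OTHER"

    cpos = canonical_positions(record, arm)

    def nt(pos: object) -> object:
        return record.base(pos) if pos is not UNKNOWN else UNKNOWN

    n9, n24, n27, n43 = (nt(cpos[k]) for k in (9, 24, 27, 43))
    flag_a9c = (n9 == "C") if n9 is not UNKNOWN else UNKNOWN
    flag_g24a = (n24 == "A") if n24 is not UNKNOWN else UNKNOWN
    unpinned = None
    if as_bin == "AS4_top" and n27 is not UNKNOWN and n43 is not UNKNOWN:
        unpinned = f"{n27}:{n43}"
    blasto = as_bin == "AS4_top" and flag_a9c is False and flag_g24a is False
    return ASClassification(
        as_bin=as_bin,
        as_paired_count=len(arm.anticodon_stem),
        al_length=arm.al_length,
        pos9=n9,
        pos24=n24,
        pos27=n27,
        pos43=n43,
        flag_A9C=flag_a9c,
        flag_G24A=flag_g24a,
        unpinned_pair=unpinned,
        blasto_like=blasto,
    )


# ---------------------------------------------------------------------------
# Retention filter
# ---------------------------------------------------------------------------

REASON_PSEUDOGENE = "pseudogene"
REASON_UNDETERMINED = "undetermined"
REASON_ANTICODON_ALPHABET = "anticodon_alphabet"
REASON_ANTICODON_WINDOW = "anticodon_window"


def filter_records(
    records: Iterable[TRNARecord],
) -> tuple[list[TRNARecord], list[tuple[TRNARecord, str]]]:
    """Apply the retention filter; every exclusion carries a reason code.

    Excluded are pseudogenes, records of undetermined type, anticodons with
    non-ACGU characters, and records whose anticodon triplet does not lie fully
    within sequence positions 33-37 (triplet start in [33, 35]).
    """
    kept: list[TRNARecord] = []
    excluded: list[tuple[TRNARecord, str]] = []
    for rec in records:
        if rec.pseudogene:
            excluded.append((rec, REASON_PSEUDOGENE))
        elif rec.undetermined and rec.isotype.lower() == "undet":
            excluded.append((rec, REASON_UNDETERMINED))
        elif any(c not in _RNA for c in _rna(rec.anticodon)):
            excluded.append((rec, REASON_ANTICODON_ALPHABET))
        elif not 33 <= rec.anticodon_start <= 35:
            excluded.append((rec, REASON_ANTICODON_WINDOW))
        else:
            kept.append(rec)
    return kept, excluded


CLASSIFICATION_COLUMNS = [
    "record_id",
    "genome_id",
    "isotype",
    "anticodon",
    "as_bin",
    "al_length",
    "unpinned_pair",
    "flag_A9C",
    "flag_G24A",
    "blasto_like",
    "exclusion_reason",
]


def classification_row(
    record: TRNARecord,
    cls: Optional[ASClassification],
    exclusion_reason: str = "",
) -> dict:
    """One output-TSV row per tRNA (excluded records carry empty class fields)."""

    def show(v: object) -> object:
        if v is UNKNOWN:
            return "UNKNOWN"
        return v

    return {
        "record_id": record.record_id,
        "genome_id": record.genome_id,
        "isotype": record.isotype,
        "anticodon": _rna(record.anticodon),
        "as_bin": cls.as_bin if cls else "",
        "al_length": cls.al_length if cls else "",
        "unpinned_pair": (cls.unpinned_pair or "") if cls else "",
        "flag_A9C": show(cls.flag_A9C) if cls else "",
        "flag_G24A": show(cls.flag_G24A) if cls else "",
        "blasto_like": cls.blasto_like if cls else "",
        "exclusion_reason": exclusion_reason,
    }
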
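"""Codon-decoding rules: strict Watson-Crick, Crick wobble, superwobble, and
the extended-superwobble rule.

Conventions: the anticodon is written 5'->3' as positions (34, 35, 36); codons
are 5'->3'; pairing is antiparallel, i.e. base 36 reads codon position 1, base
35 position 2, and the wobble base 34 codon position 3.

Third-position rules per model (readable codon 3rd bases for a given base 34):

* ``strict``  -- the Watson-Crick partner only;
* ``wobble``  -- adds G34:U, U34:G, and inosine (I34) reading U/C/A;
* ``superwobble`` -- an unmodified U34 reads all four third-position bases;
* ``extended`` -- superwobble plus C34 reading both G and A, but only on a
  tRNA whose anticodon stem is 4 bp with a 7-nt loop (top-unpinned), the
  architecture proposed to license the otherwise disfavoured C:A pair.

The engine treats inosine as an input alphabet character; A-to-I editing
itself is not modelled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from stemscan.codes import GeneticCode, get_code

__all__ = [
    "DecodingModel",
    "CoverageReport",
    "decoding_model",
    "readable_codons",
    "coverage",
    "minimal_anticodon_set",
    "MODEL_ORDER",
]

MODEL_ORDER = ("strict", "wobble", "superwobble", "extended")

_WC = {"A": "U", "U": "A", "G": "C", "C": "G", "I": "C"}
_AC_ALPHABET = set("ACGUI")

# one-letter code for isotype labels, used to flag misreading
_ISO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "fMet": "M", "iMet": "M", "Phe": "F", "Pro": "P", "Ser": "S",
    "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


@dataclass(frozen=True)
class DecodingModel:
    """Named rule set for third-position codon-anticodon pairing."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in MODEL_ORDER:
            raise ValueError(f"unknown decoding model: {self.label!r}")

    def third_bases(self, base34: str, as_bin: str) -> frozenset:
        """Readable codon third bases for wobble base ``base34``."""
        wc = _WC[base34]
        third = {wc}
        if self.label == "strict":
            return frozenset(third)
        if base34 == "G":
            third.add("U")
        elif base34 == "U":
            third.add("G")
        elif base34 == "I":
            third.update("UCA")
        if self.label in ("superwobble", "extended") and base34 == "U":
            third.update("ACGU")
        if self.label == "extended" and base34 == "C" and as_bin == "AS4_top":
            third.update("GA")
        return frozenset(third)


def decoding_model(label: str) -> DecodingModel:
    return DecodingModel(label)


def readable_codons(
    anticodon: str, as_bin: str, model: DecodingModel | str
) -> frozenset:
    """The set of codons readable by a tRNA with this anticodon and AS class."""
    if isinstance(model, str):
        model = DecodingModel(model)
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3 or any(c not in _AC_ALPHABET for c in ac):
        raise ValueError(f"ambiguous or invalid anticodon: {anticodon!r}")
    b34, b35, b36 = ac
    if b35 == "I" or b36 == "I":
        raise ValueError("inosine is modelled at position 34 only")
    first, second = _WC[b36], _WC[b35]
    return frozenset(
        first + second + third for third in model.third_bases(b34, as_bin)
    )


@dataclass
class CoverageReport:
    decoded: dict = field(default_factory=dict)  # sense codon -> set of tRNA ids
    uncovered_sense: set = field(default_factory=set)
    stop_readthrough: dict = field(default_factory=dict)  # stop codon -> ids
    misread: dict = field(default_factory=dict)  # sense codon -> ids of
    # tRNAs whose isotype differs from the codon's amino acid


def coverage(
    trnas: Iterable[tuple[str, str, str, str]],
    model: DecodingModel | str,
    code: GeneticCode | str = "standard",
) -> CoverageReport:
    """Codon coverage of a tRNA set under a decoding model and genetic code.

    ``trnas`` yields (id, isotype, anticodon, as_bin) tuples.  Sense codons
    decoded by no tRNA are reported uncovered; tRNAs whose readable set
    intersects the stop set appear in ``stop_readthrough``; tRNAs reading a
    codon assigned to a different amino acid appear in ``misread``.
    """
    if isinstance(model, str):
        model = DecodingModel(model)
    if isinstance(code, str):
        code = get_code(code)
    sense = set(code.sense_codons())
    report = CoverageReport(uncovered_sense=set(sense))
    for tid, isotype, anticodon, as_bin in trnas:
        codons = readable_codons(anticodon, as_bin, model)
        aa = _ISO1.get(isotype)
        for codon in codons:
            if codon in code.stop_codons:
                report.stop_readthrough.setdefault(codon, set()).add(tid)
                continue
            if codon not in sense:
                continue
            report.decoded.setdefault(codon, set()).add(tid)
            report.uncovered_sense.discard(codon)
            if aa is not None and code.codon_map[codon] != aa:
                report.misread.setdefault(codon, set()).add(tid)
    return report


def minimal_anticodon_set(
    model: DecodingModel | str,
    code: GeneticCode | str = "standard",
    alphabet: str = "ACGUI",
    as_classes: Sequence[str] = ("AS5", "AS4_top"),
    avoid_misreading: bool = True,
) -> tuple[int, list[tuple[str, str]]]:
    """Exact minimum number of (anticodon, AS class) units decoding all sense codons.

    The problem decomposes by amino acid: a unit whose readable set may not
    touch a codon of another amino acid or a stop (the misreading constraint,
    on by default) can only serve one amino acid, so each amino acid's codons
    are covered independently by exhaustive minimum set cover over the
    candidate units.  Returns the total cardinality and one witness set.

    Rule sets are *enabling*: a relaxed model does not force every tRNA to use
    its widest reading (an unmodified U34 superwobbles, a modified one follows
    the plain wobble rule), so candidate units are drawn from the requested
    model and every more restrictive one.  This makes the minimum
    non-increasing along strict -> wobble -> superwobble -> extended.
    """
    if isinstance(model, str):
        model = DecodingModel(model)
    if isinstance(code, str):
        code = get_code(code)
    enabled = [
        DecodingModel(lbl)
        for lbl in MODEL_ORDER[: MODEL_ORDER.index(model.label) + 1]
    ]
    sense = set(code.sense_codons())
    by_aa: dict[str, set[str]] = {}
    for codon in sense:
        by_aa.setdefault(code.codon_map[codon], set()).add(codon)

    total = 0
    witness: list[tuple[str, str]] = []
    for aa, codons in sorted(by_aa.items()):
        candidates: dict[frozenset, tuple[str, str]] = {}
        for b34, b35, b36 in itertools.product(alphabet, "ACGU", "ACGU"):
            if b35 == "I" or b36 == "I":
                continue
            ac = b34 + b35 + b36
            for as_bin in as_classes:
                for sub in enabled:
                    readable = readable_codons(ac, as_bin, sub)
                    covered = readable & codons
                    if not covered:
                        continue
                    if avoid_misreading:
                        foreign = {
                            c
                            for c in readable
                            if c in code.stop_codons
                            or (c in sense and code.codon_map[c] != aa)
                        }
                        if foreign:
                            continue
                    key = frozenset(covered)
                    candidates.setdefault(key, (ac, as_bin))
        sets = sorted(candidates, key=lambda s: (-len(s), sorted(s)))
        best = None
        for r in range(1, len(codons) + 1):
            for combo in itertools.combinations(sets, r):
                if frozenset().union(*combo) >= codons:
                    best = combo
                    break
            if best is not None:
                break
        if best is None:
            raise ValueError(f"codons of {aa} not coverable under model {model.label}")
        total += len(best)
        witness.extend(candidates[s] for s in best)
    return total, witness
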
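"""Built-in genetic code tables keyed by label.

``standard`` carries NCBI translation table 11 semantics (the bacterial code:
stops UAA/UAG/UGA); ``trp_uga`` carries table 4 semantics at UGA (UGA -> Trp,
stops UAA/UAG).  ``gly_uga`` (UGA -> Gly) and ``met_agg`` (AGG -> Met) model
the other reassignments that occur in the surveyed bacteria.  Codon maps are
derived from Biopython's codon tables and keyed by RNA codons.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

__all__ = ["GeneticCode", "get_code", "CODE_LABELS"]


@dataclass(frozen=True)
class GeneticCode:
    label: str
    codon_map: dict  # RNA codon -> one-letter amino acid ('*' for stop)
    stop_codons: frozenset

    def translate_codon(self, codon: str) -> str:
        return self.codon_map[codon.upper().replace("T", "U")]

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("T", "U") in self.stop_codons

    def sense_codons(self) -> list[str]:
        return [c for c in sorted(self.codon_map) if c not in self.stop_codons]


def _from_ncbi(table_id: int) -> tuple[dict, frozenset]:
    t = CodonTable.unambiguous_rna_by_id[table_id]
    cmap = dict(t.forward_table)
    for s in t.stop_codons:
        cmap[s] = "*"
    return cmap, frozenset(t.stop_codons)


def _build() -> dict[str, GeneticCode]:
    std_map, std_stops = _from_ncbi(11)
    codes = {"standard": GeneticCode("standard", std_map, std_stops)}

    trp_map = dict(std_map)
    trp_map["UGA"] = "W"
    codes["trp_uga"] = GeneticCode("trp_uga", trp_map, frozenset({"UAA", "UAG"}))

    gly_map = dict(std_map)
    gly_map["UGA"] = "G"
    codes["gly_uga"] = GeneticCode("gly_uga", gly_map, frozenset({"UAA", "UAG"}))

    met_map = dict(std_map)
    met_map["AGG"] = "M"
    codes["met_agg"] = GeneticCode("met_agg", met_map, std_stops)
    return codes


_CODES = _build()
CODE_LABELS = tuple(_CODES)


def get_code(label: str) -> GeneticCode:
    try:
        return _CODES[label]
    except KeyError:
        raise KeyError(f"unknown genetic code label: {label!r}") from None
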
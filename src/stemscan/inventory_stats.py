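"""Genome-level summaries: species abundance, stop-codon usage, correlations.

A tRNA "species" is an (isotype, anticodon) pair; initiator fMet and elongator
Met count as distinct isotypes when the input labels them so.  Species below
0.1% of all retained tRNAs are "low abundance".  Stop usage is taken from the
terminal codon of each coding sequence, under the genome's genetic code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from stemscan.codes import get_code
from stemscan.trna_struct import ASClassification, TRNARecord, classify, filter_records

__all__ = [
    "ClassifiedTRNA",
    "GenomeBundle",
    "CorrelationResult",
    "build_bundle",
    "species_abundance",
    "fraction_4bp_vs_size",
    "deviant_fraction_vs_abundance",
    "stop_usage",
    "pearson",
    "LOW_ABUNDANCE_PCT",
]

LOW_ABUNDANCE_PCT = 0.1


@dataclass
class ClassifiedTRNA:
    record: TRNARecord
    cls: ASClassification

    @property
    def species(self) -> tuple[str, str]:
        return (self.record.isotype, self.record.anticodon.upper().replace("T", "U"))


@dataclass
class GenomeBundle:
    """Per-genome inventory: classified tRNAs, CDS set, and metadata."""

    genome_id: str
    genome_size: int
    order_label: str
    code_label: str
    trnas: list[ClassifiedTRNA] = field(default_factory=list)
    cds: list[str] = field(default_factory=list)
    excluded: list[tuple[TRNARecord, str]] = field(default_factory=list)


def build_bundle(
    genome_id: str,
    records: Iterable[TRNARecord],
    cds: Sequence[str],
    genome_size: int = 0,
    order_label: str = "",
    code_label: str = "standard",
) -> GenomeBundle:
    """Filter, classify and assemble one genome's inventory."""
    kept, excluded = filter_records(list(records))
    return GenomeBundle(
        genome_id=genome_id,
        genome_size=genome_size,
        order_label=order_label,
        code_label=code_label,
        trnas=[ClassifiedTRNA(r, classify(r)) for r in kept],
        cds=list(cds),
        excluded=excluded,
    )


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided p from the t transform t = r*sqrt(n-2)/sqrt(1-r^2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r, n, 0.0)
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r, n, p)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def species_abundance(trnas: Sequence[ClassifiedTRNA]) -> pd.DataFrame:
    """Per-species counts, percentages and the low/high abundance bin."""
    if not trnas:
        raise ValueError("no tRNA records")
    counts: dict[tuple[str, str], int] = {}
    for t in trnas:
        counts[t.species] = counts.get(t.species, 0) + 1
    total = sum(counts.values())
    rows = [
        {
            "isotype": iso,
            "anticodon": ac,
            "species": f"{iso}-{ac}",
            "count": c,
            "percent_of_total": 100.0 * c / total,
            "bin": "low" if 100.0 * c / total < LOW_ABUNDANCE_PCT else "high",
        }
        for (iso, ac), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def _is_as4(cls: ASClassification) -> bool:
    return cls.as_bin.startswith("AS4")


def fraction_4bp_vs_size(bundles: Sequence[GenomeBundle]) -> CorrelationResult:
    """Correlate each genome's 4-bp AS tRNA gene fraction against genome size."""
    xs, ys = [], []
    for b in bundles:
        if not b.trnas:
            continue
        xs.append(b.genome_size)
        ys.append(sum(_is_as4(t.cls) for t in b.trnas) / len(b.trnas))
    if len(xs) < 3:
        raise ValueError("need >= 3 genomes with at least one retained tRNA")
    return pearson(xs, ys)


def deviant_fraction_vs_abundance(
    trnas: Sequence[ClassifiedTRNA],
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Per-species deviant (non-5-bp) AS fraction against species abundance."""
    ab = species_abundance(trnas)
    deviant: dict[str, int] = {}
    for t in trnas:
        key = f"{t.species[0]}-{t.species[1]}"
        deviant[key] = deviant.get(key, 0) + (t.cls.as_bin != "AS5")
    ab = ab.assign(
        deviant_fraction=[
            deviant.get(s, 0) / c for s, c in zip(ab["species"], ab["count"])
        ]
    )
    if len(ab) < 3:
        raise ValueError("need >= 3 tRNA species")
    corr = pearson(ab["percent_of_total"], ab["deviant_fraction"])
    return corr, ab


def stop_usage(bundle: GenomeBundle) -> dict:
    """Terminal stop-codon usage of a genome's CDS set.

    Counts UAA/UAG/UGA at CDS ends under the genome's code; a CDS whose final
    codon is not a stop under that code is excluded from the denominator with a
    warning.  For a ``trp_uga`` genome UGA is not a stop, so a UGA-terminated
    CDS is itself a warning there.
    """
    if not bundle.cds:
        raise ValueError("no CDS in bundle")
    code = get_code(bundle.code_label)
    counts = {"UAA": 0, "UAG": 0, "UGA": 0}
    warnings = []
    for k, cds in enumerate(bundle.cds):
        c = cds.upper().replace("T", "U")
        if len(c) % 3 != 0:
            warnings.append((k, "length_not_multiple_of_3"))
            continue
        last = c[-3:]
        if not code.is_stop(last):
            warnings.append((k, f"no_terminal_stop:{last}"))
            continue
        counts[last] += 1
    total = sum(counts.values())
    pct = 100.0 * counts["UGA"] / total if total else float("nan")
    return {
        "UAA": counts["UAA"],
        "UAG": counts["UAG"],
        "UGA": counts["UGA"],
        "n_stops": total,
        "pct_UGA": pct,
        "warnings": warnings,
    }
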
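"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its seed (numpy's PCG64 generator, fixed
here as the package's RNG so reruns are bit-identical) and carries planted
ground truth alongside the emitted records, so that recovery tests can compare
what the classifiers report against what was constructed.

The synthetic tRNA is a textbook cloverleaf: 7-bp acceptor stem, 4-bp D-stem,
an anticodon stem of 2-7 structural pairs, a 5-bp T-stem, and a D-loop whose
length is adjusted so the anticodon always starts at sequence position 34.
"Unpinning" is written as a genuine mispair (the lost pair renders as unpaired
dots in the structure string), matching how a structure predictor would display
it: top unpinning substitutes the 5' base of the outermost stem pair (the
C27A-style change, leaving an A:G mispair) and keeps the 7-nt anticodon loop;
bottom unpinning breaks the innermost pair and widens the loop to 9 nt.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from stemscan.trna_struct import TRNARecord, format_ss_block

__all__ = [
    "TRNASpec",
    "GenomeSpec",
    "TRNASim",
    "GenomeSim",
    "make_trna",
    "make_genome",
    "make_orthogroups",
    "orthogroup_fasta",
    "make_replicates",
    "simulate_dataset",
    "DEFAULT_SPECIES_POOL",
]

_BASES = np.array(list("ACGT"))
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_AA3 = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]

# (isotype, anticodon) pool for genomes that do not plant an explicit species
# plan; loosely follows common bacterial isoacceptors.
DEFAULT_SPECIES_POOL = [
    ("Gly", "GCC"), ("Gly", "TCC"), ("Ala", "TGC"), ("Ala", "GGC"),
    ("Lys", "TTT"), ("Lys", "CTT"), ("Asn", "GTT"), ("Met", "CAT"),
    ("fMet", "CAT"), ("Trp", "CCA"), ("Ser", "TGA"), ("Ser", "GCT"),
    ("Leu", "TAA"), ("Leu", "CAA"), ("Thr", "TGT"), ("Thr", "CGT"),
    ("Val", "TAC"), ("Glu", "TTC"), ("Gln", "TTG"), ("Pro", "TGG"),
    ("Arg", "TCT"), ("Arg", "CCT"), ("Phe", "GAA"), ("His", "GTG"),
]


@dataclass
class TRNASpec:
    """Planted structural parameters for one synthetic tRNA.

    ``as_pairs`` counts the structural (rendered) pairs of the anticodon stem
    after any unpinning, so ``unpinned != "none"`` requires ``as_pairs == 4``
    (the nominal stem is 5 pairs and one is broken).
    """

    isotype: str = "Trp"
    anticodon: str = "CCA"
    as_pairs: int = 5
    unpinned: str = "none"  # none | top | bottom
    bulge: str = "none"  # none | five_prime | three_prime
    plant_A9C: bool = False
    plant_G24A: bool = False
    pseudogene: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.as_pairs <= 7:
            raise ValueError("as_pairs must be in 2..7")
        if self.unpinned not in ("none", "top", "bottom"):
            raise ValueError(f"bad unpinned: {self.unpinned}")
        if self.bulge not in ("none", "five_prime", "three_prime"):
            raise ValueError(f"bad bulge: {self.bulge}")
        if self.unpinned != "none" and self.as_pairs != 4:
            raise ValueError("unpinning requires as_pairs == 4")
        if len(self.anticodon) != 3:
            raise ValueError("anticodon must be a triplet")

    def expected_bin(self) -> str:
        """The AS bin this spec must classify to (generator bookkeeping)."""
        span5 = self.as_pairs + (1 if self.bulge == "five_prime" else 0)
        span3 = self.as_pairs + (1 if self.bulge == "three_prime" else 0)
        bin_length = max(span5, span3)
        al = 9 if self.unpinned == "bottom" else 7
        if bin_length == 5:
            return "AS5"
        if bin_length == 4:
            return {7: "AS4_top", 9: "AS4_bottom"}.get(al, "AS4_other")
        return "OTHER"

    def expected_blasto_like(self) -> bool:
        return (
            self.expected_bin() == "AS4_top"
            and not self.plant_A9C
            and not self.plant_G24A
        )


@dataclass
class TRNASim:
    record: TRNARecord
    ss_block: str
    spec: TRNASpec


def _rand_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def make_trna(
    spec: TRNASpec,
    record_id: str = "synth.trna1",
    genome_id: str = "synth",
) -> TRNASim:
    """Build one synthetic tRNA record plus its "-ss" text block.

    The anticodon always starts at position 34; planted A9C/G24A substitutions
    are written at the mapped canonical positions (position 24's D-stem partner
    is adjusted to keep the stem paired).
    """
    rng = np.random.default_rng(spec.seed)
    n_nom = spec.as_pairs + (1 if spec.unpinned != "none" else 0)
    bulge5 = spec.bulge == "five_prime"
    bulge3 = spec.bulge == "three_prime"
    as5_len = n_nom + (1 if bulge5 else 0)
    dloop_len = 13 - as5_len
    if dloop_len < 4:
        raise ValueError("anticodon stem too long for this geometry")

    seq: list[str] = []
    st: list[str] = []

    def emit(bases: list[str], marks: str | list[str]) -> None:
        seq.extend(bases)
        st.extend(marks if isinstance(marks, list) else list(marks))

    # acceptor 5' strand (7 bp)
    acc5 = _rand_bases(rng, 7)
    emit(acc5, ">" * 7)
    # linker: positions 8 and 9
    emit([rng.choice(_BASES)], ".")
    emit(["C" if spec.plant_A9C else "A"], ".")
    # D-stem 5' (4 bp); second nucleotide pairs canonical position 24
    d5 = _rand_bases(rng, 4)
    d5[1] = "T" if spec.plant_G24A else "C"
    emit(d5, ">" * 4)
    # D-loop
    emit(_rand_bases(rng, dloop_len), "." * dloop_len)
    # D-stem 3' strand; reverse-complement of d5 (partner of d5[1] is 3rd from end)
    d3 = [_WC[b] for b in reversed(d5)]
    d3[2] = "A" if spec.plant_G24A else "G"
    emit(d3, "<" * 4)
    # linker before the anticodon stem
    emit([rng.choice(_BASES)], ".")

    # anticodon stem, nominal n_nom pairs, outermost pair fixed C:G
    stem5 = _rand_bases(rng, n_nom)
    stem5[0] = "C"
    stem3 = [_WC[b] for b in reversed(stem5)]  # stem3[-1] pairs stem5[0]
    marks5 = [">"] * n_nom
    marks3 = ["<"] * n_nom
    if spec.unpinned == "top":
        stem5[0] = "A"  # C27A-style substitution -> A:G mispair
        marks5[0] = "."
        marks3[-1] = "."
    elif spec.unpinned == "bottom":
        stem5[-1] = stem3[0]  # same-base mispair, never Watson-Crick
        marks5[-1] = "."
        marks3[0] = "."
    if bulge5 or bulge3:
        # insert the bulge between the two middle *structural* pairs
        paired_idx5 = [k for k in range(n_nom) if marks5[k] == ">"]
        mid = len(paired_idx5) // 2
        if bulge5:
            at = paired_idx5[mid]
            stem5.insert(at, str(rng.choice(_BASES)))
            marks5.insert(at, ".")
        else:
            paired_idx3 = [k for k in range(n_nom) if marks3[k] == "<"]
            at = paired_idx3[len(paired_idx3) // 2]
            stem3.insert(at, str(rng.choice(_BASES)))
            marks3.insert(at, ".")

    emit(stem5, marks5)
    # anticodon loop: 7 nt, anticodon at loop positions 3-5
    ac = spec.anticodon.upper().replace("U", "T")
    loop = _rand_bases(rng, 2) + list(ac) + _rand_bases(rng, 2)
    anticodon_start = len(seq) + 3
    emit(loop, "." * 7)
    emit(stem3, marks3)
    # variable loop
    emit(_rand_bases(rng, 4), "." * 4)
    # T-stem and loop
    t5 = _rand_bases(rng, 5)
    emit(t5, ">" * 5)
    emit(_rand_bases(rng, 7), "." * 7)
    emit([_WC[b] for b in reversed(t5)], "<" * 5)
    # acceptor 3' strand, discriminator + CCA
    emit([_WC[b] for b in reversed(acc5)], "<" * 7)
    emit([rng.choice(_BASES)] + list("CCA"), "....")

    assert anticodon_start == 34, "generator geometry must pin the anticodon at 34"
    record = TRNARecord(
        record_id=record_id,
        genome_id=genome_id,
        isotype=spec.isotype,
        anticodon=spec.anticodon,
        sequence="".join(seq),
        structure="".join(st),
        anticodon_start=anticodon_start,
        pseudogene=spec.pseudogene,
        undetermined=False,
        score=float(np.round(50 + 40 * rng.random(), 1)),
    )
    return TRNASim(record=record, ss_block=format_ss_block(record), spec=spec)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Planted composition of one synthetic genome."""

    genome_id: str = "g1"
    n_trnas: int = 40
    class_mixture: dict = field(
        default_factory=lambda: {"AS5": 0.94, "AS4_top": 0.05, "OTHER": 0.01}
    )
    n_cds: int = 200
    uga_stop_fraction: float = 0.25
    code_label: str = "standard"
    genome_size: int = 4_000_000
    order_label: str = "OrderA"
    internal_uga_rate: float = 0.02  # per-codon, trp_uga genomes only
    species_plan: Optional[list[tuple[str, str, str]]] = None
    # species_plan: explicit (isotype, anticodon, as_bin) triples overriding
    # the random species draw; as_bin in {AS5, AS4_top, AS4_bottom, OTHER}
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if self.code_label == "trp_uga" and self.uga_stop_fraction != 0:
            raise ValueError("trp_uga genomes cannot end CDS with UGA")
        if not 0 <= self.uga_stop_fraction <= 1:
            raise ValueError("uga_stop_fraction must be in [0, 1]")


@dataclass
class GenomeSim:
    spec: GenomeSpec
    trnas: list[TRNASim]
    cds: list[str]
    ss_text: str
    truth: list[dict]

    @property
    def metadata_row(self) -> dict:
        return {
            "genome_id": self.spec.genome_id,
            "size_bp": self.spec.genome_size,
            "order_label": self.spec.order_label,
            "code_label": self.spec.code_label,
        }

    def cds_fasta(self) -> str:
        return "".join(
            f">{self.spec.genome_id}.cds{k + 1}\n{s}\n" for k, s in enumerate(self.cds)
        )


_BIN_TO_SPEC = {
    "AS5": dict(as_pairs=5),
    "AS4_top": dict(as_pairs=4, unpinned="top"),
    "AS4_bottom": dict(as_pairs=4, unpinned="bottom"),
    "AS4_other": dict(as_pairs=4, unpinned="top"),
    "OTHER": None,  # as_pairs drawn from {2, 3, 6, 7}
}

_SENSE_CODONS_STD = None


def _sense_codons(stops: set[str]) -> list[str]:
    return [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in stops
    ]


def make_genome(spec: GenomeSpec) -> GenomeSim:
    """Build a genome bundle's raw inputs with planted tRNA classes and stop usage.

    CDS are random in-frame sequences over the genome's sense codons with the
    terminal stop drawn as UGA with probability ``uga_stop_fraction`` (the rest
    split evenly UAA/UAG).  Under the ``trp_uga`` code, UGA never terminates a
    CDS and internal UGA codons appear at ``internal_uga_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    trnas: list[TRNASim] = []
    truth: list[dict] = []

    if spec.species_plan is not None:
        plan = [(iso, ac, b) for iso, ac, b in spec.species_plan]
    else:
        bins = list(spec.class_mixture)
        probs = np.array([spec.class_mixture[b] for b in bins])
        drawn = rng.choice(len(bins), size=spec.n_trnas, p=probs)
        pool_idx = rng.integers(0, len(DEFAULT_SPECIES_POOL), size=spec.n_trnas)
        plan = [
            (*DEFAULT_SPECIES_POOL[pool_idx[k]], bins[drawn[k]])
            for k in range(spec.n_trnas)
        ]

    for k, (iso, ac, as_bin) in enumerate(plan):
        kw = _BIN_TO_SPEC.get(as_bin)
        if kw is None:
            kw = dict(as_pairs=int(rng.choice([2, 3, 6, 7])))
        tspec = TRNASpec(
            isotype=iso,
            anticodon=ac,
            seed=int(rng.integers(0, 2**31 - 1)),
            **kw,
        )
        sim = make_trna(
            tspec,
            record_id=f"{spec.genome_id}.trna{k + 1}",
            genome_id=spec.genome_id,
        )
        trnas.append(sim)
        truth.append(
            {
                "record_id": sim.record.record_id,
                "genome_id": spec.genome_id,
                "isotype": iso,
                "anticodon": ac.upper().replace("T", "U"),
                "as_bin": tspec.expected_bin(),
                "blasto_like": tspec.expected_blasto_like(),
            }
        )

    if spec.code_label == "trp_uga":
        stops = {"TAA", "TAG"}
    elif spec.code_label == "gly_uga":
        stops = {"TAA", "TAG"}
    else:
        stops = {"TAA", "TAG", "TGA"}
    sense = _sense_codons(stops if spec.code_label == "standard" else {"TAA", "TAG", "TGA"})
    # internal codons avoid all three classic stops so the only planted signal
    # is the terminal stop (trp_uga genomes then re-insert internal UGA below)
    cds_list: list[str] = []
    for _ in range(spec.n_cds):
        n_codons = int(rng.integers(50, 300))
        body_idx = rng.integers(0, len(sense), size=n_codons)
        body = [sense[i] for i in body_idx]
        if spec.code_label in ("trp_uga", "gly_uga") and spec.internal_uga_rate > 0:
            hits = np.nonzero(rng.random(n_codons) < spec.internal_uga_rate)[0]
            for h in hits:
                body[h] = "TGA"
        if rng.random() < spec.uga_stop_fraction:
            stop = "TGA"
        else:
            stop = "TAA" if rng.random() < 0.5 else "TAG"
        if spec.code_label in ("trp_uga", "gly_uga") and stop == "TGA":
            stop = "TAA"
        cds_list.append("".join(body) + stop)

    ss_text = "".join(sim.ss_block for sim in trnas)
    return GenomeSim(spec=spec, trnas=trnas, cds=cds_list, ss_text=ss_text, truth=truth)


# ---------------------------------------------------------------------------
# Orthogroups and replicate tables
# ---------------------------------------------------------------------------

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def make_orthogroups(
    n_families: int,
    n_members: int,
    extension_plan: Optional[dict[int, int]] = None,
    seed: int = 0,
    length: int = 120,
    sub_rate: float = 0.05,
    conserved_tail: int = 5,
    tail_gap_plan: Optional[set[int]] = None,
) -> list[dict]:
    """Protein families from a common ancestor with conserved C-termini.

    ``n_members`` standard-code members are derived by per-site substitution
    (never within the last ``conserved_tail`` residues); one extra member is
    labelled ``trp_uga`` and, for families in ``extension_plan``, carries a
    planted C-terminal extension of the stated length (a W followed by random
    residues, emulating translation through a genuine UGA stop to a downstream
    UAA/UAG).  Families in ``tail_gap_plan`` instead get one standard member
    truncated by one residue, planting a gap in the final alignment columns.
    """
    if n_members < 2:
        raise ValueError("need at least two standard-code members per family")
    extension_plan = extension_plan or {}
    tail_gap_plan = tail_gap_plan or set()
    rng = np.random.default_rng(seed)
    families = []
    for f in range(n_families):
        ancestor = rng.choice(_AA20, size=length)
        members = []
        for m in range(n_members):
            prot = ancestor.copy()
            mutable = length - conserved_tail
            hits = np.nonzero(rng.random(mutable) < sub_rate)[0]
            for h in hits:
                prot[h] = rng.choice(_AA20)
            s = "".join(prot)
            if f in tail_gap_plan and m == 0:
                s = s[:-1]
            members.append((f"fam{f}_std{m}", "standard", s))
        target = ancestor.copy()
        hits = np.nonzero(rng.random(length - conserved_tail) < sub_rate)[0]
        for h in hits:
            target[h] = rng.choice(_AA20)
        ext_len = int(extension_plan.get(f, 0))
        ext = ""
        if ext_len:
            ext = "W" + "".join(rng.choice(_AA20, size=ext_len - 1))
        members.append((f"fam{f}_reassigned", "trp_uga", "".join(target) + ext))
        families.append(
            {
                "family_id": f"fam{f}",
                "members": members,
                "planted_extension": ext_len,
                "planted_tail_gap": f in tail_gap_plan,
            }
        )
    return families


def orthogroup_fasta(family: dict) -> str:
    return "".join(
        f">{name} code={code}\n{seq}\n" for name, code, seq in family["members"]
    )


def simulate_dataset(
    outdir,
    seed: int = 0,
    n_as4_genomes: int = 10,
    n_as5_genomes: int = 5,
    n_mixed_genomes: int = 3,
    n_trp_uga_genomes: int = 1,
    n_cds: int = 60,
    n_extra_species: int = 18,
    uga_mean_as4: float = 0.15,
    uga_mean_as5: float = 0.45,
    n_orthogroup_families: int = 5,
    orthogroup_members: int = 4,
    extension_plan: Optional[dict[int, int]] = None,
) -> dict:
    """Write a complete fixture directory consumable by the full pipeline.

    One order gets ``n_as4_genomes`` genomes whose only Trp-CCA is the
    top-unpinned 4-bp variant (with lower planted UGA stop usage) and
    ``n_as5_genomes`` genomes with only the 5-bp variant (higher UGA usage);
    mixed genomes carry both variants (feeding the identity-cohort
    comparison); trp_uga genomes carry a suppressor tRNA(UCA), no UGA CDS
    ends, and codon-inference metadata supporting the reassignment.
    Truth tables (planted per-tRNA classes and per-genome stop fractions) are
    written alongside.
    """
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    meta_rows = []
    truth_trnas = []
    truth_genomes = []

    def extra_species(rng: np.random.Generator) -> list[tuple[str, str, str]]:
        idx = rng.integers(0, len(DEFAULT_SPECIES_POOL), size=n_extra_species)
        out = []
        for i in idx:
            iso, ac = DEFAULT_SPECIES_POOL[int(i)]
            if (iso, ac) == ("Trp", "CCA"):
                iso, ac = "Gly", "GCC"
            as_bin = "AS4_top" if rng.random() < 0.08 else "AS5"
            out.append((iso, ac, as_bin))
        return out

    def emit(gspec: GenomeSpec, rf2=None, codetta=0) -> None:
        sim = make_genome(gspec)
        (outdir / f"{gspec.genome_id}.ss").write_text(sim.ss_text)
        (outdir / f"{gspec.genome_id}_cds.fasta").write_text(sim.cds_fasta())
        row = dict(sim.metadata_row)
        row["rf2_present"] = "" if rf2 is None else rf2
        row["codetta_support_columns"] = codetta
        meta_rows.append(row)
        truth_trnas.extend(sim.truth)
        truth_genomes.append(
            {
                "genome_id": gspec.genome_id,
                "uga_stop_fraction": gspec.uga_stop_fraction,
                "code_label": gspec.code_label,
                "order_label": gspec.order_label,
            }
        )

    gid = 0

    def next_id() -> str:
        nonlocal gid
        gid += 1
        return f"g{gid:03d}"

    for _ in range(n_as4_genomes):
        frac = float(np.clip(uga_mean_as4 + 0.05 * rng.standard_normal(), 0.01, 0.95))
        emit(
            GenomeSpec(
                genome_id=next_id(),
                species_plan=[("Trp", "CCA", "AS4_top")] + extra_species(rng),
                n_cds=n_cds,
                uga_stop_fraction=frac,
                order_label="OrderA",
                genome_size=int(rng.integers(1_500_000, 6_000_000)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    for _ in range(n_as5_genomes):
        frac = float(np.clip(uga_mean_as5 + 0.05 * rng.standard_normal(), 0.01, 0.95))
        emit(
            GenomeSpec(
                genome_id=next_id(),
                species_plan=[("Trp", "CCA", "AS5")] + extra_species(rng),
                n_cds=n_cds,
                uga_stop_fraction=frac,
                order_label="OrderA",
                genome_size=int(rng.integers(1_500_000, 6_000_000)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    for _ in range(n_mixed_genomes):
        emit(
            GenomeSpec(
                genome_id=next_id(),
                species_plan=[
                    ("Trp", "CCA", "AS4_top"),
                    ("Trp", "CCA", "AS5"),
                ]
                + extra_species(rng),
                n_cds=n_cds,
                uga_stop_fraction=float(rng.uniform(0.1, 0.6)),
                order_label="OrderB",
                genome_size=int(rng.integers(1_500_000, 6_000_000)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    for _ in range(n_trp_uga_genomes):
        emit(
            GenomeSpec(
                genome_id=next_id(),
                species_plan=[("Trp", "CCA", "AS4_top"), ("Sup", "TCA", "AS5")]
                + extra_species(rng),
                n_cds=n_cds,
                uga_stop_fraction=0.0,
                code_label="trp_uga",
                order_label="OrderC",
                genome_size=int(rng.integers(200_000, 1_500_000)),
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
            rf2=False,
            codetta=150,
        )

    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(truth_trnas).to_csv(outdir / "truth_trnas.tsv", sep="\t", index=False)
    pd.DataFrame(truth_genomes).to_csv(
        outdir / "truth_genomes.tsv", sep="\t", index=False
    )

    og_dir = outdir / "orthogroups"
    og_dir.mkdir(exist_ok=True)
    families = make_orthogroups(
        n_orthogroup_families,
        orthogroup_members,
        extension_plan=extension_plan,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    for fam in families:
        (og_dir / f"{fam['family_id']}.fasta").write_text(orthogroup_fasta(fam))
    pd.DataFrame(
        [
            {"family_id": f["family_id"], "planted_extension": f["planted_extension"]}
            for f in families
        ]
    ).to_csv(outdir / "truth_orthogroups.tsv", sep="\t", index=False)
    return {
        "n_genomes": len(meta_rows),
        "outdir": str(outdir),
        "n_families": len(families),
    }


def make_replicates(
    group_means: list[float], sd: float, n_per_group: int, seed: int = 0
):
    """Normal replicate draws per group (western-blot-style quantification table)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in enumerate(group_means):
        vals = mu + sd * rng.standard_normal(n_per_group)
        for v in vals:
            rows.append({"group": f"group{g + 1}", "value": float(v)})
    return pd.DataFrame(rows)
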
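"""End-to-end orchestration: configuration, fixture IO, and the cohort analyses.

The on-disk layout a run consumes (and ``simulate`` writes):

    input_dir/
      metadata.tsv              genome_id, size_bp, order_label, code_label,
                                [rf2_present, codetta_support_columns]
      <genome_id>.ss            tRNA blocks in the "-ss" dialect
      <genome_id>_cds.fasta     one nucleotide record per CDS
      orthogroups/fam*.fasta    protein families, headers tagged code=...

Outputs are machine-readable TSVs (logging goes to standard error); reruns on
identical inputs, configuration and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from stemscan import __version__
from stemscan.codes import get_code
from stemscan.hypothesis_stats import (
    gated_compare,
    identity_cohorts,
    proportion_z_test,
    test_result_row,
)
from stemscan.inventory_stats import (
    ClassifiedTRNA,
    GenomeBundle,
    build_bundle,
    species_abundance,
    stop_usage,
)
from stemscan.reassignment import (
    center_star_msa,
    conserved_cterm_filter,
    cterm_extension,
    parse_orthogroup_fasta,
    summarize_evidence,
    target_truncation,
)
from stemscan.superwobble import coverage, decoding_model
from stemscan.trna_struct import (
    CLASSIFICATION_COLUMNS,
    classification_row,
    classify,
    filter_records,
    parse_ss_records,
)

__all__ = [
    "RunConfig",
    "load_bundles",
    "run_classify",
    "run_cooccurrence",
    "run_uga_compare",
    "run_identity_cohorts",
    "run_reassign_validate",
    "run_decode",
    "run_all",
    "COOCCURRENCE_PAIRS",
]


@dataclass
class RunConfig:
    input_dir: str = "."
    output_dir: str = "out"
    abundance_threshold_pct: float = 0.1
    alpha: float = 0.05
    conserved_cterm_k: int = 5
    codetta_min_support: int = 100
    min_genomes_per_order: int = 10
    align_match: int = 1
    align_mismatch: int = -1
    align_gap: int = -2
    decoding_model: str = "extended"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "abundance_threshold_pct",
            "alpha",
            "conserved_cterm_k",
            "codetta_min_support",
            "min_genomes_per_order",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _log(msg: str) -> None:
    print(f"[stemscan] {msg}", file=sys.stderr)


# ---------------------------------------------------------------------------
# Fixture IO
# ---------------------------------------------------------------------------


def _read_fasta(path: Path) -> list[str]:
    seqs: list[str] = []
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if chunks:
                    seqs.append("".join(chunks))
                chunks = []
            elif line.strip():
                chunks.append(line.strip())
    if chunks:
        seqs.append("".join(chunks))
    return seqs


def load_bundles(input_dir: str | Path) -> tuple[list[GenomeBundle], pd.DataFrame]:
    """Load every genome listed in ``metadata.tsv`` into classified bundles."""
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.tsv in {input_dir}")
    meta = pd.read_csv(meta_path, sep="\t")
    bundles: list[GenomeBundle] = []
    for _, row in meta.iterrows():
        gid = str(row["genome_id"])
        ss_path = input_dir / f"{gid}.ss"
        cds_path = input_dir / f"{gid}_cds.fasta"
        records = []
        if ss_path.exists():
            parsed = parse_ss_records(ss_path.read_text())
            for err in parsed.errors:
                _log(f"{gid}: parse error in {err.record_id}: {err.message}")
            records = parsed.records
        cds = _read_fasta(cds_path) if cds_path.exists() else []
        bundles.append(
            build_bundle(
                gid,
                records,
                cds,
                genome_size=int(row.get("size_bp", 0)),
                order_label=str(row.get("order_label", "")),
                code_label=str(row.get("code_label", "standard")),
            )
        )
    return bundles, meta


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_classify(bundles: Sequence[GenomeBundle]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classification TSV (one row per retained tRNA) and exclusions TSV."""
    rows = []
    excl = []
    for b in bundles:
        for t in b.trnas:
            rows.append(classification_row(t.record, t.cls))
        for rec, reason in b.excluded:
            excl.append(classification_row(rec, None, exclusion_reason=reason))
    cls_df = pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)
    excl_df = pd.DataFrame(excl, columns=CLASSIFICATION_COLUMNS)
    return (
        cls_df.sort_values(["genome_id", "record_id"]).reset_index(drop=True),
        excl_df.sort_values(["genome_id", "record_id"]).reset_index(drop=True),
    )


def run_summarize(bundles: Sequence[GenomeBundle]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome summary TSV and pooled per-species abundance TSV."""
    rows = []
    for b in bundles:
        n = len(b.trnas)
        n4 = sum(t.cls.as_bin.startswith("AS4") for t in b.trnas)
        usage = stop_usage(b) if b.cds else {
            "UAA": 0, "UAG": 0, "UGA": 0, "n_stops": 0, "pct_UGA": float("nan"),
            "warnings": [],
        }
        rows.append(
            {
                "genome_id": b.genome_id,
                "order_label": b.order_label,
                "code_label": b.code_label,
                "size_bp": b.genome_size,
                "n_trnas": n,
                "n_as4": n4,
                "frac_as4": round(n4 / n, 4) if n else "",
                "n_blasto_like_trp": sum(
                    t.cls.blasto_like
                    and t.record.isotype == "Trp"
                    and t.record.anticodon.upper().replace("T", "U") == "CCA"
                    for t in b.trnas
                ),
                "UAA": usage["UAA"],
                "UAG": usage["UAG"],
                "UGA": usage["UGA"],
                "pct_UGA": round(usage["pct_UGA"], 1)
                if usage["n_stops"]
                else "",
            }
        )
    genome_df = pd.DataFrame(rows).sort_values("genome_id").reset_index(drop=True)
    pooled = [t for b in bundles for t in b.trnas]
    ab_df = species_abundance(pooled) if pooled else pd.DataFrame()
    if not ab_df.empty:
        ab_df["percent_of_total"] = ab_df["percent_of_total"].round(1)
    return genome_df, ab_df


# (C-anticodon, U-anticodon) isoacceptor pairs for the 11 amino acids encoded
# by both NNA and NNG codons, derived from the standard code; the Arg CCG/UCG
# pair is excluded because CGA is generally read by an edited I34 tRNA.
def _cooccurrence_pairs() -> list[tuple[str, str, str, str, str]]:
    code = get_code("standard")
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}

    def anticodon(codon: str) -> str:
        return "".join(comp[b] for b in reversed(codon))

    out = []
    for stem in sorted({c[:2] for c in code.sense_codons()}):
        ca, cg = stem + "A", stem + "G"
        if ca in code.stop_codons or cg in code.stop_codons:
            continue
        if code.codon_map.get(ca) != code.codon_map.get(cg):
            continue
        ac_c, ac_u = anticodon(cg), anticodon(ca)
        if (ac_c, ac_u) == ("CCG", "UCG"):
            continue
        aa3 = {v: k for k, v in {
            "Ala": "A", "Arg": "R", "Gln": "Q", "Glu": "E", "Gly": "G",
            "Leu": "L", "Lys": "K", "Pro": "P", "Ser": "S", "Thr": "T",
            "Val": "V",
        }.items()}.get(code.codon_map[ca])
        if aa3 is None:
            continue
        out.append((aa3, stem, ca, cg, ac_c + "/" + ac_u))
    return [(aa, ac_pair.split("/")[0], ac_pair.split("/")[1], ca, cg)
            for aa, stem, ca, cg, ac_pair in out]


COOCCURRENCE_PAIRS = _cooccurrence_pairs()


def _has_anticodon(b: GenomeBundle, anticodon: str, isotype: Optional[str] = None):
    hits = [
        t
        for t in b.trnas
        if t.record.anticodon.upper().replace("T", "U") == anticodon
        and (isotype is None or t.record.isotype == isotype)
    ]
    return hits


def run_cooccurrence(bundles: Sequence[GenomeBundle]) -> pd.DataFrame:
    """Per-isoacceptor-pair proportion tests for the extended-superwobble prediction.

    For each (C-anticodon, U-anticodon) pair, among genomes carrying at least
    one tRNA with the C anticodon (and whose code gives NNA and NNG the same
    meaning), compare the fraction possessing the U isoacceptor between
    genomes whose C-anticodon tRNA set includes a 4-bp AS variant and genomes
    with only 5-bp AS variants.
    """
    rows = []
    for aa, ac_c, ac_u, codon_a, codon_g in COOCCURRENCE_PAIRS:
        n4 = k4 = n5 = k5 = 0
        for b in bundles:
            code = get_code(b.code_label)
            if code.is_stop(codon_a) or code.is_stop(codon_g):
                continue
            if code.codon_map[codon_a] != code.codon_map[codon_g]:
                continue
            cs = _has_anticodon(b, ac_c, isotype=aa)
            if not cs:
                continue
            has_u = bool(_has_anticodon(b, ac_u, isotype=aa))
            if any(t.cls.as_bin.startswith("AS4") for t in cs):
                n4 += 1
                k4 += has_u
            elif all(t.cls.as_bin == "AS5" for t in cs):
                n5 += 1
                k5 += has_u
        row = {
            "amino_acid": aa,
            "anticodon_C": ac_c,
            "anticodon_U": ac_u,
            "n_genomes_as4": n4,
            "k_with_U_as4": k4,
            "n_genomes_as5": n5,
            "k_with_U_as5": k5,
        }
        if n4 == 0 or n5 == 0:
            row.update(z="", p_value="", skipped="empty_stratum")
        else:
            try:
                res = proportion_z_test(k4, n4, k5, n5)
                row.update(
                    z=round(res.statistic, 4), p_value=res.p_value, skipped=""
                )
            except ValueError as exc:
                row.update(z="", p_value="", skipped=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def _trp_cca_stratum(b: GenomeBundle) -> str:
    trp = _has_anticodon(b, "CCA", isotype="Trp")
    if not trp:
        return "none"
    has4 = any(t.cls.as_bin.startswith("AS4") for t in trp)
    has5 = any(t.cls.as_bin == "AS5" for t in trp)
    if has4 and not has5:
        return "as4_only"
    if has5 and not has4:
        return "as5_only"
    if has4 and has5:
        return "mixed"
    return "other"


def run_uga_compare(
    bundles: Sequence[GenomeBundle],
    min_genomes: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-order UGA stop-usage comparison between tRNA-Trp(CCA) AS strata.

    Orders with at least ``min_genomes`` genomes carrying exclusively 4-bp AS
    Trp-CCA are compared against same-order genomes carrying only the 5-bp
    variant with the normality-gated two-group test; genomes with both
    variants are excluded from both strata.
    """
    per_order: dict[str, dict[str, list[float]]] = {}
    for b in bundles:
        stratum = _trp_cca_stratum(b)
        if stratum not in ("as4_only", "as5_only") or not b.cds:
            continue
        pct = stop_usage(b)["pct_UGA"]
        per_order.setdefault(b.order_label, {"as4_only": [], "as5_only": []})[
            stratum
        ].append(pct)

    rows = []
    for order in sorted(per_order):
        g4 = per_order[order]["as4_only"]
        g5 = per_order[order]["as5_only"]
        row = {"order_label": order, "n_as4": len(g4), "n_as5": len(g5)}
        if len(g4) < min_genomes:
            row.update(method="", p_value="", direction="", significant="",
                       skipped=f"fewer_than_{min_genomes}_as4_genomes")
        elif len(g5) < 3:
            row.update(method="", p_value="", direction="", significant="",
                       skipped="fewer_than_3_as5_genomes")
        else:
            res = gated_compare(g4, g5, alpha=alpha)
            import numpy as np

            direction = "lower" if np.median(g4) < np.median(g5) else "higher"
            row.update(
                method=res.method,
                p_value=res.p_value,
                direction=direction,
                significant=bool(res.p_value < alpha),
                skipped="",
            )
        rows.append(row)
    if not rows:
        _log("uga-compare: no qualifying order")
    return pd.DataFrame(rows)


def run_identity_cohorts(
    bundles: Sequence[GenomeBundle], **align_kwargs
) -> Optional[dict]:
    """Pairwise-identity comparison of 4- vs 5-bp AS Trp-CCA gene cohorts,
    restricted to genomes encoding both variants."""
    set4: list[str] = []
    set5: list[str] = []
    for b in bundles:
        if _trp_cca_stratum(b) != "mixed":
            continue
        for t in _has_anticodon(b, "CCA", isotype="Trp"):
            if t.cls.as_bin.startswith("AS4"):
                set4.append(t.record.rna_sequence())
            elif t.cls.as_bin == "AS5":
                set5.append(t.record.rna_sequence())
    if len(set4) < 2 or len(set5) < 2:
        _log("identity-cohorts: not enough co-occurring variants")
        return None
    return identity_cohorts(set4, set5, **align_kwargs)


def run_reassign_validate(
    bundles: Sequence[GenomeBundle],
    orthogroup_dir: Optional[str | Path],
    meta: Optional[pd.DataFrame] = None,
    k: int = 5,
    min_support: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family extension TSV and per-genome evidence summary TSV."""
    fam_rows = []
    extensions: list[int] = []
    truncations: list[int] = []
    if orthogroup_dir is not None:
        for path in sorted(Path(orthogroup_dir).glob("*.fasta")):
            proteins = parse_orthogroup_fasta(path.read_text())
            std = [p for p in proteins if p[1] == "standard"]
            tgt = [p for p in proteins if p[1] != "standard"]
            if len(std) < 2 or len(tgt) != 1:
                fam_rows.append(
                    {"family_id": path.stem, "filter_pass": "",
                     "extension_length": "", "skipped": "needs >=2 standard + 1 target"}
                )
                continue
            std_aln = center_star_msa(std)
            if not conserved_cterm_filter(std_aln, k=k):
                fam_rows.append(
                    {"family_id": path.stem, "filter_pass": False,
                     "extension_length": "", "skipped": ""}
                )
                continue
            full = center_star_msa(std + tgt)
            ext = cterm_extension(full)
            trunc = target_truncation(full)
            extensions.append(ext)
            truncations.append(trunc)
            fam_rows.append(
                {"family_id": path.stem, "filter_pass": True,
                 "extension_length": ext, "skipped": ""}
            )
    fam_df = pd.DataFrame(
        fam_rows, columns=["family_id", "filter_pass", "extension_length", "skipped"]
    )

    flags: dict[str, dict] = {}
    if meta is not None:
        for _, row in meta.iterrows():
            flags[str(row["genome_id"])] = {
                "rf2_present": bool(row["rf2_present"])
                if "rf2_present" in row and pd.notna(row["rf2_present"])
                else None,
                "codetta_support_columns": int(row["codetta_support_columns"])
                if "codetta_support_columns" in row
                and pd.notna(row["codetta_support_columns"])
                else 0,
            }
    ev_rows = []
    for b in bundles:
        if b.code_label != "trp_uga" or not b.cds:
            continue
        f = flags.get(b.genome_id, {})
        summary = summarize_evidence(
            b,
            extension_lengths=extensions,
            truncation_lengths=truncations,
            rf2_present=f.get("rf2_present"),
            codetta_support_columns=f.get("codetta_support_columns", 0),
            min_support_columns=min_support,
        )
        ev_rows.append(
            {
                "genome_id": summary.genome_id,
                "suppressor_uca_present": summary.suppressor_uca_present,
                "rf2_present": "" if summary.rf2_present is None
                else summary.rf2_present,
                "pct_uga_at_cds_ends": round(summary.pct_uga_at_cds_ends, 1),
                "n_cterm_extensions": summary.n_cterm_extensions,
                "codetta_support_columns": summary.codetta_support_columns,
                "verdict": summary.verdict,
                "reasons": ";".join(summary.reasons),
            }
        )
    return fam_df, pd.DataFrame(ev_rows)


def run_decode(
    bundles: Sequence[GenomeBundle], model_label: str = "extended"
) -> pd.DataFrame:
    """Per-genome codon coverage TSV under the requested decoding model."""
    model = decoding_model(model_label)
    rows = []
    for b in bundles:
        code = get_code(b.code_label)
        report = coverage(
            (
                (t.record.record_id, t.record.isotype,
                 t.record.anticodon, t.cls.as_bin)
                for t in b.trnas
            ),
            model,
            code,
        )
        for codon in sorted(code.codon_map):
            if codon in code.stop_codons:
                ids = sorted(report.stop_readthrough.get(codon, ()))
                rows.append(
                    {
                        "genome_id": b.genome_id, "codon": codon,
                        "amino_acid": "*", "covering_trnas": ",".join(ids),
                        "flags": "stop_readthrough" if ids else "",
                    }
                )
            else:
                ids = sorted(report.decoded.get(codon, ()))
                flags = []
                if codon in report.uncovered_sense:
                    flags.append("uncovered")
                if codon in report.misread:
                    flags.append("misread")
                rows.append(
                    {
                        "genome_id": b.genome_id, "codon": codon,
                        "amino_acid": code.codon_map[codon],
                        "covering_trnas": ",".join(ids),
                        "flags": ";".join(flags),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_all(config: RunConfig) -> Path:
    """Execute every stage on an input directory; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles, meta = load_bundles(config.input_dir)
    if not bundles:
        raise ValueError(f"no genomes found under {config.input_dir}")

    cls_df, excl_df = run_classify(bundles)
    _write(cls_df, out / "classification.tsv")
    _write(excl_df, out / "excluded.tsv")

    genome_df, ab_df = run_summarize(bundles)
    _write(genome_df, out / "genomes.tsv")
    _write(ab_df, out / "species_abundance.tsv")

    _write(run_cooccurrence(bundles), out / "cooccurrence.tsv")
    _write(
        run_uga_compare(
            bundles, min_genomes=config.min_genomes_per_order, alpha=config.alpha
        ),
        out / "uga_compare.tsv",
    )

    ident = run_identity_cohorts(
        bundles,
        match=config.align_match,
        mismatch=config.align_mismatch,
        gap=config.align_gap,
    )
    if ident is not None:
        _write(
            pd.DataFrame(
                [
                    {
                        "median_identity_as4": round(ident["median4"], 1),
                        "median_identity_as5": round(ident["median5"], 1),
                        "n_pairs_as4": len(ident["identities4"]),
                        "n_pairs_as5": len(ident["identities5"]),
                        **test_result_row(ident["t_test"]),
                        "cohens_d": round(ident["d"], 4),
                    }
                ]
            ),
            out / "identity_cohorts.tsv",
        )

    og_dir = Path(config.input_dir) / "orthogroups"
    fam_df, ev_df = run_reassign_validate(
        bundles,
        og_dir if og_dir.exists() else None,
        meta,
        k=config.conserved_cterm_k,
        min_support=config.codetta_min_support,
    )
    _write(fam_df, out / "orthogroup_extensions.tsv")
    _write(ev_df, out / "reassignment_evidence.tsv")

    _write(run_decode(bundles, config.decoding_model), out / "decoding_coverage.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_genomes": len(bundles),
        "config": asdict(config),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _log(f"run-all complete: {len(bundles)} genomes -> {out}")
    return out
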
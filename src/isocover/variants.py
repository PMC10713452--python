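"""SAP calling from read pileups, variant-proteome construction, peptide
classification against reference + mutated proteomes, and the
deleteriousness-shift test.

Pileup tables are VCF-like TSVs with columns CHROM, POS (1-based), REF,
ALT, DEPTH, ALT_COUNT, BASEQ, MAPQ, MULTIMAPPED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, CODON_TABLE, revcomp, translate

__all__ = [
    "FilterThresholds",
    "filter_variants",
    "variant_pass_mask",
    "VariantConsequence",
    "build_variant_proteome",
    "classify_sap_peptides",
    "sap_detection_summary",
    "RankSumResult",
    "deleteriousness_shift",
    "score_category_fractions",
    "SIFT_BINS",
    "POLYPHEN_BINS",
]

PILEUP_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "DEPTH", "ALT_COUNT", "BASEQ", "MAPQ",
    "MULTIMAPPED",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class FilterThresholds:
    """Pass criteria for a pileup row; all bounds are inclusive."""

    min_depth: int = 10
    min_alt: int = 5
    min_freq: float = 0.15
    min_baseq: float = 13.0
    min_mapq: float = 13.0


def variant_pass_mask(
    pileup: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> pd.Series:
    """Boolean pass flag per row; raises on malformed rows with the index."""
    missing = [c for c in PILEUP_COLUMNS if c not in pileup.columns]
    if missing:
        raise ValueError(f"pileup table missing columns: {missing}")
    for idx, row in pileup.iterrows():
        if pd.isna(row["DEPTH"]) or pd.isna(row["ALT_COUNT"]):
            raise ValueError(f"malformed pileup row {idx}: missing depth fields")
        if row["ALT_COUNT"] > row["DEPTH"]:
            raise ValueError(
                f"malformed pileup row {idx}: ALT_COUNT > DEPTH"
            )
    t = thresholds
    depth = pileup["DEPTH"].astype(float)
    alt = pileup["ALT_COUNT"].astype(float)
    freq = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    mask = (
        (depth >= t.min_depth)
        & (alt >= t.min_alt)
        & (freq >= t.min_freq)
        & (pileup["BASEQ"] >= t.min_baseq)
        & (pileup["MAPQ"] >= t.min_mapq)
        & (~pileup["MULTIMAPPED"].astype(bool))
    )
    return pd.Series(mask, index=pileup.index, name="pass")


def filter_variants(
    pileup: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> pd.DataFrame:
    """Rows passing the depth/alt/frequency/quality/multimap cascade."""
    return pileup[variant_pass_mask(pileup, thresholds)].copy()


@dataclass(frozen=True)
class VariantConsequence:
    entry_id: str
    transcript_id: str
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    aa_pos: int  # 1-based
    ref_aa: str
    alt_aa: str

    @property
    def name(self) -> str:
        return f"{self.ref_aa}{self.aa_pos}{self.alt_aa}"


def build_variant_proteome(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    calls: pd.DataFrame,
) -> tuple[dict[str, str], dict[str, str], list[VariantConsequence]]:
    """Apply passing calls to every overlapping isoform CDS.

    Returns (mutated entries, FASTA descriptions, consequences).  One
    variant per entry; synonymous changes yield no entry; calls outside any
    CDS are recorded as non-coding (returned consequence list excludes
    them, they are counted on the ``noncoding`` attribute of the frame).
    Minus-strand genes are handled through the reverse complement.
    """
    entries: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    consequences: list[VariantConsequence] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for _, row in calls.iterrows():
        chrom, pos = row["CHROM"], int(row["POS"])
        ref, alt = str(row["REF"]).upper(), str(row["ALT"]).upper()
        for gene in by_chrom.get(chrom, []):
            lo, hi = gene.span()
            if not (lo <= pos <= hi):
                continue
            for tid in gene.isoforms:
                cds_idx = gene.genomic_to_cds(tid, pos)
                if cds_idx is None:
                    continue
                cds = gene.transcript_sequence(tid, genome)
                ref_cds = ref if gene.strand == "+" else _COMPLEMENT[ref]
                alt_cds = alt if gene.strand == "+" else _COMPLEMENT[alt]
                if cds[cds_idx].upper() != ref_cds:
                    raise ValueError(
                        f"REF mismatch at {chrom}:{pos} for {tid}: "
                        f"expected {ref_cds}, CDS has {cds[cds_idx]}"
                    )
                codon_idx = cds_idx // 3
                offset = cds_idx % 3
                codon_start = codon_idx * 3
                codon = cds[codon_start : codon_start + 3].upper()
                if len(codon) < 3:
                    continue  # partial trailing codon, not translated
                new_codon = codon[:offset] + alt_cds + codon[offset + 1 :]
                ref_aa = CODON_TABLE[codon]
                alt_aa = CODON_TABLE[new_codon]
                if ref_aa == alt_aa:
                    continue  # synonymous
                protein = translate(cds)
                if codon_idx >= len(protein):
                    continue
                name = f"{ref_aa}{codon_idx + 1}{alt_aa}"
                entry_id = f"{tid}|{name}"
                mutated = (
                    protein[:codon_idx]
                    + (alt_aa if alt_aa != "*" else "")
                    + (protein[codon_idx + 1 :] if alt_aa != "*" else "")
                )
                if alt_aa == "*":
                    continue  # stop gain: no substituted-residue entry
                entries[entry_id] = mutated
                descriptions[entry_id] = f"VAR={name}"
                consequences.append(
                    VariantConsequence(
                        entry_id, tid, gene.gene_id, chrom, pos, ref, alt,
                        codon_idx + 1, ref_aa, alt_aa,
                    )
                )
    return entries, descriptions, consequences


def classify_sap_peptides(
    evidence: pd.DataFrame,
    reference_proteome: Mapping[str, str],
    variant_entries: Mapping[str, str],
    consequences: Sequence[VariantConsequence],
) -> pd.DataFrame:
    """Per unique peptide: Mutated status No / Yes / Mixed.

    A peptide provides mutated evidence only when an occurrence in a
    variant entry covers the substituted residue (occurrences elsewhere in
    the entry are indistinguishable from reference sequence).  Status is
    Yes when only mutated evidence exists, Mixed when both mutated and
    reference matches exist, No otherwise.
    """
    cons_by_entry: dict[str, VariantConsequence] = {c.entry_id: c for c in consequences}
    ref_values = list(reference_proteome.values())
    rows = []
    for seq in pd.unique(evidence["sequence"]):
        in_ref = any(seq in prot for prot in ref_values)
        mutated_hits: list[str] = []
        for entry_id, c in cons_by_entry.items():
            entry_seq = variant_entries[entry_id]
            start = entry_seq.find(seq)
            while start != -1:
                if start < c.aa_pos <= start + len(seq):  # aa_pos is 1-based
                    mutated_hits.append(c.entry_id)
                    break
                start = entry_seq.find(seq, start + 1)
        if mutated_hits and in_ref:
            status = "Mixed"
        elif mutated_hits:
            status = "Yes"
        else:
            status = "No"
        rows.append(
            {
                "sequence": seq,
                "mutated": status,
                "mutation_names": ";".join(
                    sorted(cons_by_entry[e].name for e in mutated_hits)
                ),
                "entries": ";".join(sorted(mutated_hits)),
            }
        )
    return pd.DataFrame(rows)


def sap_detection_summary(
    classified: pd.DataFrame, consequences: Sequence[VariantConsequence]
) -> pd.DataFrame:
    """Per SAP: proteomics-detected iff a status-Yes peptide covers it."""
    detected_entries: set[str] = set()
    yes = classified[classified["mutated"] == "Yes"]
    for entries in yes["entries"]:
        detected_entries.update(e for e in entries.split(";") if e)
    return pd.DataFrame(
        {
            "entry_id": [c.entry_id for c in consequences],
            "gene_id": [c.gene_id for c in consequences],
            "site": [f"{c.chrom}:{c.pos}" for c in consequences],
            "consequence": [c.name for c in consequences],
            "proteome_detected": [
                c.entry_id in detected_entries for c in consequences
            ],
        }
    )


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample
    u_statistic: float
    p_value: float
    fractions_first: dict[str, float] = field(default_factory=dict)
    fractions_second: dict[str, float] = field(default_factory=dict)


SIFT_BINS: dict[str, tuple[float, float]] = {
    "deleterious": (0.0, 0.05),
    "tolerated": (0.05, 1.0 + 1e-12),
}

POLYPHEN_BINS: dict[str, tuple[float, float]] = {
    "benign": (0.0, 0.446),
    "possibly damaging": (0.446, 0.908),
    "probably damaging": (0.908, 1.0 + 1e-12),
}


def score_category_fractions(
    scores: Sequence[float], bins: Mapping[str, tuple[float, float]]
) -> dict[str, float]:
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        return {name: float("nan") for name in bins}
    return {
        name: float(((arr >= lo) & (arr < hi)).mean()) for name, (lo, hi) in bins.items()
    }


def load_scores_tsv(path) -> pd.Series:
    """Two-column TSV (variant name, score) from an external predictor
    such as SIFT or PolyPhen; returns scores indexed by variant name."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValueError("score table must have exactly two columns")
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0])


def deleteriousness_shift(
    scores_detected: Sequence[float],
    scores_undetected: Sequence[float],
    bins: Mapping[str, tuple[float, float]] = SIFT_BINS,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (normal approximation, tie-corrected)."""
    x = np.asarray(scores_detected, dtype=float)
    y = np.asarray(scores_undetected, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both score lists must be nonempty")
    if np.all(x == x[0]) and np.all(y == x[0]):
        u1 = x.size * y.size / 2.0
        p = 1.0
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        u1, p = float(res.statistic), float(res.pvalue)
    rank_sum = u1 + x.size * (x.size + 1) / 2.0
    return RankSumResult(
        statistic=rank_sum,
        u_statistic=u1,
        p_value=float(p),
        fractions_first=score_category_fractions(x, bins),
        fractions_second=score_category_fractions(y, bins),
    )
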
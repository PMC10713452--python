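"""Synthetic genomes, gene models, variants, junction reads and peptide
evidence with the statistical structure the downstream analysis assumes.

Genes are laid out on a single chromosome, alternating strands.  Each gene
has one full isoform plus one skip isoform per cassette exon.  Coding
sequence is built from codons sampled uniformly over the 61 non-stop
codons, then iteratively repaired so that every isoform (including
frame-shifted skip isoforms) translates without internal stops.  A fixed
seed makes every output byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as iomod
from .digest import DigestParams, PROTEASES, get_protease, digest
from .models import CODON_TABLE, GeneModel, STOP_CODONS, revcomp, translate
from .variants import FilterThresholds, variant_pass_mask

__all__ = [
    "Dist",
    "DetectModel",
    "SynthConfig",
    "SynthTruth",
    "SynthResult",
    "generate_gene_models",
    "simulate_variants",
    "simulate_peptide_evidence",
    "simulate_junction_reads",
    "generate_dataset",
    "ConfigError",
]

_NONSTOP_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ConfigError(ValueError):
    """Impossible or inconsistent synthesis configuration."""


@dataclass(frozen=True)
class Dist:
    """Small distribution spec usable from YAML: ("const", v),
    ("uniform", lo, hi), ("randint", lo, hi) inclusive, ("poisson", lam),
    ("lognormal", mean, sigma), ("beta", a, b), ("normal", mu, sigma)."""

    kind: str
    args: tuple[float, ...]

    @staticmethod
    def of(spec) -> "Dist":
        if isinstance(spec, Dist):
            return spec
        if isinstance(spec, (int, float)):
            return Dist("const", (float(spec),))
        if isinstance(spec, (tuple, list)):
            kind, *args = spec
            return Dist(str(kind), tuple(float(a) for a in args))
        raise ConfigError(f"cannot interpret distribution spec {spec!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        a = self.args
        if self.kind == "const":
            return np.full(size, a[0]) if size is not None else a[0]
        if self.kind == "uniform":
            return rng.uniform(a[0], a[1], size)
        if self.kind == "randint":
            return rng.integers(int(a[0]), int(a[1]) + 1, size)
        if self.kind == "poisson":
            return rng.poisson(a[0], size)
        if self.kind == "lognormal":
            return rng.lognormal(a[0], a[1], size)
        if self.kind == "beta":
            return rng.beta(a[0], a[1], size)
        if self.kind == "normal":
            return rng.normal(a[0], a[1], size)
        raise ConfigError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class DetectModel:
    """Peptide detection probability as a function of isoform abundance.

    ``logistic``: efficiency * ceiling / (1 + exp(-slope*(log2(a) - midpoint))).
    ``always`` / ``never`` short-circuit for tests.
    """

    mode: str = "logistic"
    slope: float = 1.2
    midpoint_log2: float = 3.0
    ceiling: float = 0.95
    efficiency: Mapping[str, float] = field(default_factory=dict)

    def prob(self, abundance: float, protease: str) -> float:
        eff = float(self.efficiency.get(protease, 1.0))
        if self.mode == "always":
            return 1.0 if abundance > 0 else 0.0
        if self.mode == "never":
            return 0.0
        if abundance <= 0:
            return 0.0
        x = np.log2(abundance) - self.midpoint_log2
        return float(eff * self.ceiling / (1.0 + np.exp(-self.slope * x)))


@dataclass
class SynthConfig:
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (30, 120)  # nt
    intron_len: tuple[int, int] = (20, 60)
    cassette_fraction: float = 0.5
    frame_preserving_fraction: float | None = 0.5
    psi_dist: Dist | Sequence = ("uniform", 0.05, 0.95)
    snp_rate: float = 2.0  # nonsynonymous SNPs per kb CDS
    depth_dist: Dist | Sequence = ("poisson", 30)
    allele_freq_dist: Dist | Sequence = ("beta", 2.0, 2.0)
    baseq_dist: Dist | Sequence = ("const", 30)
    mapq_dist: Dist | Sequence = ("const", 40)
    multimapped_rate: float = 0.0
    abundance_dist: Dist | Sequence = ("lognormal", 2.0, 1.2)
    detect_model: DetectModel = field(default_factory=DetectModel)
    proteases: tuple[str, ...] = tuple(sorted(PROTEASES))
    digest_params: DigestParams = field(default_factory=DigestParams)
    junction_read_scale: float = 2.0
    cell_line: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"empty or invalid range for {name}: ({lo}, {hi})")
        if self.exon_len[1] < 3:
            raise ConfigError("exon_len range too small to host a codon")
        if not 0.0 <= self.cassette_fraction <= 1.0:
            raise ConfigError("cassette_fraction must be in [0, 1]")
        if self.cassette_fraction > 0 and self.exons_per_gene[1] < 3:
            raise ConfigError("cassette exons require genes with >= 3 exons")
        for name in ("psi_dist", "depth_dist", "allele_freq_dist", "baseq_dist",
                     "mapq_dist", "abundance_dist"):
            setattr(self, name, Dist.of(getattr(self, name)))
        unknown = [p for p in self.proteases if p.lower() not in PROTEASES]
        if unknown:
            raise ConfigError(f"unknown proteases: {unknown}")


@dataclass
class TruthEvent:
    gene_id: str
    cassette_exon: str
    inclusion_isoform: str
    skip_isoform: str
    psi: float
    frame_preserving: bool
    exon_len: int


@dataclass
class SynthTruth:
    proteins: dict[str, str] = field(default_factory=dict)  # isoform id -> aa seq
    isoform_gene: dict[str, str] = field(default_factory=dict)
    gene_abundance: dict[str, float] = field(default_factory=dict)
    isoform_abundance: dict[str, float] = field(default_factory=dict)
    events: list[TruthEvent] = field(default_factory=list)
    variants: pd.DataFrame | None = None
    peptides: pd.DataFrame | None = None


@dataclass
class SynthResult:
    cfg: SynthConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: SynthTruth

    def proteome(self) -> dict[str, str]:
        return dict(self.truth.proteins)

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _adjust_frame(length: int, preserve: bool) -> int:
    """Nudge a length to be (or not be) a multiple of 3, staying >= 3."""
    if preserve:
        adjusted = length - length % 3
        return adjusted if adjusted >= 3 else 3
    if length % 3 == 0:
        return length + 1
    return length


def _build_gene(
    rng: np.random.Generator, cfg: SynthConfig, gene_id: str, strand: str
) -> tuple[GeneModel, dict, str]:
    """Build exon layout + sense sequence; returns (model-less info) for
    later genomic placement: exon gene-coord intervals and the gene-sense
    sequence."""
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1)) for _ in range(n_ex)]
    cassette_flags = [False] * n_ex
    for i in range(1, n_ex - 1):
        if rng.random() < cfg.cassette_fraction:
            cassette_flags[i] = True
            if cfg.frame_preserving_fraction is not None:
                preserve = rng.random() < cfg.frame_preserving_fraction
                lens[i] = _adjust_frame(lens[i], preserve)
    # full-isoform CDS length must be a codon multiple
    total = sum(lens)
    lens[-1] += (3 - total % 3) % 3

    # sense CDS from uniform non-stop codons
    n_codons = sum(lens) // 3
    cds = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons))
    intron_lens = [
        int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
        for _ in range(n_ex - 1)
    ]

    # gene-coordinate (0-based half-open) exon intervals on the sense strand
    exon_iv = []
    pos = 0
    cds_off = 0
    parts = []
    for i, length in enumerate(lens):
        exon_iv.append((pos, pos + length))
        parts.append(cds[cds_off : cds_off + length])
        cds_off += length
        pos += length
        if i < n_ex - 1:
            parts.append(_random_seq(rng, intron_lens[i]))
            pos += intron_lens[i]
    gene_seq = "".join(parts)

    # isoform definitions over exon indices
    isoforms: dict[str, list[int]] = {f"{gene_id}.t1": list(range(n_ex))}
    cassette_meta = {}
    for i, flag in enumerate(cassette_flags):
        if flag:
            tid = f"{gene_id}.skip{i + 1}"
            isoforms[tid] = [j for j in range(n_ex) if j != i]
            cassette_meta[tid] = i

    gene_seq = _repair_stops(rng, gene_seq, exon_iv, isoforms)
    info = {
        "exon_iv": exon_iv,
        "isoforms": isoforms,
        "cassette_meta": cassette_meta,
        "lens": lens,
    }
    return GeneModel(gene_id, "chr1", strand), info, gene_seq


def _isoform_cds(gene_seq: str, exon_iv, exon_indices) -> str:
    return "".join(gene_seq[s:e] for s, e in (exon_iv[i] for i in exon_indices))


def _repair_stops(
    rng: np.random.Generator,
    gene_seq: str,
    exon_iv,
    isoforms: Mapping[str, list[int]],
    max_rounds: int = 100_000,
) -> str:
    """Mutate single nucleotides until no isoform CDS contains a stop."""
    seq = list(gene_seq)
    for _ in range(max_rounds):
        dirty = False
        for exon_indices in isoforms.values():
            cds = _isoform_cds("".join(seq), exon_iv, exon_indices)
            n = len(cds) - len(cds) % 3
            stop_at = next(
                (i for i in range(0, n, 3) if cds[i : i + 3] in STOP_CODONS), None
            )
            if stop_at is None:
                continue
            dirty = True
            # map CDS offset back to a gene coordinate and mutate one base
            off = stop_at + int(rng.integers(0, 3))
            acc = 0
            gpos = None
            for i in exon_indices:
                s, e = exon_iv[i]
                if off < acc + (e - s):
                    gpos = s + (off - acc)
                    break
                acc += e - s
            assert gpos is not None
            old = seq[gpos]
            seq[gpos] = rng.choice([b for b in _BASES if b != old])
            break
        if not dirty:
            return "".join(seq)
    raise RuntimeError("stop-codon repair did not converge")


def generate_gene_models(cfg: SynthConfig) -> SynthResult:
    """Genome FASTA dict, gene models and truth (proteins, events, abundance)."""
    rng = np.random.default_rng(cfg.seed)
    truth = SynthTruth()
    genes: list[GeneModel] = []
    chrom_parts: list[str] = []
    cursor = 1  # next free 1-based genomic position
    gap = 100
    for gi in range(cfg.n_genes):
        gene_id = f"g{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        model, info, gene_seq = _build_gene(rng, cfg, gene_id, strand)
        glen = len(gene_seq)
        gstart = cursor + gap
        chrom_parts.append(_random_seq(rng, gap))
        chrom_parts.append(gene_seq if strand == "+" else revcomp(gene_seq))
        cursor = gstart + glen

        exon_ids = [f"{gene_id}.e{i + 1}" for i in range(len(info["exon_iv"]))]
        for eid, (s, e) in zip(exon_ids, info["exon_iv"]):
            if strand == "+":
                model.exons[eid] = (gstart + s, gstart + e - 1)
            else:
                model.exons[eid] = (gstart + glen - e, gstart + glen - s - 1)
        for tid, exon_indices in info["isoforms"].items():
            model.isoforms[tid] = [exon_ids[i] for i in exon_indices]
        model.validate()
        genes.append(model)

        # truth: proteins and abundance
        A = float(cfg.abundance_dist.sample(rng))
        truth.gene_abundance[gene_id] = A
        psis = {}
        for tid, exon_idx in info["cassette_meta"].items():
            psi = float(np.clip(cfg.psi_dist.sample(rng), 0.01, 0.99))
            psis[tid] = psi
        full_tid = f"{gene_id}.t1"
        weights = {full_tid: float(np.prod([p for p in psis.values()]) if psis else 1.0)}
        for tid, psi in psis.items():
            others = np.prod([p for t, p in psis.items() if t != tid]) if len(psis) > 1 else 1.0
            weights[tid] = (1.0 - psi) * float(others)
        wsum = sum(weights.values())
        for tid, exon_indices in info["isoforms"].items():
            cds = _isoform_cds(gene_seq, info["exon_iv"], exon_indices)
            truth.proteins[tid] = translate(cds)
            truth.isoform_gene[tid] = gene_id
            truth.isoform_abundance[tid] = A * weights[tid] / wsum
        for tid, exon_idx in info["cassette_meta"].items():
            truth.events.append(
                TruthEvent(
                    gene_id=gene_id,
                    cassette_exon=exon_ids[exon_idx],
                    inclusion_isoform=full_tid,
                    skip_isoform=tid,
                    psi=psis[tid],
                    frame_preserving=info["lens"][exon_idx] % 3 == 0,
                    exon_len=info["lens"][exon_idx],
                )
            )
    genome = {"chr1": "".join(chrom_parts)}
    return SynthResult(cfg, genome, genes, truth)


def simulate_variants(result: SynthResult, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Pileup table plus per-variant truth (stored on result.truth.variants).

    Sites are drawn along each gene's full-isoform CDS at ``snp_rate`` per
    kb; alternative alleles are chosen to be nonsynonymous in the full
    isoform.  Depth/allele-fraction/quality fields come from the config
    distributions; truth records the filter decision.
    """
    cfg = result.cfg
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    rows = []
    truth_rows = []
    for gene in result.genes:
        full_tid = f"{gene.gene_id}.t1"
        cds = gene.transcript_sequence(full_tid, result.genome).upper()
        n_sites = rng.poisson(cfg.snp_rate * len(cds) / 1000.0)
        if n_sites == 0:
            continue
        positions = sorted(
            rng.choice(len(cds) - len(cds) % 3, size=min(n_sites, len(cds) // 3),
                       replace=False).tolist()
        )
        for cpos in positions:
            codon_idx, off = divmod(cpos, 3)
            codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
            ref_sense = cds[cpos]
            candidates = [b for b in _BASES if b != ref_sense]
            rng.shuffle(candidates)
            alt_sense = None
            for b in candidates:
                new_codon = codon[:off] + b + codon[off + 1 :]
                if (
                    new_codon not in STOP_CODONS
                    and CODON_TABLE[new_codon] != CODON_TABLE[codon]
                ):
                    alt_sense = b
                    break
            if alt_sense is None:
                continue
            gpos = gene.cds_to_genomic(full_tid, cpos)
            if gene.strand == "+":
                ref_g, alt_g = ref_sense, alt_sense
            else:
                ref_g, alt_g = _COMPLEMENT[ref_sense], _COMPLEMENT[alt_sense]
            depth = max(int(cfg.depth_dist.sample(rng)), 0)
            af = float(np.clip(cfg.allele_freq_dist.sample(rng), 0.0, 1.0))
            alt_count = int(rng.binomial(depth, af)) if depth > 0 else 0
            rows.append(
                {
                    "CHROM": gene.chrom,
                    "POS": gpos,
                    "REF": ref_g,
                    "ALT": alt_g,
                    "DEPTH": depth,
                    "ALT_COUNT": alt_count,
                    "BASEQ": float(cfg.baseq_dist.sample(rng)),
                    "MAPQ": float(cfg.mapq_dist.sample(rng)),
                    "MULTIMAPPED": bool(rng.random() < cfg.multimapped_rate),
                }
            )
            truth_rows.append(
                {
                    "CHROM": gene.chrom,
                    "POS": gpos,
                    "gene_id": gene.gene_id,
                    "transcript_id": full_tid,
                    "aa_pos": codon_idx + 1,
                    "ref_aa": CODON_TABLE[codon],
                    "alt_aa": CODON_TABLE[codon[:off] + alt_sense + codon[off + 1 :]],
                }
            )
    pileup = pd.DataFrame(
        rows,
        columns=[
            "CHROM", "POS", "REF", "ALT", "DEPTH", "ALT_COUNT", "BASEQ",
            "MAPQ", "MULTIMAPPED",
        ],
    )
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["CHROM", "POS", "gene_id", "transcript_id", "aa_pos", "ref_aa", "alt_aa"],
    )
    if len(pileup):
        truth_df["passes_filter"] = variant_pass_mask(pileup).to_numpy()
    else:
        truth_df["passes_filter"] = pd.Series(dtype=bool)
    result.truth.variants = truth_df
    return pileup


def simulate_peptide_evidence(
    result: SynthResult,
    proteases: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Peptide evidence drawn from true digestion products.

    Inclusion probability is monotone in isoform abundance via the
    configured detection model; per-protease provenance and PSM counts are
    recorded.
    """
    cfg = result.cfg
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    protease_names = [p.lower() for p in (proteases or cfg.proteases)]
    rules = [get_protease(p) for p in protease_names]
    rows = []
    for tid, protein in result.truth.proteins.items():
        abundance = result.truth.isoform_abundance[tid]
        for rule in rules:
            p_detect = cfg.detect_model.prob(abundance, rule.name)
            if p_detect <= 0:
                continue
            for rec in digest(protein, rule, cfg.digest_params, protein_id=tid):
                if rng.random() >= p_detect:
                    continue
                rows.append(
                    {
                        "sequence": rec.sequence,
                        "protein_id": tid,
                        "start": rec.start + 1,
                        "end": rec.end,
                        "protease": rule.name,
                        "cell_line": cfg.cell_line,
                        "psm_count": 1 + int(rng.poisson(2 * p_detect)),
                    }
                )
    evidence = pd.DataFrame(
        rows,
        columns=["sequence", "protein_id", "start", "end", "protease",
                 "cell_line", "psm_count"],
    )
    result.truth.peptides = evidence
    return evidence


def simulate_junction_reads(
    result: SynthResult, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Junction read counts: each junction draws Poisson reads proportional
    to the total abundance of the isoforms carrying it, so cassette PSI is
    realized at the junction level (inclusion reads split across the two
    inclusion junctions)."""
    cfg = result.cfg
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    rows = []
    for gene in result.genes:
        junction_abundance: dict[tuple[int, int], float] = {}
        for tid in gene.isoforms:
            a = result.truth.isoform_abundance[tid]
            for j in gene.junctions(tid):
                junction_abundance[j] = junction_abundance.get(j, 0.0) + a
        for (donor, acceptor), a in sorted(junction_abundance.items()):
            reads = int(rng.poisson(cfg.junction_read_scale * a))
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "donor": donor,
                    "acceptor": acceptor,
                    "reads": reads,
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "donor", "acceptor", "reads"])
    total = df["reads"].sum()
    df["rpm"] = df["reads"] / total * 1e6 if total else 0.0
    return df


def generate_dataset(cfg: SynthConfig) -> tuple[SynthResult, dict[str, pd.DataFrame]]:
    """Full synthetic bundle: models + pileup + evidence + junction reads."""
    result = generate_gene_models(cfg)
    tables = {
        "pileup": simulate_variants(result),
        "evidence": simulate_peptide_evidence(result),
        "junction_reads": simulate_junction_reads(result),
    }
    return result, tables


def write_dataset(
    result: SynthResult, tables: Mapping[str, pd.DataFrame], outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iomod.write_fasta(result.genome, outdir / "genome.fa")
    iomod.write_fasta(result.truth.proteins, outdir / "proteome.fa")
    iomod.write_gtf(result.genes, outdir / "models.gtf")
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    if result.truth.variants is not None:
        result.truth.variants.to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)
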
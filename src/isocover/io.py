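"""File interchange: FASTA via Biopython, GTF and tabular TSV helpers.

GTF output is 1-based inclusive with ``gene_id``/``transcript_id``
attributes and ``exon`` + ``CDS`` features (transcripts here are fully
coding, so the two mirror each other).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel

__all__ = ["read_fasta", "write_fasta", "write_gtf", "read_gtf"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> sequence, insertion-ordered; description retained separately
    by callers that need it (see :func:`read_fasta_with_desc`)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_desc(path: str | Path) -> dict[str, tuple[str, str]]:
    return {
        rec.id: (str(rec.seq), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(
    seqs: Mapping[str, str], path: str | Path, descriptions: Mapping[str, str] | None = None
) -> None:
    records = []
    for name, seq in seqs.items():
        desc = descriptions.get(name, "") if descriptions else ""
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")


def write_gtf(genes: list[GeneModel], path: str | Path, source: str = "isocover") -> None:
    lines = []
    for gene in genes:
        g_start, g_end = gene.span()
        attrs = f'gene_id "{gene.gene_id}";'
        lines.append(
            "\t".join(
                [gene.chrom, source, "gene", str(g_start), str(g_end), ".",
                 gene.strand, ".", attrs]
            )
        )
        for tid, exon_ids in gene.isoforms.items():
            blocks = [gene.exons[e] for e in exon_ids]
            t_start = min(s for s, _ in blocks)
            t_end = max(e for _, e in blocks)
            tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
            lines.append(
                "\t".join(
                    [gene.chrom, source, "transcript", str(t_start), str(t_end),
                     ".", gene.strand, ".", tattrs]
                )
            )
            for n, (eid, (s, e)) in enumerate(zip(exon_ids, blocks), start=1):
                eattrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tid}"; '
                    f'exon_number "{n}"; exon_id "{eid}";'
                )
                for feat in ("exon", "CDS"):
                    lines.append(
                        "\t".join(
                            [gene.chrom, source, feat, str(s), str(e), ".",
                             gene.strand, ".", eattrs]
                        )
                    )
    Path(path).write_text("\n".join(lines) + "\n")


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Rebuild :class:`GeneModel` objects from a GTF written by this package
    (or any GTF whose exon features carry gene_id/transcript_id)."""
    genes: dict[str, GeneModel] = {}
    tx_exons: dict[tuple[str, str], list[tuple[int, int, str | None]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, feat, start, end, _score, strand, _frame, attr_str = (
            line.split("\t")
        )
        if feat != "exon":
            continue
        attrs = dict(_ATTR_RE.findall(attr_str))
        gid = attrs["gene_id"]
        tid = attrs["transcript_id"]
        if gid not in genes:
            genes[gid] = GeneModel(gid, chrom, strand)
        tx_exons.setdefault((gid, tid), []).append(
            (int(start), int(end), attrs.get("exon_id"))
        )
    for (gid, tid), blocks in tx_exons.items():
        gene = genes[gid]
        blocks.sort(key=lambda b: b[0], reverse=gene.strand == "-")
        exon_ids = []
        for s, e, eid in blocks:
            eid = eid or f"{gid}:{s}-{e}"
            gene.exons[eid] = (s, e)
            exon_ids.append(eid)
        gene.isoforms[tid] = exon_ids
    for gene in genes.values():
        gene.validate()
    return list(genes.values())
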
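"""Gene models shared across the splicing, synthesis and variant modules.

Genomic coordinates are 1-based inclusive (GTF convention) everywhere in
this module.  "Transcript order" means 5'->3' along the direction of
transcription: ascending genomic coordinates on the plus strand, descending
on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GeneModel", "revcomp", "translate", "CODON_TABLE", "STOP_CODONS"]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[_i * 16 + _j * 4 + _k]
STOP_CODONS = frozenset(c for c, a in CODON_TABLE.items() if a == "*")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(cds: str, trim_to_frame: bool = True, stop_at_stop: bool = False) -> str:
    """Translate frame 0; trailing partial codon dropped when ``trim_to_frame``."""
    n = len(cds) - len(cds) % 3 if trim_to_frame else len(cds)
    aas = []
    for i in range(0, n, 3):
        aa = CODON_TABLE[cds[i : i + 3].upper()]
        if aa == "*" and stop_at_stop:
            break
        aas.append(aa)
    return "".join(aas)


@dataclass
class GeneModel:
    """A gene with exon coordinates and isoforms as ordered exon-id lists.

    ``exons`` maps exon id -> (start, end) genomic, 1-based inclusive.
    ``isoforms`` maps transcript id -> exon ids in transcript order.
    The whole transcript is treated as coding (synthetic models are built
    that way; real models should be restricted to CDS features upstream).
    """

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: dict[str, tuple[int, int]] = field(default_factory=dict)
    isoforms: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for tid, exon_ids in self.isoforms.items():
            blocks = [self.exons[e] for e in exon_ids]
            for s, e in blocks:
                if s > e:
                    raise ValueError(f"{self.gene_id}/{tid}: exon start > end")
            ordered = sorted(blocks, reverse=self.strand == "-")
            if blocks != ordered:
                raise ValueError(
                    f"{self.gene_id}/{tid}: exons not in transcript order"
                )
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                overlapping = s2 <= e1 if self.strand == "+" else e2 >= s1
                if overlapping:
                    raise ValueError(
                        f"{self.gene_id}/{tid}: overlapping exons {s1}-{e1},{s2}-{e2}"
                    )

    # -- geometry --------------------------------------------------------
    def exon_blocks(self, transcript_id: str) -> list[tuple[int, int]]:
        """Genomic (start, end) blocks in transcript order."""
        return [self.exons[e] for e in self.isoforms[transcript_id]]

    def transcript_length(self, transcript_id: str) -> int:
        return sum(e - s + 1 for s, e in self.exon_blocks(transcript_id))

    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons.values()]
        ends = [e for _, e in self.exons.values()]
        return min(starts), max(ends)

    def transcript_sequence(self, transcript_id: str, genome: dict[str, str]) -> str:
        """Spliced transcript sequence in coding sense."""
        chrom_seq = genome[self.chrom]
        parts = []
        for s, e in self.exon_blocks(transcript_id):
            block = chrom_seq[s - 1 : e]
            parts.append(revcomp(block) if self.strand == "-" else block)
        return "".join(parts)

    def cds_to_genomic(self, transcript_id: str, cds_pos: int) -> int:
        """Map a 0-based transcript/CDS nucleotide offset to a genomic position."""
        off = cds_pos
        for s, e in self.exon_blocks(transcript_id):
            length = e - s + 1
            if off < length:
                return s + off if self.strand == "+" else e - off
            off -= length
        raise IndexError(f"CDS offset {cds_pos} beyond {transcript_id}")

    def genomic_to_cds(self, transcript_id: str, gpos: int) -> int | None:
        """Inverse of :meth:`cds_to_genomic`; None if ``gpos`` is intronic."""
        acc = 0
        for s, e in self.exon_blocks(transcript_id):
            if s <= gpos <= e:
                return acc + (gpos - s if self.strand == "+" else e - gpos)
            acc += e - s + 1
        return None

    def junctions(self, transcript_id: str) -> list[tuple[int, int]]:
        """(donor, acceptor) genomic coordinate pairs in transcript order.

        Donor = last base of the upstream exon, acceptor = first base of the
        downstream exon, both in the transcription sense.
        """
        blocks = self.exon_blocks(transcript_id)
        out = []
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((s1, e2))
        return out
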
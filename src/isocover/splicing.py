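"""Splice graphs, alternative-splicing events, peptide-to-genome projection
and junction-level detection accounting.

The graph follows the exon-boundary convention: nodes are the beginnings
and ends of exons (in the transcription sense), intra-exon edges connect an
exon's begin to its end, and junction edges connect a donor (exon end) to
an acceptor (exon begin).  Every isoform is a path through the graph.

An AS event is a minimal "bubble": a pair of anchor nodes joined by at
least two paths that share no intermediate node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .models import GeneModel

__all__ = [
    "Node",
    "build_graph",
    "ASEvent",
    "enumerate_events",
    "PeptideGenomicAlignment",
    "project_peptide",
    "junction_peptide_support",
    "apply_event_support",
    "classify_junctions",
    "event_psi",
    "psi_optimum_analytic",
    "simulate_psi_detection_curve",
]

# A node is (genomic position, side); side "b" = exon begin, "e" = exon end,
# both in the transcription sense.
Node = tuple[int, str]


def _order_key(gene: GeneModel):
    sign = 1 if gene.strand == "+" else -1

    def key(node: Node) -> tuple[int, int]:
        pos, side = node
        return (sign * pos, 0 if side == "b" else 1)

    return key


def build_graph(gene: GeneModel) -> nx.DiGraph:
    """Exon-boundary splice graph with per-edge supporting isoform sets."""
    gene.validate()
    g = nx.DiGraph(gene_id=gene.gene_id, strand=gene.strand)
    for tid in gene.isoforms:
        blocks = gene.exon_blocks(tid)
        prev_end: Node | None = None
        for s, e in blocks:
            b: Node = (s if gene.strand == "+" else e, "b")
            en: Node = (e if gene.strand == "+" else s, "e")
            _add_edge(g, b, en, kind="exon", length=e - s + 1, tid=tid)
            if prev_end is not None:
                _add_edge(g, prev_end, b, kind="junction", length=0, tid=tid)
            prev_end = en
    return g


def _add_edge(g: nx.DiGraph, u: Node, v: Node, kind: str, length: int, tid: str) -> None:
    if g.has_edge(u, v):
        data = g[u][v]
        if data["kind"] != kind:
            raise ValueError(f"conflicting edge kinds between {u} and {v}")
        data["isoforms"].add(tid)
    else:
        g.add_edge(u, v, kind=kind, length=length, isoforms={tid})


def isoform_path(gene: GeneModel, tid: str) -> list[Node]:
    nodes: list[Node] = []
    for s, e in gene.exon_blocks(tid):
        nodes.append((s if gene.strand == "+" else e, "b"))
        nodes.append((e if gene.strand == "+" else s, "e"))
    return nodes


@dataclass
class ASEvent:
    """A minimal splice-graph bubble between two anchor nodes.

    ``paths`` holds node lists in transcription order, sorted by decreasing
    exonic length so that ``paths[0]`` is the inclusion-like path and
    ``paths[-1]`` the exclusion-like path.
    """

    gene_id: str
    anchor_start: Node
    anchor_end: Node
    paths: list[list[Node]]
    path_lengths: list[int]  # exonic nt per path
    path_junctions: list[list[tuple[int, int]]]  # (donor, acceptor) per path
    event_type: str
    frame_preserving: bool
    psi: float | None = None
    rna_support: str | None = None  # "none" | "one alternative" | "both"
    proteomic_support: list[int] = field(default_factory=list)
    detection: str | None = None  # "none" | "one" | "both"

    @property
    def inserted_length(self) -> int:
        return self.path_lengths[0] - self.path_lengths[-1]

    def key(self) -> tuple:
        return (
            self.gene_id,
            self.anchor_start,
            self.anchor_end,
            tuple(sorted(tuple(p) for p in self.paths)),
        )


def _path_edges(g: nx.DiGraph, path: Sequence[Node]):
    return [(u, v, g[u][v]) for u, v in zip(path, path[1:])]


def _path_exonic_length(g: nx.DiGraph, path: Sequence[Node]) -> int:
    return sum(d["length"] for _, _, d in _path_edges(g, path) if d["kind"] == "exon")


def _path_junctions(g: nx.DiGraph, path: Sequence[Node]) -> list[tuple[int, int]]:
    return [
        (u[0], v[0])
        for u, v, d in _path_edges(g, path)
        if d["kind"] == "junction"
    ]


def _classify(g: nx.DiGraph, paths: list[list[Node]]) -> str:
    if len(paths) != 2:
        return "other"
    patterns = []
    for p in paths:
        patterns.append(tuple(d["kind"] for _, _, d in _path_edges(g, p)))
    long_pat, short_pat = patterns  # paths pre-sorted by exonic length desc
    if short_pat == ("junction",) and long_pat == ("junction", "exon", "junction"):
        return "cassette exon"
    # the retained-intron path is the longer one (a single intra-exon edge)
    if long_pat == ("exon",) and short_pat == ("exon", "junction", "exon"):
        return "intron retention"
    if long_pat == short_pat == ("junction", "exon"):
        return "alt 3'"
    if long_pat == short_pat == ("exon", "junction"):
        return "alt 5'"
    if long_pat == short_pat == ("junction", "exon", "junction"):
        return "mutually exclusive"
    return "other"


def enumerate_events(g: nx.DiGraph, gene: GeneModel | None = None) -> list[ASEvent]:
    """All minimal bubbles: anchor pairs with >=2 intermediate-disjoint paths."""
    gene_id = g.graph.get("gene_id", "")
    nodes = list(nx.topological_sort(g))
    index = {n: i for i, n in enumerate(nodes)}
    events: list[ASEvent] = []
    seen: set[tuple] = set()
    for a, b in combinations(nodes, 2):
        if index[a] >= index[b]:
            continue
        paths = [list(p) for p in nx.all_simple_paths(g, a, b)]
        if len(paths) < 2:
            continue
        inner = [set(p[1:-1]) for p in paths]
        common = set.intersection(*inner) if inner else set()
        if common:
            continue
        lengths = [_path_exonic_length(g, p) for p in paths]
        order = sorted(range(len(paths)), key=lambda i: -lengths[i])
        paths = [paths[i] for i in order]
        lengths = [lengths[i] for i in order]
        ev = ASEvent(
            gene_id=gene_id,
            anchor_start=a,
            anchor_end=b,
            paths=paths,
            path_lengths=lengths,
            path_junctions=[_path_junctions(g, p) for p in paths],
            event_type=_classify(g, paths),
            frame_preserving=(lengths[0] - lengths[-1]) % 3 == 0,
        )
        if ev.key() in seen:
            continue
        seen.add(ev.key())
        events.append(ev)
    return events


@dataclass
class PeptideGenomicAlignment:
    """Genomic footprint of a peptide on one isoform."""

    peptide: str
    transcript_id: str
    strand: str
    blocks_tx: list[tuple[int, int]]  # transcript order, 1-based inclusive
    junctions: list[tuple[int, int]]  # (donor, acceptor) between blocks

    @property
    def blocks(self) -> list[tuple[int, int]]:
        """Blocks in ascending genomic order regardless of strand."""
        return sorted(self.blocks_tx)

    @property
    def nt_length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks_tx)


def project_peptide(
    gene: GeneModel,
    transcript_id: str,
    aa_start: int,
    aa_end: int,
    peptide: str = "",
) -> PeptideGenomicAlignment:
    """Map protein coordinates (1-based inclusive) to genomic blocks.

    The nt footprint is ``[3*(aa_start-1), 3*aa_end)`` in CDS space, split
    across the isoform's exon blocks.
    """
    if aa_start < 1 or aa_end < aa_start:
        raise ValueError("invalid aa interval")
    nt_lo = 3 * (aa_start - 1)
    nt_hi = 3 * aa_end
    blocks = gene.exon_blocks(transcript_id)
    total = sum(e - s + 1 for s, e in blocks)
    if nt_hi > total:
        raise ValueError(
            f"peptide extends beyond CDS of {transcript_id} ({nt_hi} > {total})"
        )
    out: list[tuple[int, int]] = []
    acc = 0
    for s, e in blocks:
        length = e - s + 1
        lo = max(nt_lo, acc)
        hi = min(nt_hi, acc + length)
        if lo < hi:
            if gene.strand == "+":
                out.append((s + (lo - acc), s + (hi - acc) - 1))
            else:
                out.append((e - (hi - acc) + 1, e - (lo - acc)))
        acc += length
        if acc >= nt_hi:
            break
    junctions = []
    for (s1, e1), (s2, e2) in zip(out, out[1:]):
        if gene.strand == "+":
            junctions.append((e1, s2))
        else:
            junctions.append((s1, e2))
    return PeptideGenomicAlignment(peptide, transcript_id, gene.strand, out, junctions)


def junction_peptide_support(
    alignments: Iterable[PeptideGenomicAlignment], min_flank: int = 3
) -> dict[tuple[int, int], set[str]]:
    """Peptides crossing each junction with >= ``min_flank`` nt on both sides."""
    support: dict[tuple[int, int], set[str]] = {}
    for aln in alignments:
        for i, junction in enumerate(aln.junctions):
            left = aln.blocks_tx[i]
            right = aln.blocks_tx[i + 1]
            if (left[1] - left[0] + 1) >= min_flank and (
                right[1] - right[0] + 1
            ) >= min_flank:
                support.setdefault(junction, set()).add(aln.peptide)
    return support


def apply_event_support(
    events: Iterable[ASEvent],
    junction_support: Mapping[tuple[int, int], set[str]],
) -> None:
    """Fill proteomic_support and detection status in place.

    A path is supported by the unique peptides crossing any of its
    junctions; junction-free paths (retained introns) count peptides only
    via their flanking junctions and therefore report 0 here.
    """
    for ev in events:
        per_path = []
        for junctions in ev.path_junctions:
            peps: set[str] = set()
            for j in junctions:
                peps |= junction_support.get(j, set())
            per_path.append(len(peps))
        ev.proteomic_support = per_path
        n_detected = sum(1 for c in per_path if c > 0)
        ev.detection = (
            "both" if n_detected >= 2 else "one" if n_detected == 1 else "none"
        )


def classify_junctions(
    gene: GeneModel, g: nx.DiGraph, events: Iterable[ASEvent]
) -> dict[tuple[int, int], str]:
    """constitutive / inclusion / exclusion class per junction of the gene."""
    all_iso = set(gene.isoforms)
    classes: dict[tuple[int, int], str] = {}
    for u, v, d in g.edges(data=True):
        if d["kind"] != "junction":
            continue
        j = (u[0], v[0])
        classes[j] = "constitutive" if d["isoforms"] == all_iso else "unclassified"
    for ev in events:
        for j in ev.path_junctions[0]:
            if classes.get(j) == "unclassified":
                classes[j] = "inclusion"
        for j in ev.path_junctions[-1]:
            if classes.get(j) == "unclassified":
                classes[j] = "exclusion"
    return classes


def event_psi(
    ev: ASEvent, junction_reads: Mapping[tuple[int, int], float]
) -> float | None:
    """PSI from junction reads: the inclusion path's junction reads are
    averaged (two junctions support one inclusion transcript) and compared
    with the exclusion path's support.  Junction-free exclusion paths
    (retained introns) are looked up under their (start, end) span as an
    intra-intron read proxy."""
    def path_reads(i: int) -> float | None:
        junctions = ev.path_junctions[i]
        if junctions:
            vals = [junction_reads.get(j, 0.0) for j in junctions]
            return float(np.mean(vals))
        span = (ev.paths[i][0][0], ev.paths[i][-1][0])
        return float(junction_reads.get(span, 0.0))

    incl = path_reads(0)
    excl = path_reads(len(ev.paths) - 1)
    total = incl + excl
    if total <= 0:
        return None
    return incl / total


def psi_optimum_analytic() -> float:
    """PSI at which inclusion (two junctions) and exclusion (one junction)
    detection signals balance: 2*psi = 1 - psi."""
    return 1.0 / 3.0


def simulate_psi_detection_curve(
    n_events: int = 10_000,
    seed: int = 0,
    bin_width: float = 0.07,
    bin_origin: float = 0.02,
    efficiency: float = 0.45,
) -> pd.DataFrame:
    """Per-path detection curves over a PSI grid under equal per-junction
    efficiency.

    The inclusion isoform exposes two detectable junctions, so its detection
    signal is proportional to 2*psi; the exclusion isoform exposes one, with
    signal proportional to 1-psi.  Each event's paths are detected as
    independent Bernoulli draws with those probabilities (scaled by a common
    efficiency).  ``balanced_rate`` -- the rate at which the limiting path
    is detected, min(inclusion, exclusion) -- peaks where the two signals
    cross: 2*psi = 1-psi, i.e. psi = 1/3.

    Default bin edges put 1/3 inside the [0.30, 0.37) bin.
    """
    rng = np.random.default_rng(seed)
    psi = rng.uniform(0.0, 1.0, size=n_events)
    p_incl = np.clip(efficiency * 2 * psi, 0.0, 1.0)
    p_excl = np.clip(efficiency * (1 - psi), 0.0, 1.0)
    incl_detected = rng.random(n_events) < p_incl
    excl_detected = rng.random(n_events) < p_excl
    edges = np.concatenate(
        [[0.0], np.arange(bin_origin, 1.0, bin_width)[1:], [1.0]]
    )
    idx = np.clip(np.digitize(psi, edges) - 1, 0, len(edges) - 2)
    df = pd.DataFrame(
        {
            "psi_bin_lo": edges[idx],
            "psi_bin_hi": edges[idx + 1],
            "incl": incl_detected,
            "excl": excl_detected,
        }
    )
    curve = (
        df.groupby(["psi_bin_lo", "psi_bin_hi"], as_index=False)
        .agg(inclusion_rate=("incl", "mean"), exclusion_rate=("excl", "mean"),
             n=("incl", "size"))
    )
    curve["balanced_rate"] = curve[["inclusion_rate", "exclusion_rate"]].min(axis=1)
    return curve


def psi_balance_bin(curve: pd.DataFrame) -> tuple[float, float]:
    """Bin where the inclusion and exclusion detection rates balance.

    The limiting-path rate min(inclusion, exclusion) peaks where the two
    curves cross.  Both rates are linear in PSI under the equal-efficiency
    model, so the crossing is located by a least-squares fit of the rate
    difference against the bin midpoint (pooling all simulated events,
    which is far tighter than the argmin over noisy per-bin differences);
    the returned bin is the one containing the fitted root."""
    mid = ((curve["psi_bin_lo"] + curve["psi_bin_hi"]) / 2).to_numpy()
    diff = (curve["inclusion_rate"] - curve["exclusion_rate"]).to_numpy()
    w = curve["n"].to_numpy(dtype=float)
    b, a = np.polyfit(mid, diff, 1, w=np.sqrt(w))
    root = -a / b if b != 0 else float("nan")
    if not np.isfinite(root) or not (0.0 <= root <= 1.0):
        idx = int(np.argmin(np.abs(diff)))
    else:
        inside = (curve["psi_bin_lo"] <= root) & (root < curve["psi_bin_hi"])
        idx = int(inside.idxmax()) if inside.any() else int(np.argmin(np.abs(diff)))
    row = curve.loc[idx]
    return float(row["psi_bin_lo"]), float(row["psi_bin_hi"])


def detection_rate_table(
    events: pd.DataFrame, by: str, bins: Sequence[float]
) -> pd.DataFrame:
    """Detection rate of events grouped into bins of one covariate.

    ``events`` needs a boolean ``detected`` column and the ``by`` column.
    """
    cut = pd.cut(events[by], bins=list(bins), include_lowest=True)
    out = (
        events.assign(_bin=cut)
        .groupby("_bin", observed=True)["detected"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"_bin": by + "_bin", "mean": "detection_rate", "count": "n"})
    )
    return out
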
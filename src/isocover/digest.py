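"""Multi-protease in silico digestion and theoretical proteome coverage.

Cleavage positions use a 0-based, half-open convention: a site at position
``i`` separates ``protein[:i]`` from ``protein[i:]``.  All tabular output is
converted to 1-based inclusive coordinates at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteaseRule",
    "DigestParams",
    "PeptideRecord",
    "PeptideSet",
    "PROTEASES",
    "get_protease",
    "cleavage_sites",
    "digest",
    "digest_proteome",
    "theoretical_coverage",
    "CoverageSummary",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity of a single protease.

    ``residues`` are the recognition residues; ``cut_side`` is ``"C"`` for
    cleavage C-terminal to a recognition residue and ``"N"`` for N-terminal.
    ``blocked_by`` lists residues that veto the cut when found on the far
    side of the scissile bond (the classic no-cut-before-proline rule).
    """

    name: str
    residues: frozenset[str]
    cut_side: str  # "C" or "N"
    blocked_by: frozenset[str] = frozenset()
    max_missed: int = 2

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residues must be nonempty")
        if self.cut_side not in ("C", "N"):
            raise ValueError(f"cut_side must be 'C' or 'N', got {self.cut_side!r}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    def without_proline_rule(self) -> "ProteaseRule":
        return replace(self, blocked_by=frozenset())


@dataclass(frozen=True)
class DigestParams:
    """Detectability window applied after fragment enumeration."""

    min_len: int = 7
    max_len: int = 35

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    protein_id: str
    start: int  # 0-based
    end: int  # 0-based, exclusive
    n_missed: int


@dataclass
class PeptideSet:
    """Digestion products with positional provenance."""

    records: list[PeptideRecord] = field(default_factory=list)

    @property
    def sequences(self) -> set[str]:
        return {r.sequence for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """1-based inclusive coordinates, one row per fragment."""
        return pd.DataFrame(
            {
                "peptide": [r.sequence for r in self.records],
                "protein_id": [r.protein_id for r in self.records],
                "start_1based": [r.start + 1 for r in self.records],
                "end_1based": [r.end for r in self.records],
                "n_missed": [r.n_missed for r in self.records],
            }
        )


# Default specificities: standard MaxQuant-style rules.  The proline
# exception is applied to the C-side cutters by default and is togglable
# via ``without_proline_rule``.
PROTEASES: dict[str, ProteaseRule] = {
    "trypsin": ProteaseRule("trypsin", frozenset("KR"), "C", frozenset("P"), 2),
    "lysc": ProteaseRule("lysc", frozenset("K"), "C", frozenset("P"), 2),
    "lysn": ProteaseRule("lysn", frozenset("K"), "N", frozenset(), 2),
    "aspn": ProteaseRule("aspn", frozenset("D"), "N", frozenset(), 2),
    "gluc": ProteaseRule("gluc", frozenset("E"), "C", frozenset("P"), 2),
    "chymotrypsin": ProteaseRule(
        "chymotrypsin", frozenset("FWYL"), "C", frozenset("P"), 4
    ),
}


def get_protease(name: str) -> ProteaseRule:
    try:
        return PROTEASES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown protease {name!r}; known: {sorted(PROTEASES)}"
        ) from None


def cleavage_sites(protein: str, rule: ProteaseRule) -> list[int]:
    """Return strictly increasing between-residue cut positions.

    Positions are in ``(0, len(protein))`` exclusive; termini are never
    reported.  Non-standard residues (U, X, B, Z, ...) are never cut at and
    never block a cut, but count toward peptide length.
    """
    sites: list[int] = []
    n = len(protein)
    if rule.cut_side == "C":
        for i in range(1, n):
            if protein[i - 1] in rule.residues and protein[i] not in rule.blocked_by:
                sites.append(i)
    else:
        for i in range(1, n):
            if protein[i] in rule.residues and protein[i - 1] not in rule.blocked_by:
                sites.append(i)
    return sites


def digest(
    protein: str,
    rule: ProteaseRule,
    params: DigestParams | None = None,
    protein_id: str = "",
    max_missed: int | None = None,
) -> PeptideSet:
    """Enumerate fully-specific fragments with up to ``max_missed`` internal sites.

    ``params=None`` disables the length window.  ``max_missed`` overrides the
    rule's own allowance when given.
    """
    out = PeptideSet()
    if not protein:
        return out
    mm = rule.max_missed if max_missed is None else max_missed
    bounds = [0, *cleavage_sites(protein, rule), len(protein)]
    nb = len(bounds)
    for i in range(nb - 1):
        for j in range(i + 1, min(i + mm + 2, nb)):
            start, end = bounds[i], bounds[j]
            length = end - start
            if params is not None and not (params.min_len <= length <= params.max_len):
                continue
            out.records.append(
                PeptideRecord(protein[start:end], protein_id, start, end, j - i - 1)
            )
    return out


def digest_proteome(
    proteome: Mapping[str, str],
    rules: Iterable[ProteaseRule],
    params: DigestParams | None = DigestParams(),
) -> pd.DataFrame:
    """Digest every protein with every rule; returns a tidy 1-based table."""
    frames = []
    for rule in rules:
        for pid, seq in proteome.items():
            ps = digest(seq, rule, params, protein_id=pid)
            if ps.records:
                df = ps.to_frame()
                df["protease"] = rule.name
                frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "peptide",
                "protein_id",
                "start_1based",
                "end_1based",
                "n_missed",
                "protease",
            ]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CoverageSummary:
    covered_residues: int
    total_residues: int

    @property
    def fraction(self) -> float:
        return self.covered_residues / self.total_residues if self.total_residues else 0.0


def theoretical_coverage(
    proteome: Mapping[str, str],
    rules: Iterable[ProteaseRule],
    params: DigestParams | None = DigestParams(),
) -> tuple[dict[str, float], CoverageSummary]:
    """Residue coverage by the union of retained fragments over all rules.

    Returns per-protein covered fractions and the aggregate residue count.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("at least one protease rule required")
    per_protein: dict[str, float] = {}
    covered_total = 0
    residue_total = 0
    for pid, seq in proteome.items():
        mask = np.zeros(len(seq), dtype=bool)
        for rule in rules:
            for rec in digest(seq, rule, params):
                mask[rec.start : rec.end] = True
        per_protein[pid] = float(mask.mean()) if len(seq) else 0.0
        covered_total += int(mask.sum())
        residue_total += len(seq)
    return per_protein, CoverageSummary(covered_total, residue_total)
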
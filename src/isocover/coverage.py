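"""Observed sequence coverage from peptide evidence, protease-combination
scans and transmembrane-segment coverage profiles.

Coverage follows the occurrence rule: each evidence peptide is searched for
all occurrences in its designated protein, ignoring enzyme specificity, and
every matched residue is marked once.  I and L are distinct during
matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageRecord",
    "TMAnnotation",
    "observed_coverage",
    "coverage_table",
    "combination_scan",
    "tm_profile",
]


@dataclass
class CoverageRecord:
    protein_id: str
    length: int
    mask: np.ndarray  # bool per residue
    n_peptides: int

    @property
    def fraction(self) -> float:
        return float(self.mask.mean()) if self.length else 0.0


@dataclass(frozen=True)
class TMAnnotation:
    protein_id: str
    segments: tuple[tuple[int, int], ...]  # 1-based inclusive aa intervals

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in sorted(self.segments):
            if s <= prev_end:
                raise ValueError(f"{self.protein_id}: overlapping TM segments")
            if s < 1 or e < s:
                raise ValueError(f"{self.protein_id}: bad segment ({s}, {e})")
            prev_end = e


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def observed_coverage(
    evidence: pd.DataFrame,
    proteome: Mapping[str, str],
    subset: Mapping[str, object] | None = None,
) -> dict[str, CoverageRecord]:
    """Per-protein coverage from an evidence table.

    ``evidence`` needs ``sequence`` and ``protein_id`` columns; ``subset``
    filters rows by exact match on other columns (e.g. protease, cell line).
    Peptides absent from their designated protein are skipped with a
    warning and counted in the log.
    """
    rows = evidence
    if subset:
        for col, val in subset.items():
            rows = rows[rows[col] == val]
    records = {
        pid: CoverageRecord(pid, len(seq), np.zeros(len(seq), dtype=bool), 0)
        for pid, seq in proteome.items()
    }
    n_skipped = 0
    seen: set[tuple[str, str]] = set()
    for seq, pid in zip(rows["sequence"], rows["protein_id"]):
        if (seq, pid) in seen:
            continue
        seen.add((seq, pid))
        if pid not in records:
            n_skipped += 1
            continue
        protein = proteome[pid]
        hits = list(_find_all(protein, seq))
        if not hits:
            n_skipped += 1
            warnings.warn(
                f"peptide {seq!r} not found in protein {pid}; row skipped",
                stacklevel=2,
            )
            continue
        rec = records[pid]
        for start in hits:
            rec.mask[start : start + len(seq)] = True
        rec.n_peptides += 1
    if n_skipped:
        logger.info("observed_coverage: skipped %d evidence rows", n_skipped)
    return records


def coverage_table(records: Mapping[str, CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": list(records),
            "length": [r.length for r in records.values()],
            "coverage": [r.fraction for r in records.values()],
            "n_peptides": [r.n_peptides for r in records.values()],
        }
    )


def _median(values: Sequence[float]) -> float:
    # linear-interpolation median, fixed convention
    return float(np.median(np.asarray(values, dtype=float)))


def combination_scan(
    evidence: pd.DataFrame,
    proteome: Mapping[str, str],
    proteases: Sequence[str],
    sizes: Sequence[int] = (2, 3, 4, 5),
    protease_column: str = "protease",
    top: int | None = None,
) -> pd.DataFrame:
    """Score every protease subset of the requested sizes by median coverage.

    Deterministic ranking: score descending, then lexicographic subset name.
    """
    proteases = sorted(set(proteases))
    if len(proteases) < 2:
        raise ValueError("need at least two proteases for a combination scan")
    rows = []
    for size in sizes:
        scored = []
        for combo in combinations(proteases, size):
            mask = evidence[protease_column].isin(combo)
            recs = observed_coverage(evidence[mask], proteome)
            score = _median([r.fraction for r in recs.values()])
            scored.append((score, combo))
        scored.sort(key=lambda t: (-t[0], t[1]))
        if top is not None:
            scored = scored[:top]
        for rank, (score, combo) in enumerate(scored, start=1):
            rows.append(
                {
                    "size": size,
                    "rank": rank,
                    "proteases": "+".join(combo),
                    "median_coverage": score,
                }
            )
    return pd.DataFrame(rows)


def tm_profile(
    records: Mapping[str, CoverageRecord],
    annotations: Iterable[TMAnnotation],
    anchor: str = "N",
    max_offset: int = 50,
) -> pd.DataFrame:
    """Mean coverage by residue offset from the anchored TM-segment boundary.

    ``anchor="N"`` aligns segments at their N-terminal boundary (offset 0 =
    first segment residue, positive offsets run into the segment);
    ``anchor="C"`` aligns at the C-terminal boundary (offset 0 = last
    segment residue, positive offsets run back into the segment).  Offsets
    outside the protein are ignored.
    """
    if anchor not in ("N", "C"):
        raise ValueError("anchor must be 'N' or 'C'")
    sums = np.zeros(2 * max_offset + 1)
    counts = np.zeros(2 * max_offset + 1)
    for ann in annotations:
        rec = records.get(ann.protein_id)
        if rec is None:
            continue
        for s, e in ann.segments:
            boundary = s - 1 if anchor == "N" else e - 1  # 0-based
            direction = 1 if anchor == "N" else -1
            for off in range(-max_offset, max_offset + 1):
                pos = boundary + direction * off
                if 0 <= pos < rec.length:
                    sums[off + max_offset] += rec.mask[pos]
                    counts[off + max_offset] += 1
    offsets = np.arange(-max_offset, max_offset + 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    df = pd.DataFrame({"offset": offsets, "mean_coverage": mean, "n": counts})
    return df[df["n"] > 0].reset_index(drop=True)
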
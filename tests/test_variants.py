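from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from isocover.models import GeneModel, translate
from isocover.variants import (
    FilterThresholds,
    build_variant_proteome,
    classify_sap_peptides,
    deleteriousness_shift,
    filter_variants,
    sap_detection_summary,
    variant_pass_mask,
)


def pileup_row(depth=20, alt=10, baseq=30, mapq=40, multimapped=False, pos=100):
    return {
        "CHROM": "chr1", "POS": pos, "REF": "A", "ALT": "G",
        "DEPTH": depth, "ALT_COUNT": alt, "BASEQ": baseq, "MAPQ": mapq,
        "MULTIMAPPED": multimapped,
    }


class TestFilterVariants:
    def test_boundary_values_pass(self):
        # exact thresholds from the filter cascade: all inclusive
        df = pd.DataFrame([pileup_row(depth=10, alt=5, baseq=13, mapq=13)])
        assert variant_pass_mask(df).tolist() == [True]

    def test_single_criterion_failures(self):
        rows = [
            pileup_row(depth=9, alt=9),            # depth
            pileup_row(depth=20, alt=4),           # alt count
            pileup_row(depth=100, alt=5),          # frequency 5% < 15%
            pileup_row(baseq=12.9),                # base quality
            pileup_row(mapq=12),                   # mapping quality
            pileup_row(multimapped=True),          # multimapped
        ]
        assert variant_pass_mask(pd.DataFrame(rows)).tolist() == [False] * 6

    def test_oracle_1000_rows(self, rng):
        rows = []
        for _ in range(1000):
            depth = int(rng.integers(0, 40))
            rows.append(
                pileup_row(
                    depth=depth,
                    alt=int(rng.integers(0, depth + 1)),
                    baseq=float(rng.uniform(0, 40)),
                    mapq=float(rng.uniform(0, 60)),
                    multimapped=bool(rng.random() < 0.1),
                )
            )
        df = pd.DataFrame(rows)
        got = variant_pass_mask(df).tolist()
        want = [
            r["DEPTH"] >= 10
            and r["ALT_COUNT"] >= 5
            and (r["ALT_COUNT"] / r["DEPTH"] if r["DEPTH"] else 0) >= 0.15
            and r["BASEQ"] >= 13
            and r["MAPQ"] >= 13
            and not r["MULTIMAPPED"]
            for r in rows
        ]
        assert got == want

    def test_row_order_invariant(self, rng):
        df = pd.DataFrame(
            [pileup_row(depth=int(d), alt=int(min(a, d)))
             for d, a in zip(rng.integers(0, 30, 50), rng.integers(0, 10, 50))]
        )
        shuffled = df.sample(frac=1, random_state=0)
        direct = set(filter_variants(df).index)
        assert set(filter_variants(shuffled).index) == direct

    def test_threshold_monotonicity(self, rng):
        df = pd.DataFrame(
            [
                pileup_row(
                    depth=int(rng.integers(0, 30)),
                    alt=int(rng.integers(0, 15)),
                    baseq=float(rng.uniform(0, 40)),
                    mapq=float(rng.uniform(0, 40)),
                )
                for _ in range(200)
            ]
        )
        df["ALT_COUNT"] = np.minimum(df["ALT_COUNT"], df["DEPTH"])
        base = variant_pass_mask(df)
        relaxed = [
            FilterThresholds(min_depth=5),
            FilterThresholds(min_alt=1),
            FilterThresholds(min_freq=0.01),
            FilterThresholds(min_baseq=0),
            FilterThresholds(min_mapq=0),
        ]
        for t in relaxed:
            assert (variant_pass_mask(df, t) | ~base).all()

    def test_malformed_row_reports_index(self):
        df = pd.DataFrame([pileup_row(), pileup_row(depth=5, alt=9)])
        with pytest.raises(ValueError, match="row 1"):
            variant_pass_mask(df)


def simple_gene(strand="+"):
    """One-exon gene; CDS = GAA AAA ... on the coding strand."""
    cds = "GAAAAA" * 5  # EKEKEKEKEK, 30 nt
    if strand == "+":
        genome = {"chr1": "N" * 100 + cds}
        gene = GeneModel("g", "chr1", "+", {"e1": (101, 130)}, {"t1": ["e1"]})
    else:
        from isocover.models import revcomp

        genome = {"chr1": "N" * 100 + revcomp(cds)}
        gene = GeneModel("g", "chr1", "-", {"e1": (101, 130)}, {"t1": ["e1"]})
    return gene, genome


class TestBuildVariantProteome:
    def test_synonymous_no_entry(self):
        gene, genome = simple_gene()
        # GAA -> GAG at codon 1 position 3: E -> E
        calls = pd.DataFrame([{"CHROM": "chr1", "POS": 103, "REF": "A", "ALT": "G"}])
        entries, _, cons = build_variant_proteome([gene], genome, calls)
        assert entries == {} and cons == []

    def test_e_to_k_substitution(self):
        gene, genome = simple_gene()
        # codon 9 = GAA at CDS offsets 24..26 -> genomic 125..127; G->A gives AAA (K)
        calls = pd.DataFrame([{"CHROM": "chr1", "POS": 125, "REF": "G", "ALT": "A"}])
        entries, desc, cons = build_variant_proteome([gene], genome, calls)
        assert list(entries) == ["t1|E9K"]
        assert desc["t1|E9K"] == "VAR=E9K"
        assert entries["t1|E9K"] == "EKEKEKEKKK"
        ref_protein = translate("GAAAAA" * 5)
        assert ref_protein == "EKEKEKEKEK"
        assert sum(a != b for a, b in zip(entries["t1|E9K"], ref_protein)) == 1

    def test_minus_strand_consequence(self):
        gene, genome = simple_gene("-")
        # same E9K on the minus strand: CDS offset 24 -> genomic pos e - 24
        gpos = 130 - 24
        calls = pd.DataFrame(
            [{"CHROM": "chr1", "POS": gpos, "REF": "C", "ALT": "T"}]
        )  # genomic C = sense G; T = sense A
        entries, _, cons = build_variant_proteome([gene], genome, calls)
        assert [c.name for c in cons] == ["E9K"]

    def test_ref_mismatch_raises(self):
        gene, genome = simple_gene()
        calls = pd.DataFrame([{"CHROM": "chr1", "POS": 125, "REF": "T", "ALT": "A"}])
        with pytest.raises(ValueError, match="REF mismatch"):
            build_variant_proteome([gene], genome, calls)

    def test_noncoding_call_ignored(self):
        gene, genome = simple_gene()
        calls = pd.DataFrame([{"CHROM": "chr1", "POS": 50, "REF": "N", "ALT": "A"}])
        entries, _, cons = build_variant_proteome([gene], genome, calls)
        assert entries == {}

    def test_mutated_cds_roundtrip(self, small_dataset):
        # translating the mutated CDS reproduces the mutated protein
        from isocover.synth import simulate_variants

        result, tables = small_dataset
        pileup = tables["pileup"]
        entries, _, cons = build_variant_proteome(result.genes, result.genome, pileup)
        for c in cons:
            gene = result.gene(c.gene_id)
            cds = list(gene.transcript_sequence(c.transcript_id, result.genome))
            cds_idx = gene.genomic_to_cds(c.transcript_id, c.pos)
            base = c.alt if gene.strand == "+" else {"A": "T", "T": "A", "C": "G", "G": "C"}[c.alt]
            cds[cds_idx] = base
            assert translate("".join(cds)) == entries[c.entry_id]


class TestClassifySAPPeptides:
    def _setup(self):
        gene, genome = simple_gene()
        calls = pd.DataFrame([{"CHROM": "chr1", "POS": 125, "REF": "G", "ALT": "A"}])
        entries, _, cons = build_variant_proteome([gene], genome, calls)
        ref = {"t1": translate("GAAAAA" * 5)}  # EKEKEKEKEK
        return ref, entries, cons

    def test_yes_peptide(self):
        ref, entries, cons = self._setup()
        # suffix peptide carrying the K substitution at position 9: "EKEKKK"
        ev = pd.DataFrame({"sequence": [entries["t1|E9K"][4:]]})
        out = classify_sap_peptides(ev, ref, entries, cons)
        assert out.loc[0, "mutated"] == "Yes"
        summary = sap_detection_summary(out, cons)
        assert summary["proteome_detected"].tolist() == [True]

    def test_no_peptide(self):
        ref, entries, cons = self._setup()
        ev = pd.DataFrame({"sequence": ["EKEKE"]})  # matches reference only
        out = classify_sap_peptides(ev, ref, entries, cons)
        assert out.loc[0, "mutated"] == "No"
        assert not sap_detection_summary(out, cons)["proteome_detected"].any()

    def test_mixed_peptide(self):
        # a peptide covering the substituted residue that also occurs in the
        # reference elsewhere
        gene, genome = simple_gene()
        calls = pd.DataFrame([{"CHROM": "chr1", "POS": 125, "REF": "G", "ALT": "A"}])
        entries, _, cons = build_variant_proteome([gene], genome, calls)
        ref = {"t1": translate("GAAAAA" * 5), "other": "KKKK"}
        ev = pd.DataFrame({"sequence": ["KK"]})  # covers E9K site in variant entry
        out = classify_sap_peptides(ev, ref, entries, cons)
        assert out.loc[0, "mutated"] == "Mixed"

    def test_planted_saps_on_synth(self, small_dataset):
        result, tables = small_dataset
        evidence = tables["evidence"]
        passing = filter_variants(tables["pileup"])
        entries, _, cons = build_variant_proteome(result.genes, result.genome, passing)
        classified = classify_sap_peptides(evidence, result.proteome(), entries, cons)
        summary = sap_detection_summary(classified, cons)
        # oracle: a SAP is detectable iff some variant-entry peptide evidence
        # could cover it -- verify detected implies a Yes peptide covers it
        for _, row in summary[summary["proteome_detected"]].iterrows():
            entry_seq = entries[row["entry_id"]]
            aa_pos = int(row["consequence"][1:-1])
            hit = False
            yes = classified[classified["mutated"] == "Yes"]
            for _, prow in yes.iterrows():
                if row["entry_id"] in prow["entries"].split(";"):
                    start = entry_seq.find(prow["sequence"])
                    assert start != -1
                    hit = hit or (start < aa_pos <= start + len(prow["sequence"]))
            assert hit


def exact_rank_sum_oracle(x, y):
    """Exhaustive enumeration: rank sum of x and exact two-sided p-value."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    n = len(pooled)
    stats = []
    for idx in combinations(range(n), len(x)):
        stats.append(ranks[list(idx)].sum())
    stats = np.array(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12)
    return w_obs, p


class TestDeleteriousnessShift:
    def test_identical_lists(self):
        res = deleteriousness_shift([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_all_tied(self):
        res = deleteriousness_shift([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_statistic_matches_exact_enumeration(self, rng):
        for _ in range(10):
            n, m = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            res = deleteriousness_shift(x, y)
            w_oracle, p_exact = exact_rank_sum_oracle(x, y)
            assert res.statistic == pytest.approx(w_oracle)
            # normal approximation close to the exact permutation p (loose
            # for tiny n where the approximation is crude)
            assert res.p_value == pytest.approx(p_exact, abs=0.2)

    def test_simple_separation(self):
        res = deleteriousness_shift([1, 2, 3], [4, 5, 6])
        w_oracle, _ = exact_rank_sum_oracle(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert res.statistic == w_oracle == 6.0

    def test_shifted_normals_significant(self):
        gen = np.random.default_rng(99)
        x = gen.normal(0.0, 1.0, 500)
        y = gen.normal(0.5, 1.0, 500)
        assert deleteriousness_shift(x, y).p_value < 0.01

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            deleteriousness_shift([], [1.0])

    def test_category_fractions(self):
        res = deleteriousness_shift([0.01, 0.2], [0.03, 0.04])
        assert res.fractions_first["deleterious"] == pytest.approx(0.5)
        assert res.fractions_second["deleterious"] == pytest.approx(1.0)


def test_load_scores_tsv(tmp_path):
    from isocover.variants import load_scores_tsv

    p = tmp_path / "sift.tsv"
    p.write_text("variant\tscore\nE9K\t0.02\nA5T\t0.7\n")
    scores = load_scores_tsv(p)
    assert scores["E9K"] == 0.02
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\tb\tc\n1\t2\t3\n")
        load_scores_tsv(bad)
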
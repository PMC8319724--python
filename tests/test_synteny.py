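import pytest

from consynt.counterparts import STATUS_CURATED, STATUS_NONE, CounterpartAssignment
from consynt.io import GeneRecord, PhenotypeAnnotation
from consynt.synteny import (
    BlockCriteria,
    block_report,
    evaluate_block,
    find_candidates,
)


def gene(gid, chrom, start, length=10_000):
    return GeneRecord(gid, gid, "human", chrom, start, start + length - 1)


def assignment(g, counterpart):
    if counterpart is None:
        return CounterpartAssignment(g, "secondary", None, STATUS_NONE)
    return CounterpartAssignment(g, "secondary", counterpart, STATUS_CURATED)


class TestFindCandidates:
    def test_gap_rule_traced_by_hand(self):
        # gaps between consecutive intervals: 10 kb, 20 kb, 5 Mb, 15 kb
        starts = [0, 0, 0, 0, 0]
        pos = 1_000_000
        recs = []
        for i, gap in enumerate([None, 10_000, 20_000, 5_000_000, 15_000]):
            if gap is not None:
                pos += 10_000 + gap  # previous length + gap
            recs.append(gene(f"g{i}", "chr1", pos))
        del starts
        cands = find_candidates(recs, max_gap_bp=1_000_000, min_genes=3)
        assert len(cands) == 1
        assert cands[0].genes == ["g0", "g1", "g2"]

    def test_two_genes_below_min_genes(self):
        recs = [gene("a", "chr1", 100_000), gene("b", "chr1", 150_000)]
        assert find_candidates(recs, 1_000_000, min_genes=3) == []

    def test_chromosomes_never_mix(self):
        recs = [
            gene("a", "chr1", 100_000), gene("b", "chr1", 150_000),
            gene("c", "chr2", 160_000),
        ]
        assert find_candidates(recs, 10_000_000, min_genes=3) == []

    def test_no_gene_in_two_candidates(self):
        recs = [gene(f"g{i}", "chr3", 1_000_000 + i * 200_000) for i in range(10)]
        cands = find_candidates(recs, 500_000, min_genes=3)
        seen = [g for c in cands for g in c.genes]
        assert len(seen) == len(set(seen))

    def test_unsorted_input_sorted_internally(self):
        recs = [
            gene("c", "chr1", 1_300_000),
            gene("a", "chr1", 1_000_000),
            gene("b", "chr1", 1_150_000),
        ]
        (cand,) = find_candidates(recs, 1_000_000, 3)
        assert cand.genes == ["a", "b", "c"]
        assert cand.span_bp == 1_300_000 + 9_999 - 1_000_000

    @pytest.mark.parametrize("tight,loose", [(100_000, 400_000), (50_000, 5_000_000)])
    def test_shrinking_gap_never_grows_candidates(self, tight, loose):
        recs = [gene(f"g{i}", "chr1", 1_000_000 + i * 230_000) for i in range(12)]
        big = {
            tuple(c.genes): c.size for c in find_candidates(recs, loose, min_genes=1)
        }
        for c in find_candidates(recs, tight, min_genes=1):
            containing = [
                size for genes, size in big.items() if set(c.genes) <= set(genes)
            ]
            assert containing and all(c.size <= s for s in containing)

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValueError):
            find_candidates([], 0)


class TestEvaluateBlock:
    def _block(self, genes=("a", "b", "c", "d")):
        recs = [gene(g, "chr1", 1_000_000 + i * 50_000) for i, g in enumerate(genes)]
        (cand,) = find_candidates(recs, 1_000_000, min_genes=3)
        return cand

    def _secondary(self, mapping):
        return [
            GeneRecord(cp, cp, "secondary", chrom, 1_000, 2_000)
            for cp, chrom in mapping.items()
        ]

    def test_all_lethal_block_reports_4_of_4(self):
        cand = self._block()
        assignments = [assignment(g, f"t{g}") for g in cand.genes]
        secondary = self._secondary({f"t{g}": "chr9" for g in cand.genes})
        phenos = [PhenotypeAnnotation(g, ["lethal"]) for g in cand.genes]
        block = evaluate_block(cand, assignments, secondary, phenos)
        assert block.accepted
        assert block.counterpart_coverage == 1.0
        assert ("Lethal", 4, 4) in block.shared_phenotypes

    def test_partial_sharing_3_of_5(self):
        cand = self._block(genes=("a", "b", "c", "d", "e"))
        assignments = [assignment(g, f"t{g}") for g in cand.genes]
        secondary = self._secondary({f"t{g}": "chr9" for g in cand.genes})
        phenos = [
            PhenotypeAnnotation(g, ["locomotion variant"] if g in "abc" else [])
            for g in cand.genes
        ]
        block = evaluate_block(cand, assignments, secondary, phenos)
        assert ("Locomotion", 3, 5) in [
            (t, k, n) for t, k, n in block.shared_phenotypes
        ]

    def test_singleton_phenotypes_not_shared(self):
        cand = self._block()
        assignments = [assignment(g, f"t{g}") for g in cand.genes]
        secondary = self._secondary({f"t{g}": "chr9" for g in cand.genes})
        phenos = [PhenotypeAnnotation("a", ["lethal"])]
        block = evaluate_block(cand, assignments, secondary, phenos)
        assert block.shared_phenotypes == []

    def test_wide_secondary_spread_rejected(self):
        cand = self._block(genes=tuple("abcdefgh"))
        assignments = [assignment(g, f"t{g}") for g in cand.genes]
        secondary = self._secondary(
            {f"t{g}": f"chr{i + 1}" for i, g in enumerate(cand.genes)}
        )
        block = evaluate_block(cand, assignments, secondary, [])
        assert len(block.chromosomes_secondary) == 8
        assert not block.accepted

    def test_low_counterpart_coverage_rejected(self):
        cand = self._block()
        assignments = [assignment("a", "ta")] + [
            assignment(g, None) for g in ("b", "c", "d")
        ]
        secondary = self._secondary({"ta": "chr9"})
        block = evaluate_block(cand, assignments, secondary, [])
        assert block.counterpart_coverage == 0.25
        assert not block.accepted

    def test_criteria_are_parameters(self):
        cand = self._block()
        assignments = [assignment(g, f"t{g}") for g in cand.genes]
        secondary = self._secondary(
            {f"t{g}": f"chr{i % 2 + 1}" for i, g in enumerate(cand.genes)}
        )
        strict = BlockCriteria(max_secondary_chromosomes=1)
        loose = BlockCriteria(max_secondary_chromosomes=5)
        assert not evaluate_block(cand, assignments, secondary, [], strict).accepted
        assert evaluate_block(cand, assignments, secondary, [], loose).accepted


class TestBlockReport:
    def _blocks(self, n_accept, n_reject):
        blocks = []
        for i in range(n_accept + n_reject):
            genes = [f"b{i}g{j}" for j in range(3)]
            recs = [gene(g, f"chr{i % 23 + 1}", 1_000_000 + j * 50_000)
                    for j, g in enumerate(genes)]
            (cand,) = find_candidates(recs, 1_000_000, 3)
            accept = i < n_accept
            assignments = [
                assignment(g, f"t{g}" if accept else None) for g in genes
            ]
            secondary = (
                [GeneRecord(f"t{g}", f"t{g}", "s", "chr5", 1000, 2000) for g in genes]
                if accept else []
            )
            blocks.append(evaluate_block(cand, assignments, secondary, []))
        return blocks

    def test_accepted_and_audit_partition(self, tmp_path):
        blocks = self._blocks(23, 13)
        out, audit = tmp_path / "blocks.tsv", tmp_path / "audit.tsv"
        frame = block_report(blocks, path=out, audit_path=audit)
        assert len(frame) == 36
        assert frame["accepted"].sum() == 23
        accepted_rows = out.read_text().strip().splitlines()
        audit_rows = audit.read_text().strip().splitlines()
        assert len(accepted_rows) - 1 == 23
        assert len(audit_rows) - 1 == 13

    def test_empty_block_list_writes_header_only(self, tmp_path):
        out = tmp_path / "blocks.tsv"
        frame = block_report([], path=out)
        assert len(frame) == 0
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("genes\t")

    def test_row_format(self):
        blocks = self._blocks(1, 0)
        frame = block_report(blocks)
        row = frame.iloc[0]
        assert row["genes"] == "b0g0-b0g1-b0g2"
        assert row["chromosomes_secondary"] == "chr5"
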
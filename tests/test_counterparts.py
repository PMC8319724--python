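import pytest
from hypothesis import given
from hypothesis import strategies as st

from consynt.counterparts import (
    STATUS_CURATED,
    STATUS_DISTANT,
    STATUS_NONE,
    STATUS_SEARCH,
    ConfigurationError,
    CounterpartThresholds,
    HomologyHit,
    assign_counterparts,
    classify_hit,
    tally_conservation,
)
from consynt.io import RiskGeneSet, ValidationError
from consynt.simulate import SyntheticDatasetSpec, build_dataset


def hit(query="Q", species="human", subject="S", identity=40.0,
        aln=120, qlen=200, slen=210):
    return HomologyHit(query, species, subject, identity, aln, qlen, slen)


class TestClassifyHit:
    def test_high_identity_is_search_counterpart(self):
        assert classify_hit(hit(identity=40.0), []) == STATUS_SEARCH

    def test_marginal_identity_needs_convergence(self):
        marginal = hit(identity=22.0)
        assert classify_hit(marginal, []) == STATUS_NONE
        corroborating = [
            hit(species="anole", identity=24.0),
            hit(species="gar", identity=23.0),
        ]
        assert classify_hit(marginal, corroborating) == STATUS_DISTANT

    def test_convergence_must_hit_same_subject(self):
        other_subject = [hit(species="anole", subject="OTHER")]
        assert classify_hit(hit(identity=22.0), other_subject) == STATUS_NONE

    def test_below_floor_is_none(self):
        assert classify_hit(hit(identity=15.0), [hit(species="anole")]) == STATUS_NONE

    def test_distant_band_lower_edge_inclusive(self):
        assert classify_hit(hit(identity=20.0), [hit(species="gar")]) == STATUS_DISTANT

    def test_poor_coverage_fails(self):
        assert classify_hit(hit(identity=40.0, aln=50), []) == STATUS_NONE

    def test_length_ratio_out_of_bounds_fails(self):
        assert (
            classify_hit(hit(identity=40.0, qlen=900, slen=300, aln=200), [])
            == STATUS_NONE
        )

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            CounterpartThresholds(identity_distant_low=30, identity_counterpart=25)


class TestHitInvariants:
    def test_alignment_longer_than_shorter_protein_rejected(self):
        with pytest.raises(ValidationError):
            hit(aln=500, qlen=200, slen=300)

    def test_identity_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            hit(identity=101.0)


class TestAssignCounterparts:
    @pytest.fixture()
    def mixed_fixture(self):
        members = [f"g{i}" for i in range(10)]
        risk = RiskGeneSet("fix", members)
        curated = {f"g{i}": f"t{i}" for i in range(6)}
        hits = [
            hit(query="g6", subject="t6", identity=40.0),
            hit(query="g7", subject="t7", identity=30.0),
        ]
        return risk, curated, hits

    def test_status_partition_6_2_0_2(self, mixed_fixture):
        risk, curated, hits = mixed_fixture
        assignments = assign_counterparts(risk, curated, hits)
        statuses = [a.status for a in assignments]
        assert statuses.count(STATUS_CURATED) == 6
        assert statuses.count(STATUS_SEARCH) == 2
        assert statuses.count(STATUS_DISTANT) == 0
        assert statuses.count(STATUS_NONE) == 2
        assert len(assignments) == risk.size  # one per member

    def test_curated_takes_precedence_and_search_confirmation_flagged(self):
        risk = RiskGeneSet("r", ["g0"])
        hits = [hit(query="g0", subject="t0", identity=55.0)]
        (a,) = assign_counterparts(risk, {"g0": "t0"}, hits)
        assert a.status == STATUS_CURATED
        assert "search-confirmed" in a.evidence
        # conflicting search evidence never overrides the curated entry
        (b,) = assign_counterparts(
            risk, {"g0": "t0"}, [hit(query="g0", subject="tX", identity=90.0)]
        )
        assert b.counterpart_gene == "t0" and "search-confirmed" not in b.evidence

    def test_tie_break_is_order_independent(self):
        risk = RiskGeneSet("r", ["g0"])
        a = hit(query="g0", subject="tB", identity=40.0, aln=120)
        b = hit(query="g0", subject="tA", identity=40.0, aln=120)
        first = assign_counterparts(risk, {}, [a, b])[0]
        second = assign_counterparts(risk, {}, [b, a])[0]
        assert first.counterpart_gene == second.counterpart_gene == "tA"

    def test_longer_alignment_beats_subject_name(self):
        risk = RiskGeneSet("r", ["g0"])
        short = hit(query="g0", subject="tA", identity=40.0, aln=110)
        long = hit(query="g0", subject="tB", identity=40.0, aln=130)
        (a,) = assign_counterparts(risk, {}, [short, long])
        assert a.counterpart_gene == "tB"

    @given(perm=st.permutations(range(4)))
    def test_assignment_invariant_under_hit_row_permutation(self, perm):
        risk = RiskGeneSet("r", ["g0", "g1"])
        hits = [
            hit(query="g0", subject="tA", identity=40.0),
            hit(query="g0", subject="tB", identity=35.0),
            hit(query="g1", subject="tC", identity=22.0),
            hit(query="g1", species="anole", subject="tC", identity=23.0),
        ]
        shuffled = [hits[i] for i in perm]
        base = assign_counterparts(risk, {}, hits)
        other = assign_counterparts(risk, {}, shuffled)
        assert [(a.counterpart_gene, a.status) for a in base] == [
            (a.counterpart_gene, a.status) for a in other
        ]

    def test_proxy_query_supported_and_flagged(self):
        risk = RiskGeneSet("r", ["g0"])
        hits = [hit(query="g0para", subject="t0", identity=45.0)]
        (a,) = assign_counterparts(
            risk, {}, hits, proxy_queries={"g0": "g0para"}
        )
        assert a.status == STATUS_SEARCH
        assert any(e.startswith("proxy-query") for e in a.evidence)

    @pytest.mark.parametrize("threshold", [25.0, 30.0, 41.0])
    def test_raising_counterpart_threshold_never_adds_search_hits(self, threshold):
        risk = RiskGeneSet("r", [f"g{i}" for i in range(5)])
        hits = [
            hit(query=f"g{i}", subject=f"t{i}", identity=idt)
            for i, idt in enumerate([22.0, 28.0, 33.0, 40.0, 55.0])
        ]
        base = assign_counterparts(risk, {}, hits)
        n_base = sum(a.status == STATUS_SEARCH for a in base)
        raised = assign_counterparts(
            risk, {}, hits,
            thresholds=CounterpartThresholds(identity_counterpart=threshold),
        )
        assert sum(a.status == STATUS_SEARCH for a in raised) <= n_base


class TestTallyConservation:
    def test_paper_counts_give_expected_percentages(self, paper_fixture):
        worm = tally_conservation(paper_fixture.assignments("celegans"))
        fish = tally_conservation(paper_fixture.assignments("zebrafish"))
        assert (worm.with_counterpart, worm.total) == (276, 336)
        assert round(worm.percent, 1) == 82.1
        assert (fish.with_counterpart, fish.total) == (324, 336)
        assert round(fish.percent, 1) == 96.4

    def test_all_none_gives_zero(self):
        risk = RiskGeneSet("r", [f"g{i}" for i in range(10)])
        assignments = assign_counterparts(risk, {}, [])
        assert tally_conservation(assignments).fraction == 0.0

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            tally_conservation([])

    def test_recovers_planted_rate_exactly_on_noise_free_data(self):
        # curated lookup built directly from the generator's counterpart map:
        # the tally must equal the realized planted rate, no estimation error
        spec = SyntheticDatasetSpec(seed=5, n_genes_primary=800, risk_set_size=200)
        ds = build_dataset(spec)
        tally = tally_conservation(ds.assignments())
        realized = sum(g in ds.counterparts for g in ds.risk_set.members)
        assert tally.with_counterpart == realized
        assert tally.total == 200
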
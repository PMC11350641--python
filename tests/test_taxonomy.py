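import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trophicniche.io_model import (
    AbundanceTable,
    RunConfig,
    SampleMetadata,
    TaxonRecord,
    ValidationError,
)
from trophicniche.taxonomy import (
    aggregate_to_rank,
    apply_rank_resolution,
    group_composition,
    resolve_rank_assignment,
    top_k_items,
)
from tests.conftest import make_profile


class TestRankResolution:
    @pytest.mark.parametrize(
        "identity,single,expected",
        [
            (99.5, True, "species"),
            (98.5, None, "genus"),
            (99.5, False, "genus"),  # species rule needs a unique best hit
            (97.0, None, "unresolved_below_genus"),
            (99.0, True, "species"),  # at the species threshold
            (98.0, True, "unresolved_below_genus"),  # genus rule is strict
        ],
    )
    def test_identity_rule(self, cfg, identity, single, expected):
        t = TaxonRecord("t", best_identity_pct=identity, single_best_hit=single)
        assert resolve_rank_assignment(t, cfg) == expected

    def test_local_distribution_vetoes_species(self, cfg):
        t = TaxonRecord("t", best_identity_pct=99.5, single_best_hit=True,
                        locally_distributed=False)
        assert resolve_rank_assignment(t, cfg) == "genus"

    def test_unscored_passes_through_at_deepest_rank(self, cfg):
        t = TaxonRecord("t", lineage={"kingdom": "A", "phylum": "P", "class": "C"})
        assert resolve_rank_assignment(t, cfg) == "unscored:class"

    @settings(max_examples=50, deadline=None)
    @given(lo=st.floats(0, 100), hi=st.floats(0, 100))
    def test_monotone_in_identity(self, lo, hi):
        """Raising identity never yields a shallower rank."""
        cfg = RunConfig()
        lo, hi = min(lo, hi), max(lo, hi)
        depth = {"unresolved_below_genus": 0, "genus": 1, "species": 2}
        r_lo = resolve_rank_assignment(
            TaxonRecord("t", best_identity_pct=lo, single_best_hit=True), cfg)
        r_hi = resolve_rank_assignment(
            TaxonRecord("t", best_identity_pct=hi, single_best_hit=True), cfg)
        assert depth[r_hi] >= depth[r_lo]


class TestAggregation:
    def test_same_order_counts_add(self, small_table, cfg):
        agg = aggregate_to_rank(small_table, "order", cfg)
        assert agg.taxon_ids() == ["Lepidoptera", "Diptera"]
        assert np.array_equal(agg.counts, [[12, 3], [2, 8]])

    def test_unresolved_taxon_pools_into_unassigned_at_genus(self, cfg):
        taxa = [
            TaxonRecord("t1", lineage={"kingdom": "A", "phylum": "P", "class": "C",
                                       "order": "O", "family": "F", "genus": "G"},
                        best_identity_pct=98.5),
            TaxonRecord("t2", lineage={"kingdom": "A", "phylum": "P", "class": "C",
                                       "order": "O", "family": "F", "genus": "G2"},
                        best_identity_pct=97.0),
        ]
        table = AbundanceTable(["s1"], taxa, np.array([[4, 6]]))
        resolved = apply_rank_resolution(table, cfg)
        at_order = aggregate_to_rank(resolved, "order", cfg)
        assert at_order.taxon_ids() == ["O"] and at_order.counts[0, 0] == 10
        at_genus = aggregate_to_rank(resolved, "genus", cfg)
        assert dict(zip(at_genus.taxon_ids(), at_genus.counts[0])) == {
            "G": 4, "Unassigned@genus": 6,
        }

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_read_conservation_over_random_tables(self, seed):
        """Per-sample totals are identical before and after aggregation at
        every rank."""
        cfg = RunConfig()
        rng = np.random.default_rng(seed)
        n_taxa, n_samples = 12, 4
        taxa = [
            TaxonRecord(
                f"t{j}",
                lineage={"kingdom": "K", "phylum": f"P{j % 2}", "class": f"C{j % 3}",
                         "order": f"O{j % 4}", "family": f"F{j % 6}",
                         "genus": f"G{j}"} if j % 5 else {"kingdom": "K"},
            )
            for j in range(n_taxa)
        ]
        counts = rng.integers(0, 50, size=(n_samples, n_taxa))
        counts[:, 0] += 1
        table = AbundanceTable([f"s{i}" for i in range(n_samples)], taxa, counts)
        for rank in ("phylum", "class", "order", "family", "genus"):
            agg = aggregate_to_rank(table, rank, cfg)
            assert np.array_equal(agg.counts.sum(axis=1), counts.sum(axis=1))


class TestGroupComposition:
    def _table(self, counts, samples, genus_names):
        taxa = [
            TaxonRecord(g, lineage={"kingdom": "K", "phylum": "P", "class": "C",
                                    "order": "O", "family": "F", "genus": g})
            for g in genus_names
        ]
        return AbundanceTable(samples, taxa, np.asarray(counts))

    def test_single_sample_proportions(self, cfg):
        table = self._table([[45, 30, 25]], ["s1"], ["a", "b", "c"])
        meta = [SampleMetadata("s1", "A", 2000, "COI")]
        prof = group_composition(table, meta, "A", cfg)
        assert np.allclose(prof.proportions, [0.45, 0.30, 0.25])

    def test_pooling_sums_counts_across_samples(self, cfg):
        table = self._table([[10, 0], [0, 10]], ["s1", "s2"], ["a", "b"])
        meta = [SampleMetadata(s, "A", 2000, "COI") for s in ("s1", "s2")]
        prof = group_composition(table, meta, "A", cfg)
        assert np.allclose(prof.proportions, [0.5, 0.5])

    def test_printed_top_three_echoed(self, cfg):
        """A fixture built from printed top-genus relative abundances
        (45.48 / 21.76 / 17.84 %) reproduces those proportions."""
        counts = [[4548, 2176, 1784, 1492]]
        table = self._table(counts, ["s1"], ["Arum", "Frangula", "Graphephorum", "Rest"])
        meta = [SampleMetadata("s1", "Apodemus chevrieri", 2800, "RbcL")]
        prof = group_composition(table, meta, "Apodemus chevrieri", cfg)
        got = prof.as_dict()
        assert got["Arum"] == pytest.approx(0.4548)
        assert got["Frangula"] == pytest.approx(0.2176)
        assert got["Graphephorum"] == pytest.approx(0.1784)

    def test_scale_invariance(self, cfg):
        table1 = self._table([[3, 5, 2]], ["s1"], ["a", "b", "c"])
        table2 = self._table([[30, 50, 20]], ["s1"], ["a", "b", "c"])
        meta = [SampleMetadata("s1", "A", 2000, "COI")]
        p1 = group_composition(table1, meta, "A", cfg)
        p2 = group_composition(table2, meta, "A", cfg)
        assert np.allclose(p1.proportions, p2.proportions)

    def test_unknown_group_rejected(self, small_table, small_metadata, cfg):
        with pytest.raises(ValidationError):
            group_composition(small_table, small_metadata, "nope", cfg)


class TestTopK:
    def test_remainder_pools_into_other(self):
        p = np.arange(1, 21, dtype=float)
        prof = make_profile(p / p.sum())
        top = top_k_items(prof, 15)
        assert len(top.items) == 16 and top.items[-1] == "Other"
        assert top.proportions.sum() == pytest.approx(1.0)
        assert top.proportions[-1] == pytest.approx(p[:5].sum() / p.sum())

    def test_k_at_least_item_count_has_no_other(self):
        prof = make_profile([0.5, 0.3, 0.2])
        top = top_k_items(prof, 5)
        assert "Other" not in top.items and len(top.items) == 3

    def test_ties_resolved_lexicographically(self):
        prof = make_profile([0.25, 0.25, 0.25, 0.25], items=("d", "b", "c", "a"))
        top = top_k_items(prof, 2)
        assert top.items[:2] == ("a", "b")

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValidationError):
            top_k_items(make_profile([1.0]), 0)
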
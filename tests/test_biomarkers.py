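import numpy as np
import pytest

from trophicniche.biomarkers import lefse_biomarkers, pairwise_wilcoxon
from trophicniche.io_model import (
    AbundanceTable,
    RunConfig,
    SampleMetadata,
    TaxonRecord,
    ValidationError,
)
from trophicniche.synthetic_data import SyntheticDietSpec, generate_dataset


def make_dataset(rng, n_per_group=10, n_features=30, planted=None, fold=16.0,
                 groups=("A", "B")):
    """Dirichlet-multinomial counts for several groups with optionally
    planted enriched features in the last group."""
    planted = planted or []
    base = rng.dirichlet(np.ones(n_features) * 2.0)
    comp = {g: base.copy() for g in groups}
    last = groups[-1]
    for j in planted:
        comp[last][j] *= fold
    comp[last] /= comp[last].sum()
    taxa = [
        TaxonRecord(f"G{j}", lineage={"kingdom": "K", "phylum": f"P{j % 3}",
                                      "class": f"C{j % 5}", "order": f"O{j % 8}",
                                      "family": f"F{j % 15}", "genus": f"G{j}"})
        for j in range(n_features)
    ]
    rows, samples, meta = [], [], []
    for g in groups:
        for i in range(n_per_group):
            sid = f"{g}{i}"
            p = rng.dirichlet(comp[g] * 300)
            rows.append(rng.multinomial(50_000, p))
            samples.append(sid)
            meta.append(SampleMetadata(sid, g, 2000, "COI"))
    counts = np.asarray(rows)
    counts[:, 0] += 1
    return AbundanceTable(samples, taxa, counts), meta


class TestPairwiseWilcoxon:
    def test_exact_p_for_separated_triples(self):
        p, direction = pairwise_wilcoxon([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert direction == -1

    def test_identical_samples_p_one(self):
        p, direction = pairwise_wilcoxon([2, 2, 2], [2, 2, 2])
        assert p == 1.0 and direction == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_wilcoxon([], [1])

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        """At n=10 per group the normal approximation tracks the exact
        enumeration within 0.02."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(21)
        for _ in range(25):
            a = rng.normal(size=10)
            b = rng.normal(0.5, 1.0, size=10)
            exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            asym = mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic").pvalue
            assert abs(exact - asym) < 0.02


class TestLefse:
    def test_planted_sixteen_fold_feature_recovered(self):
        rng = np.random.default_rng(22)
        table, meta = make_dataset(rng, planted=[4], fold=16.0)
        recs = lefse_biomarkers(table, meta, RunConfig(), ranks=("genus",))
        by_feature = {r.feature: r for r in recs}
        hit = by_feature["G4"]
        assert hit.passed and hit.kw_p < 0.05 and hit.enriched_group == "B"
        assert hit.lda_score >= 2.0

    def test_identical_feature_never_passes(self):
        """A feature with the same relative abundance in every sample is
        screened out and cannot pass."""
        rng = np.random.default_rng(23)
        taxa = [TaxonRecord(f"G{j}", lineage={"kingdom": "K", "phylum": "P",
                                              "class": "C", "order": "O",
                                              "family": "F", "genus": f"G{j}"},
                            unresolved_gap=True)
                for j in range(3)]
        base = np.array([1, 2, 7])
        depths = rng.integers(1, 20, size=8)
        counts = np.outer(depths, base)  # identical proportions everywhere
        samples = [f"s{i}" for i in range(8)]
        meta = [SampleMetadata(s, "A" if i < 4 else "B", 2000, "COI")
                for i, s in enumerate(samples)]
        table = AbundanceTable(samples, taxa, counts)
        recs = lefse_biomarkers(table, meta, RunConfig(), ranks=("genus",))
        assert not any(r.passed for r in recs)
        assert recs == []  # constant features are skipped entirely

    def test_null_false_positive_rate_below_alpha(self):
        """On label-permuted null data the expected fraction of passing
        features stays at or below alpha (200 replicates)."""
        rng = np.random.default_rng(24)
        cfg = RunConfig()
        total = passed = 0
        for _ in range(200):
            table, meta = make_dataset(rng, n_per_group=5, n_features=15,
                                       groups=("A", "B", "C"))
            # shuffle group labels to enforce the null
            labels = [m.consumer_species for m in meta]
            rng.shuffle(labels)
            meta = [
                SampleMetadata(m.sample_id, lab, m.elevation_m, m.marker)
                for m, lab in zip(meta, labels)
            ]
            recs = lefse_biomarkers(table, meta, cfg, ranks=("genus",))
            total += len(recs)
            passed += sum(r.passed for r in recs)
        assert passed / total <= cfg.alpha

    def test_per_sample_rescaling_leaves_outputs_unchanged(self):
        """Multiplying all counts of one sample by a constant changes no
        biomarker record (per-sample normalisation)."""
        rng = np.random.default_rng(25)
        table, meta = make_dataset(rng, n_per_group=4, n_features=12)
        scaled_counts = table.counts.copy()
        scaled_counts[0] *= 7
        scaled = AbundanceTable(table.samples, table.taxa, scaled_counts)
        a = lefse_biomarkers(table, meta, RunConfig(), ranks=("genus", "order"))
        b = lefse_biomarkers(scaled, meta, RunConfig(), ranks=("genus", "order"))
        assert [(r.feature, r.rank, round(r.lda_score, 9), r.passed) for r in a] == [
            (r.feature, r.rank, round(r.lda_score, 9), r.passed) for r in b
        ]

    def test_effect_size_monotone_in_planted_fold(self):
        """Median recovered effect size never decreases as the planted fold
        grows."""
        rng = np.random.default_rng(26)
        medians = []
        for fold in (2.0, 4.0, 8.0, 16.0):
            scores = []
            for _ in range(10):
                table, meta = make_dataset(rng, n_per_group=6, n_features=15,
                                           planted=[3], fold=fold)
                recs = lefse_biomarkers(table, meta, RunConfig(), ranks=("genus",))
                rec = {r.feature: r for r in recs}.get("G3")
                scores.append(rec.lda_score if rec and np.isfinite(rec.lda_score)
                              else 0.0)
            medians.append(np.median(scores))
        assert all(b >= a - 0.15 for a, b in zip(medians, medians[1:]))

    def test_infinite_cutoff_passes_nothing(self):
        rng = np.random.default_rng(27)
        table, meta = make_dataset(rng, planted=[1], fold=16.0)
        recs = lefse_biomarkers(table, meta, RunConfig(lda_cutoff=float("inf")),
                                ranks=("genus",))
        assert not any(r.passed for r in recs)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(28)
        table, meta = make_dataset(rng, n_per_group=3)
        meta = [SampleMetadata(m.sample_id, "A", m.elevation_m, m.marker)
                for m in meta]
        with pytest.raises(ValidationError):
            lefse_biomarkers(table, meta, RunConfig())

    def test_small_groups_warn(self):
        rng = np.random.default_rng(29)
        table, meta = make_dataset(rng, n_per_group=2, n_features=8)
        with pytest.warns(UserWarning, match="fewer than 3"):
            lefse_biomarkers(table, meta, RunConfig(), ranks=("genus",))

    def test_planted_biomarkers_recovered_from_generator(self):
        """End-to-end: folds planted by the synthetic generator are found
        with high sensitivity and low false-positive rate."""
        found = 0
        fp = total_null = 0
        n_reps = 20
        for seed in range(n_reps):
            spec = SyntheticDietSpec(
                elevations=tuple(range(2000, 4000, 200)),  # 10 samples/group
                missing_cells=(),
                planted_biomarkers=(("Genus050", "Apodemus ilex", 6.0),),
                rng_seed=seed,
            )
            table, meta, truth = generate_dataset(spec)
            recs = lefse_biomarkers(table, meta, RunConfig(), ranks=("genus",))
            by_feature = {r.feature: r for r in recs}
            rec = by_feature.get("Genus050")
            if rec and rec.passed and rec.enriched_group == "Apodemus ilex":
                found += 1
        assert found / n_reps >= 0.9
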
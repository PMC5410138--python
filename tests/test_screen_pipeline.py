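"""Sample screening, dedup, densities, statistics and method overlap."""

import numpy as np
import pandas as pd
import pytest

from _oracles import exact_ranksum_p
from hmmscreen import screen_pipeline as sp
from hmmscreen import search_engine as se
from hmmscreen import synthetic_data as sd
from hmmscreen.screen_pipeline import (
    DegenerateDataError,
    SampleSummary,
    compare_densities,
    dedup_hits,
    density_table,
    method_overlap,
    oral_stool_densities,
    screen_sample,
)
from hmmscreen.search_engine import Hit


def make_hit(contig, start, end, ev, frame=1, target="t"):
    return Hit(
        model_name="m", target_id=target, bit_score=10.0, evalue=ev,
        ali_start=1, ali_end=5, contig_id=contig, frame=frame,
        nt_start=start, nt_end=end,
    )


class TestDedup:
    def test_overlapping_frames_keep_best_evalue(self):
        h1 = make_hit("c1", 100, 400, 1e-40, frame=1)
        h2 = make_hit("c1", 399, 700, 1e-7, frame=2)
        kept = dedup_hits([h2, h1])
        assert len(kept) == 1 and kept[0].evalue == 1e-40

    def test_disjoint_intervals_both_kept(self):
        h1 = make_hit("c1", 100, 200, 1e-10)
        h2 = make_hit("c1", 300, 400, 1e-8)
        assert len(dedup_hits([h1, h2])) == 2

    def test_different_contigs_never_collapse(self):
        h1 = make_hit("c1", 100, 200, 1e-10)
        h2 = make_hit("c2", 100, 200, 1e-8)
        assert len(dedup_hits([h1, h2])) == 2


class TestSampleSummary:
    def test_density_arithmetic(self):
        s = SampleSummary("s", "Stool", n_hits=10, assembly_mb=2.0)
        assert s.density == pytest.approx(5.0)
        assert s.has_hit

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SampleSummary("s", "Stool", n_hits=1, assembly_mb=0.0)
        with pytest.raises(ValueError):
            SampleSummary("s", "Stool", n_hits=-1, assembly_mb=1.0)


class TestDensityTable:
    def test_fraction_with_hit(self):
        sums = [
            SampleSummary("a", "Stool", 2, 1.0),
            SampleSummary("b", "Stool", 1, 1.0),
            SampleSummary("c", "Stool", 0, 1.0),
        ]
        table = density_table(sums)
        assert table.loc["Stool", "pct_with_hit"] == pytest.approx(100 * 2 / 3)
        assert table.loc["Stool", "total_hits"] == 3

    def test_single_sample_group_mean_is_its_density(self):
        sums = [SampleSummary("a", "Saliva", 4, 2.0), SampleSummary("b", "Stool", 0, 1.0)]
        table = density_table(sums)
        assert table.loc["Saliva", "mean_density"] == pytest.approx(2.0)

    def test_unknown_site_warned_and_grouped_other(self):
        sums = [SampleSummary("a", "Elbow", 1, 1.0), SampleSummary("b", "Stool", 0, 1.0)]
        with pytest.warns(UserWarning, match="unknown body site"):
            table = density_table(sums)
        assert "other" in table.index

    def test_pooled_oral_is_eight_non_stool_sites(self):
        assert len(sp.ORAL_SITES) == 8 and "Stool" not in sp.ORAL_SITES
        sums = [SampleSummary("a", site, 1, 1.0) for site in sp.BODY_SITES]
        oral, stool = oral_stool_densities(sums)
        assert len(oral) == 8 and len(stool) == 1

    def test_totals_match_sample_sums(self):
        rng = np.random.default_rng(3)
        sums = [
            SampleSummary(f"s{i}", rng.choice(sp.BODY_SITES), int(rng.integers(0, 5)), 1.0)
            for i in range(30)
        ]
        table = density_table(sums)
        assert table.total_hits.sum() == sum(s.n_hits for s in sums)
        assert ((table.pct_with_hit >= 0) & (table.pct_with_hit <= 100)).all()


class TestCompareDensities:
    def test_exact_toy_case(self):
        res = compare_densities([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.test_name == "wilcoxon_rank_sum"

    def test_exact_agrees_with_enumeration_up_to_n8(self):
        rng = np.random.default_rng(7)
        for na in range(2, 5):
            for nb in range(2, 9 - na):
                for _ in range(4):
                    vals = rng.permutation(rng.uniform(0, 1, na + nb))
                    x, y = list(vals[:na]), list(vals[na:])
                    assert compare_densities(x, y).p_value == pytest.approx(
                        exact_ranksum_p(x, y), abs=1e-12
                    )

    def test_identical_groups_no_evidence(self):
        res = compare_densities([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value >= 0.99

    def test_welch_separated_groups(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1e-9, 4)
        b = 1 + rng.normal(0, 1e-9, 4)
        res = compare_densities(a, b, test="welch_t")
        assert res.p_value < 1e-6

    def test_degenerate_data_raises(self):
        with pytest.raises(DegenerateDataError):
            compare_densities([2.0, 2.0], [2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_densities([1.0], [2.0, 3.0])

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(13)
        a = list(rng.normal(0, 1, 30))
        b = list(rng.normal(1.5, 1, 30))
        res = compare_densities(a, b)
        assert res.p_value < 1e-4


class TestMethodOverlap:
    @staticmethod
    def table(rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "contig_id", "nt_start", "nt_end"]
        )

    def test_two_method_partition(self):
        h1 = ("s1", "c1", 100, 400)
        h2 = ("s1", "c2", 100, 400)
        h3 = ("s1", "c3", 100, 400)
        ov = method_overlap({"A": self.table([h1, h2]), "B": self.table([h2, h3])})
        counts = ov.region_counts
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"B"})] == 1
        assert counts[frozenset({"A", "B"})] == 1

    def test_three_identical_tables_all_triple(self):
        rows = [("s1", "c1", 1, 300), ("s1", "c2", 50, 500)]
        tables = {m: self.table(rows) for m in ("A", "B", "C")}
        ov = method_overlap(tables)
        assert ov.region_counts == {frozenset({"A", "B", "C"}): 2}

    def test_disjoint_tables_only_unique_regions(self):
        ov = method_overlap(
            {
                "A": self.table([("s1", "c1", 1, 300)]),
                "B": self.table([("s2", "c1", 1, 300)]),
            }
        )
        assert set(ov.region_counts) == {frozenset({"A"}), frozenset({"B"})}

    def test_totals_equal_method_hit_counts(self):
        a = self.table([("s1", "c1", 1, 300), ("s1", "c2", 1, 300)])
        b = self.table([("s1", "c1", 100, 380), ("s1", "c9", 1, 200)])
        ov = method_overlap({"A": a, "B": b})
        assert ov.total_for("A") == 2 and ov.total_for("B") == 2

    def test_below_half_overlap_is_distinct(self):
        # 100 bp shared of a 300 bp hit: 33% of the shorter -> distinct loci
        a = self.table([("s1", "c1", 1, 300)])
        b = self.table([("s1", "c1", 201, 500)])
        ov = method_overlap({"A": a, "B": b})
        assert frozenset({"A", "B"}) not in ov.region_counts

    def test_within_method_duplicates_collapse_with_warning(self):
        a = self.table([("s1", "c1", 1, 300), ("s1", "c1", 10, 310)])
        b = self.table([("s1", "c9", 1, 100)])
        with pytest.warns(UserWarning, match="duplicate"):
            ov = method_overlap({"A": a, "B": b})
        assert ov.total_for("A") == 1


class TestScreenSample:
    def test_implants_recovered_and_density(self, family_setup):
        ancestor, _, model = family_setup
        implants = [sd.diverge(ancestor, 0.2, seed=600 + i) for i in range(3)]
        for i, p in enumerate(implants):
            p.id = f"imp{i}"
        cfg = sd.SimConfig(
            seed=61, n_contigs=8, contig_length_mean=4000,
            implant_positions=[(0, 500, 1, 0), (2, 800, -1, 1), (5, 100, 1, 2)],
        )
        contigs, truth = sd.make_metagenome(cfg, implants)
        summary, hits = screen_sample(
            model, contigs, site="Stool", search_config=se.SearchConfig(), sample_id="sim"
        )
        assert summary.n_hits == 3
        assert sorted(h.contig_id for h in hits) == sorted(truth.contig_id)
        total_nt = sum(len(c) for c in contigs)
        assert summary.density == pytest.approx(3 / (total_nt / 1e6))
        # each hit's translated segment overlaps its implanted CDS; the
        # segment may extend upstream of the gene (no in-frame stop there)
        by_contig = truth.set_index("contig_id")
        for h in hits:
            row = by_contig.loc[h.contig_id]
            overlap = min(h.nt_end, row.nt_end) - max(h.nt_start, row.nt_start) + 1
            assert overlap >= 0.8 * (row.nt_end - row.nt_start + 1)

    def test_empty_assembly_raises(self, family_setup):
        *_, model = family_setup
        with pytest.raises(ValueError, match="empty assembly"):
            screen_sample(model, [], site="Stool", sample_id="s0")

    def test_deterministic_tsv_output(self, family_setup, tmp_path):
        ancestor, _, model = family_setup
        imp = sd.diverge(ancestor, 0.2, seed=700)
        cfg = sd.SimConfig(seed=71, n_contigs=4, contig_length_mean=3000,
                           implant_positions=[(1, 200, 1, 0)])
        contigs, _ = sd.make_metagenome(cfg, [imp])
        outs = []
        for run in (1, 2):
            _, hits = screen_sample(
                model, contigs, site="Stool",
                search_config=se.SearchConfig(), sample_id="sim",
            )
            path = tmp_path / f"hits{run}.tsv"
            sp.write_hits_tsv(hits, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]


class TestScreenGenomes:
    def test_synthetic_genome_density(self, family_setup):
        ancestor, _, model = family_setup
        implants = [sd.diverge(ancestor, 0.2, seed=800 + i) for i in range(2)]
        genomes = []
        total_nt = 0
        for g in range(2):
            cfg = sd.SimConfig(
                seed=81 + g, n_contigs=3, contig_length_mean=5000,
                implant_positions=[(0, 1000, 1, 0)] if g == 0 else [(1, 500, -1, 1)],
            )
            contigs, _ = sd.make_metagenome(cfg, implants)
            genomes.append(contigs)
            total_nt += sum(len(c) for c in contigs)
        hits, density = sp.screen_genomes(model, genomes, se.SearchConfig())
        assert len(hits) == 2
        assert density == pytest.approx(2 / (total_nt / 1e6))

    def test_paper_scale_ratio(self):
        # seven detections over a 1,166.67 Mb database print as 0.006 hits/Mb
        s = SampleSummary("hmrgd", "Stool", n_hits=7, assembly_mb=7 / 0.006)
        assert round(s.density, 3) == 0.006
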
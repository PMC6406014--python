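"""Tests of the de novo RAD locus pipeline."""

import math
from fractions import Fraction

import numpy as np
import pytest

from radpheno import radloci, simdata
from radpheno.radloci import (
    Marker,
    SiteTable,
    cluster_within_individual,
    dedup_exact,
    demultiplex_and_cutsite_filter,
    filter_short_reads,
    filter_sites,
    hwe_exact_het_excess,
    mask_and_filter_markers,
    remove_paralogs_self_match,
    build_pseudo_reference,
    run_pipeline,
)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class TestDemultiplex:
    BARCODES = {"AAAAAAAA": "ind1", "CCCCTTTT": "ind2", "GGGGCCCC": "ind3"}

    def test_exact_barcode_and_cutsite_assigned(self):
        reads = ["AAAAAAAA" + "TGCAGG" + "ACGT" * 20]
        out, stats = demultiplex_and_cutsite_filter(reads, self.BARCODES)
        assert len(out["ind1"]) == 1
        assert out["ind1"][0].startswith("TGCAGG")
        assert stats.assigned == 1

    def test_one_mismatch_tolerated_two_rejected(self):
        ok = "AAAAAAAT" + "TGCAGG" + "A" * 50
        bad = "AAAAAATT" + "TGCAGG" + "A" * 50
        out, stats = demultiplex_and_cutsite_filter([ok, bad], self.BARCODES)
        assert len(out["ind1"]) == 1
        assert stats.unassigned_barcode == 1

    def test_cutsite_mismatch_over_one_dropped(self):
        bad = "AAAAAAAA" + "TGTTGG" + "A" * 50  # two mismatches
        ok = "AAAAAAAA" + "TGCAGC" + "A" * 50  # one mismatch
        out, stats = demultiplex_and_cutsite_filter([bad, ok], self.BARCODES)
        assert stats.failed_cut_site == 1
        assert len(out["ind1"]) == 1

    def test_too_close_barcode_set_rejected(self):
        with pytest.raises(ValueError, match="Hamming"):
            demultiplex_and_cutsite_filter([], {"AAAAAAAA": "a", "AAAAAAAT": "b"})

    def test_simulated_assignment_is_perfect_without_errors(self, small_scenario):
        reads, truth = simdata.simulate_reads(small_scenario)
        pooled = [r for ind in reads for r in reads[ind]]
        out, stats = demultiplex_and_cutsite_filter(pooled, truth.barcode_map)
        assert stats.assigned == len(pooled)
        assert stats.unassigned_barcode == stats.failed_cut_site == 0
        for ind, seqs in reads.items():
            assert len(out[ind]) == len(seqs)


class TestDedup:
    def test_unique_input_unchanged(self):
        seqs = ["ACGT", "TTTT", "GGGG"]
        assert dedup_exact(seqs) == seqs

    def test_copies_collapse_to_first(self):
        assert dedup_exact(["AAAA"] * 7 + ["CCCC"]) == ["AAAA", "CCCC"]

    def test_survivors_match_truth_unique_count(self):
        mf = simdata.make_manifest_fixture().head(4).copy()
        sc = simdata.SimScenario(
            manifest=mf, seed=9, n_loci=20, mean_coverage=8.0, duplicate_rate=0.5
        )
        reads, truth = simdata.simulate_reads(sc)
        pooled = [r for ind in reads for r in reads[ind]]
        out, _ = demultiplex_and_cutsite_filter(pooled, truth.barcode_map)
        bc_len = len(next(iter(truth.barcode_map)))
        for ind in out:
            # truth counts distinct full reads; compare after stripping barcode
            expect = len({r[bc_len:] for r in reads[ind]})
            assert len(dedup_exact(out[ind])) == expect


class TestClustering:
    def test_identical_reads_form_one_marker(self):
        markers = cluster_within_individual(["ACGTACGTAC" * 6] * 10, "x")
        assert len(markers) == 1
        assert markers[0].supporting_read_count == 10

    def test_diverged_loci_stay_separate(self):
        rng = np.random.default_rng(7)
        a = random_seq(rng, 100)
        b = list(a)
        for pos in rng.choice(100, size=20, replace=False):  # 80% identity
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        markers = cluster_within_individual([a] * 5 + [b] * 5, "x")
        assert len(markers) == 2

    def test_singleton_not_retained(self):
        assert cluster_within_individual(["ACGT" * 25], "x") == []

    def test_raising_identity_never_decreases_marker_count(self):
        rng = np.random.default_rng(8)
        reads = []
        for _ in range(10):
            base = random_seq(rng, 80)
            reads += [base] * 2
            mut = list(base)
            mut[5] = "A" if mut[5] != "A" else "C"
            reads += ["".join(mut)] * 2
        counts = [
            len(cluster_within_individual(reads, "x", identity=i))
            for i in (0.80, 0.90, 0.95, 0.999)
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestMasking:
    def mk(self, seq):
        return Marker("x", seq, supporting_read_count=2)

    def test_balanced_sequence_untouched(self):
        m = mask_and_filter_markers([self.mk("ACGT" * 25)])
        assert m[0].representative_sequence == "ACGT" * 25
        assert m[0].n_fraction == 0.0

    def test_pure_dinucleotide_repeat_masked_and_dropped(self):
        assert mask_and_filter_markers([self.mk("AT" * 50)]) == []

    def test_homopolymer_masked(self):
        seq = "ACGTCGTACG" + "A" * 12 + "CGTACGTACG" * 3
        (m,) = mask_and_filter_markers([self.mk(seq)])
        assert "A" * 12 not in m.representative_sequence
        assert "N" * 12 in m.representative_sequence

    def test_n_fraction_boundary(self):
        base = "ACGTCGTAGC" * 7  # 70 informative bases
        dropped = mask_and_filter_markers([self.mk(base + "N" * 32)])  # 31.4% N
        kept = mask_and_filter_markers([self.mk(base + "N" * 30)])  # 30% N
        assert dropped == []
        assert len(kept) == 1


class TestParalogRemoval:
    def test_unrelated_markers_retained(self):
        rng = np.random.default_rng(9)
        markers = [Marker("x", random_seq(rng, 100), 2) for _ in range(6)]
        assert len(remove_paralogs_self_match(markers)) == 6

    def test_98_percent_pair_both_removed(self):
        rng = np.random.default_rng(10)
        a = random_seq(rng, 100)
        b = list(a)
        for pos in (3, 50):
            b[pos] = "A" if b[pos] != "A" else "G"
        markers = [Marker("x", a, 2), Marker("x", "".join(b), 2)]
        assert remove_paralogs_self_match(markers) == []
        assert all(m.paralog for m in markers)

    def test_single_marker_retained(self):
        m = Marker("x", "ACGT" * 30, 2)
        assert remove_paralogs_self_match([m]) == [m]


class TestPseudoReference:
    def test_shared_locus_retained_rare_locus_dropped(self):
        rng = np.random.default_rng(11)
        shared = random_seq(rng, 90)
        rare = random_seq(rng, 90)
        markers = {
            f"i{k}": [Marker(f"i{k}", shared, 3)] for k in range(10)
        }
        for k in range(5):  # 50% share < 60% threshold
            markers[f"i{k}"].append(Marker(f"i{k}", rare, 3))
        catalog = build_pseudo_reference(markers)
        assert len(catalog) == 1
        assert catalog[0].representative_sequence == shared

    def test_min_share_monotonicity(self):
        rng = np.random.default_rng(12)
        markers = {f"i{k}": [] for k in range(10)}
        for j in range(8):
            seq = random_seq(rng, 80)
            for k in range(rng.integers(4, 11)):
                markers[f"i{k}"].append(Marker(f"i{k}", seq, 2))
        sizes = [
            len(build_pseudo_reference(markers, min_share=s)) for s in (0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_short_representative_excluded(self):
        markers = {
            "a": [Marker("a", "ACGTACGTACGTACGTACGT", 2)],  # 20 nt < 50
            "b": [Marker("b", "ACGTACGTACGTACGTACGT", 2)],
        }
        assert build_pseudo_reference(markers) == []


class TestEndToEnd:
    def test_noiseless_recovery_exact(self, small_scenario):
        reads, truth = simdata.simulate_reads(small_scenario)
        pooled = [r for ind in reads for r in reads[ind]]
        res = run_pipeline(pooled, truth.barcode_map)
        assert len(res.catalog) == small_scenario.n_loci

    def test_shuffling_reads_preserves_catalog_size(self, small_scenario):
        reads, truth = simdata.simulate_reads(small_scenario)
        pooled = [r for ind in reads for r in reads[ind]]
        res1 = run_pipeline(pooled, truth.barcode_map)
        rng = np.random.default_rng(0)
        shuffled = [pooled[i] for i in rng.permutation(len(pooled))]
        res2 = run_pipeline(shuffled, truth.barcode_map)
        assert len(res1.catalog) == len(res2.catalog)

    def test_homozygote_and_heterozygote_counts(self, small_scenario):
        reads, truth = simdata.simulate_reads(small_scenario)
        pooled = [r for ind in reads for r in reads[ind]]
        res = run_pipeline(pooled, truth.barcode_map)
        inds = res.site_table.individuals
        cut = len(small_scenario.cut_site)  # representatives keep the remnant
        checked = 0
        for locus in res.catalog:
            # match catalog locus back to a truth locus
            matches = [
                j
                for j, seq in enumerate(truth.loci)
                if radloci._identity(locus.representative_sequence[cut:], seq) >= 0.98
            ]
            assert len(matches) == 1
            j = matches[0]
            counts = res.site_table.base_counts[locus.locus_id]
            pos = truth.snp_positions[j] + cut
            if pos >= counts.shape[1]:
                continue
            major, minor = truth.snp_alleles[j]
            mi = "ACGT".index(major)
            ni = "ACGT".index(minor)
            for i, ind in enumerate(inds):
                k = list(small_scenario.manifest.individual_id).index(ind)
                g = truth.genotypes[k, j]
                maj_c = counts[i, pos, mi]
                min_c = counts[i, pos, ni]
                if maj_c + min_c == 0:
                    continue
                if g == 0:
                    assert min_c == 0
                elif g == 2:
                    assert maj_c == 0
                else:
                    assert maj_c > 0 or min_c > 0
                checked += 1
        assert checked > 50


class TestHweExactTest:
    @staticmethod
    def oracle(n_hom_major, n_het, n_hom_minor):
        """Exact-rational enumeration of the conditional het-count distribution."""
        n = n_hom_major + n_het + n_hom_minor
        n_minor = 2 * n_hom_minor + n_het
        probs = {}
        for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
            hom_min = (n_minor - h) // 2
            hom_maj = n - h - hom_min
            if hom_min < 0 or hom_maj < 0:
                continue
            probs[h] = (
                Fraction(math.factorial(n), math.factorial(hom_maj) * math.factorial(h) * math.factorial(hom_min))
                * Fraction(2**h)
                * Fraction(
                    math.factorial(n_minor) * math.factorial(2 * n - n_minor),
                    math.factorial(2 * n),
                )
            )
        total = sum(probs.values())
        tail = sum(p for h, p in probs.items() if h >= n_het)
        return float(tail / total)

    @pytest.mark.parametrize(
        "counts",
        [
            (5, 5, 0),
            (0, 20, 0),
            (10, 0, 10),
            (3, 7, 2),
            (25, 10, 15),
            (1, 1, 1),
            (0, 1, 0),
            (49, 1, 0),
            (12, 26, 12),
        ],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_het_excess(*counts) == pytest.approx(self.oracle(*counts), abs=1e-12)

    def test_all_heterozygous_is_extreme(self):
        # 20 heterozygotes, no homozygotes: paralog signature
        assert hwe_exact_het_excess(0, 20, 0) < 1e-4

    def test_moderate_heterozygosity_retained(self):
        assert hwe_exact_het_excess(5, 5, 0) > 1e-4


class TestSiteFilters:
    def make_table(self, counts):
        """counts: (n_ind, L, 4) array for a single locus."""
        counts = np.asarray(counts, dtype=np.int32)
        return SiteTable(
            individuals=[f"i{k}" for k in range(counts.shape[0])],
            locus_ids=["L0"],
            ref_seqs={"L0": "A" * counts.shape[1]},
            base_counts={"L0": counts},
        )

    def test_triallelic_site_drops_marker(self):
        n, L = 12, 5
        counts = np.zeros((n, L, 4), dtype=np.int32)
        counts[:, :, 0] = 10  # A everywhere
        counts[:4, 2, 1] = 10  # C in four individuals
        counts[4:8, 2, 2] = 10  # G in four others: three alleles at site 2
        table = self.make_table(counts)
        res = filter_sites(table)
        assert res.flags.flag_multiallelic_marker.all()
        assert res.n_retained == 0

    def test_heterozygote_excess_site_dropped(self):
        n, L = 20, 4
        counts = np.zeros((n, L, 4), dtype=np.int32)
        counts[:, :, 0] = 10
        counts[:, 1, 0] = 5  # every individual half A half C: all het
        counts[:, 1, 1] = 5
        res = filter_sites(self.make_table(counts))
        site = res.flags[res.flags.position == 1].iloc[0]
        assert site.flag_hwe_excess

    def test_low_presence_site_flagged(self):
        n, L = 10, 3
        counts = np.zeros((n, L, 4), dtype=np.int32)
        counts[:, :, 0] = 8
        counts[5:, 1, :] = 0  # half the individuals have no coverage
        counts[0, 1, 1] = 4  # make it variable
        counts[1, 1, 1] = 4
        res = filter_sites(self.make_table(counts), min_presence=0.60)
        site = res.flags[res.flags.position == 1]
        assert site.flag_low_presence.all()
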
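"""Tripartite detection chain: per-operation examples plus end-to-end
recovery of planted libraries."""

import numpy as np
import pytest

from tricontact.fragmap import Genome, digest, reverse_complement
from tricontact.multiway import (
    SegmentHit,
    TripartiteContact,
    build_matrix,
    deduplicate,
    demultiplex,
    detect_tripartite,
    is_undigested,
    map_segment,
    quality_trim_length,
    rescue_third,
    split_read,
    strip_viewpoint,
    trim,
    zone_fraction,
)
from tricontact.quant4c import ViewpointSpec
from tricontact.reads import RawRead
from tricontact.seqindex import GenomeIndex
from tricontact.simulate import SimulationConfig, default_primer_tag, simulate_library


def read_of(seq, q=40):
    return RawRead("r", seq, (q,) * len(seq))


class TestDemultiplex:
    def test_exact_prefix_assignment(self):
        table = {"s1": "AAAA", "s2": "CCCC"}
        reads = [read_of("AAAA" + "G" * 30)] * 10 + [read_of("CCCC" + "T" * 30)] * 10
        bins = demultiplex(reads, table)
        assert len(bins["s1"]) == 10 and len(bins["s2"]) == 10
        assert bins["unassigned"] == []
        assert bins["s1"][0].sequence == "G" * 30  # barcode removed

    def test_mismatch_goes_unassigned(self):
        bins = demultiplex([read_of("AATA" + "G" * 30)], {"s1": "AAAA"})
        assert len(bins["unassigned"]) == 1

    def test_conservation(self):
        rng = np.random.default_rng(0)
        reads = [
            read_of("".join(rng.choice(list("ACGT"), size=30))) for _ in range(100)
        ]
        bins = demultiplex(reads, {"s1": "AAAA", "s2": "CCCC"})
        assert sum(len(v) for v in bins.values()) == 100

    def test_duplicate_barcode_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"s1": "AAAA", "s2": "AAAA"})


class TestStripViewpoint:
    VP = ViewpointSpec("vp", "c", 0, 10, primer_tag="GGTTGGTTGG")

    def test_tag_removed_up_to_first_catg(self):
        read = read_of("GGTTGGTTGG" + "CATGAAA")
        out = strip_viewpoint(read, self.VP)
        assert out.sequence == "CATGAAA"

    def test_missing_tag_discarded(self):
        assert strip_viewpoint(read_of("T" * 30), self.VP) is None

    def test_intervening_bases_skipped_to_catg(self):
        read = read_of("GGTTGGTTGG" + "TT" + "CATGCCC")
        out = strip_viewpoint(read, self.VP)
        assert out.sequence == "CATGCCC"


class TestTrim:
    def brute_force_suffix(self, quals, thr):
        # independent oracle: largest k with every partial 3' sum positive
        best = 0
        for k in range(1, len(quals) + 1):
            sums = np.cumsum([thr - q for q in quals[::-1][:k]])
            if (sums > 0).all():
                best = k
        return best

    def test_high_quality_no_adapter_unchanged(self):
        read = read_of("CATG" + "A" * 40)
        assert trim(read).sequence == read.sequence

    def test_cut_at_first_gatc(self):
        read = read_of("CATGAAA" + "GATC" + "TTT" + "A" * 20)
        assert trim(read, min_len=4).sequence == "CATGAAA"

    def test_short_read_discarded(self):
        assert trim(read_of("CATGAAAGATCTTT")) is None  # 7 bases < 24

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_quality_rule_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        quals = [int(q) for q in rng.integers(2, 41, size=60)]
        got = quality_trim_length(quals, 10)
        assert got == self.brute_force_suffix(quals, 10)


class TestSplitRead:
    @pytest.mark.parametrize(
        "seq,mid,third",
        [
            ("CATGAAAA", "CATGAAAA", None),
            ("CATGAAACATGTTT", "CATGAAA", "CATGTTT"),
            ("CATGCATGCATG", "CATG", "CATGCATG"),
        ],
    )
    def test_split_examples(self, seq, mid, third):
        m, t = split_read(read_of(seq))
        assert m.sequence == mid
        assert (t.sequence if t is not None else None) == third


@pytest.fixture(scope="module")
def toy_mapping_world():
    rng = np.random.default_rng(33)
    seq = "".join(rng.choice(list("ACGT"), size=8_000))
    genome = Genome({"c": seq})
    return genome, digest(genome), GenomeIndex(genome)


class TestMapSegment:
    def test_unique_forward_hit(self, toy_mapping_world):
        genome, fmap, index = toy_mapping_world
        seg = genome["c"][500:530]
        hit = map_segment(read_of(seg), index, fmap, "mid")
        assert hit is not None
        assert (hit.pos, hit.strand) == (500, "+")
        assert hit.fragment_index == fmap.locate("c", 500)

    def test_reverse_complement_same_pos_minus(self, toy_mapping_world):
        genome, fmap, index = toy_mapping_world
        seg = reverse_complement(genome["c"][500:530])
        hit = map_segment(read_of(seg), index, fmap, "mid")
        assert (hit.pos, hit.strand) == (500, "-")

    def test_below_min_len_unmapped(self, toy_mapping_world):
        genome, fmap, index = toy_mapping_world
        assert map_segment(read_of(genome["c"][500:515]), index, fmap, "mid") is None

    def test_duplicated_segment_unmapped(self):
        core = "ACGGTTAACCGGATAACCGGTTAACA"
        genome = Genome({"c": "TTTT" + core + "AAAA" + core + "TTTT"})
        index = GenomeIndex(genome)
        fmap = digest(genome)
        assert map_segment(read_of(core), index, fmap, "mid") is None


class TestRescueThird:
    def test_rescue_splits_and_maps_prefix(self, toy_mapping_world):
        genome, fmap, index = toy_mapping_world
        start = next(
            p for p in range(1000, 4000) if "CATG" not in genome["c"][p : p + 30]
        )
        unique = genome["c"][start : start + 30]
        third = read_of(unique + "CATG" + "N" * 20)
        # direct mapping fails (junk tail), rescue maps the 5' part
        assert map_segment(third, index, fmap, "third") is None
        hit = rescue_third(third, index, fmap)
        assert hit is not None and hit.pos == start

    def test_no_internal_catg_unrescuable(self, toy_mapping_world):
        genome, fmap, index = toy_mapping_world
        third = read_of("N" * 40)
        assert rescue_third(third, index, fmap) is None


class TestUndigested:
    def hit(self, frag, strand, chrom="c"):
        return SegmentHit("mid", chrom, 0, strand, frag)

    def test_collinear_plus_dropped(self):
        assert is_undigested(self.hit(5, "+"), self.hit(6, "+"))

    def test_opposite_strand_kept(self):
        assert not is_undigested(self.hit(5, "+"), self.hit(6, "-"))

    def test_collinear_minus_dropped(self):
        assert is_undigested(self.hit(5, "-"), self.hit(4, "-"))

    def test_minus_wrong_direction_kept(self):
        assert not is_undigested(self.hit(5, "-"), self.hit(6, "-"))

    def test_strand_agnostic_variant(self):
        assert is_undigested(self.hit(5, "+"), self.hit(6, "-"), strand_aware=False)
        assert not is_undigested(self.hit(5, "+"), self.hit(8, "-"), strand_aware=False)


class TestDeduplicate:
    def contact(self, xp, xs="+", yp=500, ys="+"):
        return TripartiteContact("vp", "c", xp, xs, "c", yp, ys)

    def test_identical_collapse_to_one(self):
        contacts = [self.contact(100)] * 5
        assert len(deduplicate(contacts)) == 1

    def test_strand_distinguishes(self):
        a, b = self.contact(100, ys="+"), self.contact(100, ys="-")
        assert len(deduplicate([a, b])) == 2

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(1)
        contacts = [
            self.contact(int(rng.integers(0, 50)) * 10) for _ in range(100)
        ]
        once = deduplicate(contacts)
        assert deduplicate(once) == once
        seen = [c.x_pos for c in once]
        firsts = []
        for c in contacts:
            if c.x_pos not in firsts:
                firsts.append(c.x_pos)
        assert seen == firsts


class TestMatrix:
    def contact(self, xp, yp):
        return TripartiteContact("vp", "c", xp, "+", "c", yp, "+")

    def test_binning_and_symmetry(self):
        m = build_matrix(
            [self.contact(15_000, 20_000)], ("c", 0, 100_000), binsize=20_000
        )
        assert m.matrix[0, 1] == 1 and m.matrix[1, 0] == 1
        assert m.matrix.sum() == 2

    def test_same_bin_diagonal_once(self):
        m = build_matrix(
            [self.contact(1_000, 2_000)], ("c", 0, 100_000), binsize=20_000
        )
        assert m.matrix[0, 0] == 1 and m.matrix.sum() == 1

    def test_out_of_region_dropped(self):
        m = build_matrix(
            [self.contact(1_000, 300_000)], ("c", 0, 100_000), binsize=20_000
        )
        assert m.matrix.sum() == 0 and m.contacts == []

    def test_upper_triangle_conservation(self):
        rng = np.random.default_rng(2)
        contacts = [
            self.contact(int(rng.integers(0, 100_000)), int(rng.integers(0, 100_000)))
            for _ in range(200)
        ]
        m = build_matrix(contacts, ("c", 0, 100_000), binsize=20_000)
        upper = np.triu(m.matrix).sum()
        assert upper == 200
        assert (m.matrix == m.matrix.T).all()

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            build_matrix([], ("c", 100, 100), binsize=20_000)


class TestZoneFraction:
    def test_empty_matrix_zero(self):
        m = build_matrix([], ("c", 0, 100_000), binsize=20_000)
        assert zone_fraction(m, (0, 100_000)) == 0.0

    def test_all_touched_hundred(self):
        contacts = [
            TripartiteContact("vp", "c", p, "+", "c", p + 1_000, "+")
            for p in range(0, 100_000, 20_000)
        ]
        m = build_matrix(contacts, ("c", 0, 100_000), binsize=20_000)
        assert zone_fraction(m, (0, 100_000)) == 100.0

    def test_zone_without_bins_rejected(self):
        m = build_matrix([], ("c", 0, 100_000), binsize=20_000)
        with pytest.raises(ValueError):
            zone_fraction(m, (200_000, 300_000))


@pytest.fixture(scope="module")
def pipeline_run():
    cfg = SimulationConfig(
        chrom_length=400_000,
        viewpoint_pos=100_000,
        n_reads=800,
        seed=77,
        duplicate_rate=0.2,
        undigested_rate=0.1,
        hub_zone=(250_000, 320_000),
        hub_prob=0.5,
        barcodes=["ACGTAC", "TGCATG"],
    )
    genome, fmap, model, reads, truth = simulate_library(cfg, multiway=True)
    frag = fmap.fragment_at(cfg.chrom_name, cfg.viewpoint_pos)
    vp = ViewpointSpec(
        "vp", cfg.chrom_name, frag.start, frag.end,
        default_primer_tag(genome, fmap, cfg),
    )
    table = {"s1": "ACGTAC", "s2": "TGCATG"}
    result = detect_tripartite(reads, table, vp, fmap, genome)
    return cfg, truth, table, result


class TestEndToEnd:
    def test_read_conservation_across_classes(self, pipeline_run):
        cfg, truth, table, result = pipeline_run
        assert sum(result.qc_totals().values()) == cfg.n_reads

    def test_unique_contacts_equal_planted_pairs(self, pipeline_run):
        cfg, truth, table, result = pipeline_run
        for sample, barcode in table.items():
            got = {c.key for c in result.contacts[sample]}
            assert got == truth.unique_pairs(sample=barcode)

    def test_dropped_undigested_equal_planted_set(self, pipeline_run):
        cfg, truth, table, result = pipeline_run
        dropped = {
            c.key for cs in result.dropped_undigested.values() for c in cs
        }
        planted = {
            (truth.chrom, r.x_pos, r.x_strand, truth.chrom, r.y_pos, r.y_strand)
            for r in truth.records
            if r.undigested
        }
        assert dropped == planted

    def test_duplicate_removal_count_matches_truth(self, pipeline_run):
        cfg, truth, table, result = pipeline_run
        for sample, barcode in table.items():
            kept = [
                r
                for r in truth.records
                if r.sample == barcode and not r.undigested and r.y_pos is not None
            ]
            expected_removed = len(kept) - len(truth.unique_pairs(sample=barcode))
            assert result.qc[sample]["duplicate"] == expected_removed
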
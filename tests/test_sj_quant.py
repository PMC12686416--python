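"""Splice-junction parsing and donor-anchored quantification."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mexquant.sj import (
    FormatError,
    IsoformCounts,
    SpliceJunctionRecord,
    classify_junctions,
    detect_isoform,
    merge_cohort,
    quantify,
    read_sj_table,
)

from conftest import make_toy_model, mirror_model, mirror_record


def rec(start, end, chrom="chr1", unique=1, multi=0):
    return SpliceJunctionRecord(
        chrom=chrom, intron_start=start, intron_end=end, strand_code=1,
        motif_code=1, annotated=1, unique_reads=unique, multi_reads=multi,
        max_overhang=50,
    )


# ---------------------------------------------------------------------------
# parsing

class TestReadSjTable:
    def test_well_formed_file(self):
        text = (
            "chr1\t1001\t1100\t1\t1\t1\t10\t2\t50\n"
            "chr1\t1001\t1300\t1\t1\t1\t20\t0\t48\n"
            "chr2\t5000\t6000\t2\t2\t0\t3\t1\t30\n"
        )
        records = read_sj_table(io.StringIO(text))
        assert len(records) == 3
        assert records[0].intron_start == 1001
        assert records[2].strand_code == 2

    def test_empty_file(self):
        assert read_sj_table(io.StringIO("")) == []

    def test_wrong_column_count_names_line(self):
        text = "chr1\t1001\t1100\t1\t1\t1\t10\t2\n"  # 8 columns
        with pytest.raises(FormatError, match="line 1"):
            read_sj_table(io.StringIO(text))

    def test_non_numeric_count_names_line(self):
        text = (
            "chr1\t1001\t1100\t1\t1\t1\t10\t2\t50\n"
            "chr1\t1001\t1300\t1\t1\t1\tten\t0\t48\n"
        )
        with pytest.raises(FormatError, match="line 2"):
            read_sj_table(io.StringIO(text))

    def test_gzip_roundtrip(self, tmp_path):
        import gzip

        path = tmp_path / "s.SJ.out.tab.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("chr1\t1001\t1100\t1\t1\t1\t10\t2\t50\n")
        assert len(read_sj_table(path)) == 1

    def test_gdc_dialect_skips_header(self):
        text = (
            "chromosome\tintron_start\tintron_end\tstrand\tmotif\tannotated\tunique\tmulti\toverhang\n"
            "chr1\t1001\t1100\t1\t1\t1\t10\t2\t50\n"
        )
        records = read_sj_table(io.StringIO(text), dialect="gdc")
        assert len(records) == 1


# ---------------------------------------------------------------------------
# classification

class TestClassify:
    def test_toy_example(self, toy_model):
        records = [
            rec(1001, 1100), rec(1001, 1300), rec(1001, 1500),
            rec(1001, 1400),  # unknown acceptor -> other
            rec(1104, 1300),  # wrong donor -> excluded
        ]
        labelled = classify_junctions(records, toy_model)
        assert [lab for lab, _ in labelled] == ["ex4:3bp", "ex4:22bp", "ex4:ex6", "other"]

    def test_no_donor_match(self, toy_model):
        assert classify_junctions([rec(2001, 2100)], toy_model) == []

    def test_other_chromosome_excluded(self, toy_model):
        assert classify_junctions([rec(1001, 1100, chrom="chr9")], toy_model) == []

    def test_minus_strand_mirror_same_labels(self, toy_model):
        records = [rec(1001, 1100), rec(1001, 1300), rec(1001, 1500), rec(1001, 1400)]
        plus = sorted(lab for lab, _ in classify_junctions(records, toy_model))
        mirrored_model = mirror_model(toy_model)
        mirrored_records = [mirror_record(r) for r in records]
        minus = sorted(lab for lab, _ in classify_junctions(mirrored_records, mirrored_model))
        assert plus == minus

    def test_order_invariance(self, toy_model):
        records = [rec(1001, 1100, unique=5), rec(1001, 1300, unique=7), rec(1001, 1500, unique=2)]
        fwd = quantify(records, toy_model, min_total=1)
        rev = quantify(records[::-1], toy_model, min_total=1)
        assert fwd.counts == rev.counts


# ---------------------------------------------------------------------------
# quantification

class TestQuantify:
    def test_proportions_arithmetic(self, toy_model):
        records = [rec(1001, 1100, unique=25), rec(1001, 1300, unique=50), rec(1001, 1500, unique=25)]
        ic = quantify(records, toy_model, min_total=10)
        assert ic.total_donor_reads == 100
        assert ic.proportions["ex4:3bp"] == 0.25
        assert ic.proportions["ex4:22bp"] == 0.50
        assert ic.proportions["ex4:ex6"] == 0.25

    def test_below_min_total_undefined(self, toy_model):
        records = [rec(1001, 1100, unique=4)]
        ic = quantify(records, toy_model, min_total=10)
        assert ic.proportions is None
        assert ic.counts["ex4:3bp"] == 4
        assert detect_isoform(ic) is None

    def test_count_field_includes_multimappers_on_request(self, toy_model):
        records = [rec(1001, 1100, unique=10, multi=5), rec(1001, 1500, unique=10, multi=0)]
        unique_only = quantify(records, toy_model, min_total=1)
        with_multi = quantify(records, toy_model, min_total=1, count_field="unique+multi")
        assert unique_only.total_donor_reads == 20
        assert with_multi.total_donor_reads == 25

    def test_multinomial_error_bound(self, toy_model):
        """Estimated proportions sit within 3 binomial SEs of the simulated truth."""
        true_p = {"ex4:3bp": 0.2, "ex4:18bp": 0.0, "ex4:22bp": 0.5, "ex4:ex6": 0.3}
        depth = 10_000
        rng = np.random.default_rng(42)
        counts = rng.multinomial(depth, list(true_p.values()))
        acceptors = {"ex4:3bp": 1100, "ex4:18bp": 1200, "ex4:22bp": 1300, "ex4:ex6": 1500}
        records = [
            rec(1001, acceptors[lab], unique=int(n))
            for lab, n in zip(true_p, counts) if n > 0
        ]
        ic = quantify(records, toy_model)
        for lab, p in true_p.items():
            se = np.sqrt(p * (1 - p) / depth)
            assert abs(ic.proportions[lab] - p) <= 3 * se + 1e-12

    @given(
        counts=st.lists(
            st.tuples(st.sampled_from([1100, 1200, 1300, 1400, 1500]),
                      st.integers(min_value=0, max_value=100)),
            min_size=0, max_size=20,
        )
    )
    def test_conservation_property(self, counts):
        """Sum of category counts equals the donor total; proportions sum to 1."""
        toy = make_toy_model()
        records = [rec(1001, acc, unique=n) for acc, n in counts]
        ic = quantify(records, toy, min_total=1)
        assert sum(ic.counts.values()) == ic.total_donor_reads
        if ic.proportions is not None:
            assert abs(sum(ic.proportions.values()) - 1.0) < 1e-12

    def test_brute_force_tally_oracle(self, toy_model):
        """quantify equals a per-read expansion tally on small instances."""
        from mexquant.gene_model import acceptor_map, donor_site

        rng = np.random.default_rng(7)
        site = donor_site(toy_model)
        amap = acceptor_map(toy_model)
        for _ in range(50):
            records = []
            for _ in range(rng.integers(0, 20)):
                start = int(rng.choice([1001, 1050]))  # true donor or a wrong one
                end = int(rng.choice([1100, 1200, 1300, 1400, 1500]))
                chrom = str(rng.choice(["chr1", "chr9"]))
                records.append(rec(start, end, chrom=chrom, unique=int(rng.integers(0, 30))))
            ic = quantify(records, toy_model, min_total=1)
            tally: dict = {}
            for r in records:
                if r.chrom != "chr1" or r.intron_start != site:
                    continue
                lab = amap.get(r.intron_end, "other")
                for _read in range(r.unique_reads):
                    tally[lab] = tally.get(lab, 0) + 1
            for lab, n in ic.counts.items():
                assert tally.get(lab, 0) == n


# ---------------------------------------------------------------------------
# presence calls

class TestDetect:
    def make_counts(self, p3):
        counts = {"ex4:3bp": int(p3 * 1000), "ex4:18bp": 0,
                  "ex4:22bp": 500, "ex4:ex6": 1000 - int(p3 * 1000) - 500, "other": 0}
        return IsoformCounts("s", counts, 1000, {k: v / 1000 for k, v in counts.items()}, 10)

    def test_strictly_above_threshold_detected(self):
        det = detect_isoform(self.make_counts(0.051))
        assert det["ex4:3bp"] is True

    def test_exactly_at_threshold_not_detected(self):
        det = detect_isoform(self.make_counts(0.050))
        assert det["ex4:3bp"] is False

    def test_planted_cohort_presence_count(self, toy_model):
        """51 samples, 34 planted above the 5% threshold: exactly 34 detected."""
        rng = np.random.default_rng(3)
        above = [True] * 34 + [False] * 17
        rng.shuffle(above)
        detected = 0
        for flag in above:
            p3 = rng.uniform(0.08, 0.5) if flag else rng.uniform(0.0, 0.04)
            n3 = int(round(p3 * 10_000))
            records = [rec(1001, 1300, unique=5000), rec(1001, 1500, unique=5000 - n3)]
            if n3:
                records.append(rec(1001, 1100, unique=n3))
            det = detect_isoform(quantify(records, toy_model))
            detected += det["ex4:3bp"]
        assert detected == 34


# ---------------------------------------------------------------------------
# cohort assembly

class TestMergeCohort:
    def make_ic(self, sid, p3=0.2, defined=True):
        counts = {"ex4:3bp": 20, "ex4:18bp": 0, "ex4:22bp": 50, "ex4:ex6": 30, "other": 0}
        props = {"ex4:3bp": p3, "ex4:18bp": 0.0, "ex4:22bp": 0.5, "ex4:ex6": 0.3 - (p3 - 0.2),
                 "other": 0.0}
        return IsoformCounts(sid, counts, 100, props if defined else None, 10)

    def test_basic_merge_sortable(self):
        per = [self.make_ic("a", 0.1), self.make_ic("b", 0.3), self.make_ic("c", 0.2)]
        meta = pd.DataFrame({"sample_id": ["a", "b", "c"], "er": ["+", "-", "+"]})
        table = merge_cohort(per, meta)
        assert len(table) == 3
        assert list(table.sort_values("ex4:3bp")["sample_id"]) == ["a", "c", "b"]

    def test_missing_metadata_names_sample(self):
        per = [self.make_ic("a"), self.make_ic("zz")]
        meta = pd.DataFrame({"sample_id": ["a"], "er": ["+"]})
        with pytest.raises(ValueError, match="zz"):
            merge_cohort(per, meta)

    def test_duplicate_sample_id_rejected(self):
        per = [self.make_ic("a"), self.make_ic("a")]
        meta = pd.DataFrame({"sample_id": ["a"], "er": ["+"]})
        with pytest.raises(ValueError, match="duplicate"):
            merge_cohort(per, meta)

    def test_undefined_samples_flagged_not_dropped(self):
        per = [self.make_ic("a"), self.make_ic("b", defined=False)]
        meta = pd.DataFrame({"sample_id": ["a", "b"], "er": ["+", "-"]})
        table = merge_cohort(per, meta)
        assert len(table) == 2
        row_b = table.set_index("sample_id").loc["b"]
        assert not row_b["defined"]
        assert np.isnan(row_b["ex4:3bp"])

    def test_merge_split_merge_roundtrip(self):
        per = [self.make_ic(s, p) for s, p in [("a", 0.1), ("b", 0.3), ("c", 0.2)]]
        meta = pd.DataFrame({"sample_id": ["a", "b", "c"], "er": ["+", "-", "+"]})
        once = merge_cohort(per, meta)
        again = merge_cohort(per, once[["sample_id", "er"]])
        pd.testing.assert_frame_equal(once, again)
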
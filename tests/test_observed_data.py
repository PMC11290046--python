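import numpy as np
import pandas as pd
import pytest

from gp4pg.fixtures import make_toy_vcf
from gp4pg.observed_data import (
    CallableMask,
    FilterConfig,
    VariantRecord,
    apply_masks,
    build_observed,
    filter_variants,
    make_blocks,
    merge_intervals,
    polarize,
    read_bed,
    read_vcf,
    window_density_mask,
)

HET = np.array([[0, 1], [0, 0], [0, 0], [0, 0]])


def _rec(pos, ref="A", alts=("G",), qual=50.0, passing=True, depth=30, chrom="1", gts=None):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        qual=qual,
        filter_pass=passing,
        depth=depth,
        gts=HET.copy() if gts is None else np.asarray(gts),
    )


class TestFilterVariants:
    def test_six_record_fixture_attributes_each_drop(self):
        records = [
            _rec(100, depth=3),
            _rec(200, qual=10.0),
            _rec(300, passing=False),
            _rec(400, alts=("G", "T")),
            _rec(500, ref="AT", alts=("A",)),  # the indel
            _rec(504, ),  # 4 bp from the indel span
            _rec(900),  # clean
        ]
        kept, drops = filter_variants(records)
        assert [r.pos for r in kept] == [900]
        assert drops["depth"] == 1
        assert drops["qual"] == 1
        assert drops["not_pass"] == 1
        assert drops["multiallelic"] == 1
        assert drops["indel_flank"] == 1
        assert drops["indel_record"] == 1

    def test_empty_input(self):
        kept, drops = filter_variants([])
        assert kept == [] and sum(drops.values()) == 0

    def test_all_passing_is_identity(self):
        records = [_rec(100), _rec(200), _rec(300)]
        kept, _ = filter_variants(records)
        assert kept == records

    def test_missing_fields_counted_unscorable(self):
        kept, drops = filter_variants([_rec(100, depth=None)])
        assert kept == [] and drops["unscorable"] == 1

    def test_order_stability_for_independent_predicates(self):
        # each record violates at most one predicate, so total drops equal
        # the sum of individual failures regardless of evaluation order
        records = [_rec(100, depth=3), _rec(5000, qual=5.0), _rec(9000)]
        _, drops = filter_variants(records)
        assert drops["depth"] == 1 and drops["qual"] == 1


class TestMasks:
    def test_record_inside_repeat_dropped(self, tmp_path):
        bed = tmp_path / "repeats.bed"
        bed.write_text("1\t90\t110\n")
        kept, drops = apply_masks([_rec(100), _rec(300)], {"repeats": bed})
        assert [r.pos for r in kept] == [300] and drops["repeats"] == 1

    def test_gene_flank_boundary(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t40000\t42000\n")
        masked = _rec(20_001)
        kept_rec = _rec(20_000)
        beyond = _rec(62_001)
        kept, _ = apply_masks([masked, kept_rec, beyond], {"genes": bed}, gene_flank_bp=20_000)
        assert [r.pos for r in kept] == [20_000, 62_001]

    def test_idempotent(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("1\t0\t150\n1\t400\t600\n")
        records = [_rec(p) for p in (100, 200, 500, 700)]
        once, _ = apply_masks(records, {"m": bed})
        twice, _ = apply_masks(once, {"m": bed})
        assert [r.pos for r in twice] == [r.pos for r in once]

    def test_survivors_match_interval_stabbing_oracle(self, tmp_path, rng):
        iv1 = [(100, 300), (500, 800)]
        iv2 = [(250, 550)]
        (tmp_path / "a.bed").write_text("".join(f"1\t{a}\t{b}\n" for a, b in iv1))
        (tmp_path / "b.bed").write_text("".join(f"1\t{a}\t{b}\n" for a, b in iv2))
        positions = sorted(rng.integers(1, 1000, 10).tolist())
        records = [_rec(int(p)) for p in positions]
        kept, _ = apply_masks(
            records, {"a": tmp_path / "a.bed", "b": tmp_path / "b.bed"}
        )
        oracle = [
            p
            for p in positions
            if not any(a <= p - 1 < b for a, b in iv1 + iv2)
        ]
        assert [r.pos for r in kept] == oracle

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("1\t0\t100\n1\tnot_a_number\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(bed)

    def test_merge_intervals(self):
        iv = np.array([[10, 20], [15, 30], [40, 50]])
        assert merge_intervals(iv).tolist() == [[10, 30], [40, 50]]


class TestWindowDensity:
    def test_95_percent_window_retained(self):
        pos = np.arange(1, 9501)  # 9500 callable of the first 10k window
        mask = window_density_mask({"1": pos}, 10_000, 2_500, 0.9)
        assert mask.contains("1", 100)

    def test_80_percent_window_dropped(self):
        pos = np.arange(1, 8001)
        mask = window_density_mask({"1": pos}, 10_000, 10_000, 0.9)
        assert not mask.intervals.get("1", np.zeros((0, 2))).size

    def test_matches_brute_force_sliding_oracle(self, rng):
        # staggered coverage hovering around the 90% cutoff
        pos = np.unique(rng.integers(1, 40_001, 37_000))
        mask = window_density_mask({"1": pos}, 10_000, 2_500, 0.9)
        kept = []
        start = 0
        while start < pos[-1]:
            inside = ((pos > start) & (pos <= start + 10_000)).sum()
            if inside / 10_000 > 0.9:
                kept.append((start, start + 10_000))
            start += 2_500
        expected = merge_intervals(np.array(kept)) if kept else np.zeros((0, 2), int)
        got = mask.intervals.get("1", np.zeros((0, 2), int))
        assert np.array_equal(got, expected)


class TestPolarize:
    def test_ancestral_equals_ref(self):
        r = _rec(100)
        r.aa = "A"
        table, _ = polarize([r], {f"S{i}": f"P{i}" for i in range(4)}, [f"S{i}" for i in range(4)])
        assert table.loc[0, "P0"] == 1 and table.loc[0, "P1"] == 0

    def test_ancestral_equals_alt_flips(self):
        r = _rec(100, gts=np.zeros((4, 2), int))  # all 0/0
        r.aa = "G"
        table, _ = polarize([r], {f"S{i}": f"P{i}" for i in range(4)}, [f"S{i}" for i in range(4)])
        assert (table[[f"P{i}" for i in range(4)]] == 2).all().all()

    def test_ancestral_matches_neither_drops(self):
        r = _rec(100)
        r.aa = "T"
        table, drops = polarize([r], {"S0": "P0"}, ["S0"])
        assert len(table) == 0 and drops["ancestral_mismatch"] == 1

    def test_missing_ancestral_counted(self):
        r = _rec(100)
        table, drops = polarize([r], {"S0": "P0"}, ["S0"])
        assert drops["missing_ancestral"] == 1


class TestMakeBlocks:
    def test_one_block_per_mask_interval(self):
        mask = CallableMask(intervals={"1": np.array([[0, 100], [200, 300], [400, 500]])})
        sites = pd.DataFrame({"chrom": ["1"] * 3, "pos": [50, 250, 450], "P0": [1, 1, 1]})
        out = make_blocks(sites, mask)
        assert out["block"].tolist() == [0, 1, 2]

    def test_record_outside_mask_excluded(self):
        mask = CallableMask(intervals={"1": np.array([[0, 100]])})
        sites = pd.DataFrame({"chrom": ["1", "1"], "pos": [50, 150], "P0": [1, 1]})
        assert len(make_blocks(sites, mask)) == 1

    def test_fixed_tiling_matches_oracle(self):
        mask = CallableMask(intervals={"1": np.array([[0, 2_500_000]])})
        positions = [1, 999_999, 1_000_000, 1_000_001, 2_400_000]
        sites = pd.DataFrame({"chrom": "1", "pos": positions, "P0": 1})
        out = make_blocks(sites, mask, scheme="fixed", tile_bp=1_000_000)
        oracle = [(p - 1) // 1_000_000 for p in positions]
        remap = {}
        expected = [remap.setdefault(t, len(remap)) for t in oracle]
        assert out["block"].tolist() == expected


class TestEndToEnd:
    def test_toy_vcf_pipeline_reproduces_sidecar_survivors(self, tmp_path):
        sidecar = make_toy_vcf(tmp_path)
        masks = {
            name: tmp_path / f"{name}.bed"
            for name in ("repeats", "cnv", "genes", "cpg")
        }
        table, report = build_observed(
            tmp_path / "toy.vcf",
            pops=sidecar["pops"],
            masks=masks,
            ancestral_fasta=tmp_path / "ancestral.fa",
        )
        assert sorted(table["pos"].tolist()) == sidecar["survivors"]

    def test_filter_then_sfs_matches_hand_tally(self, tmp_path):
        sidecar = make_toy_vcf(tmp_path)
        masks = {
            name: tmp_path / f"{name}.bed"
            for name in ("repeats", "cnv", "genes", "cpg")
        }
        table, _ = build_observed(
            tmp_path / "toy.vcf",
            pops=sidecar["pops"],
            masks=masks,
            ancestral_fasta=tmp_path / "ancestral.fa",
        )
        from gp4pg.sfs_stats import compute_4jsfs

        pops = sorted(set(sidecar["pops"].values()))
        sfs = compute_4jsfs(table, pops)
        # survivors: four het-in-POP1 sites (1,0,0,0 -> code 27, index 26)
        # and one flipped site (0,2,2,2 -> code 0*27+2*9+2*3+2 = 26, index 25)
        assert sfs.values[26] == 4
        assert sfs.values[25] == 1
        assert sfs.values.sum() == 5
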
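"""TMB, HRD components, aneuploidy score, and subtype genomics summaries."""

import numpy as np
import pandas as pd
import pytest

from trfscape.instability import (
    ArmModel,
    aneuploidy_score,
    driver_frequency_tables,
    group_score_comparison,
    hrd_score,
    loh_large,
    lst,
    ntai,
    segment_count,
    tmb,
)

MB = 1_000_000


@pytest.fixture(scope="module")
def arm_model():
    return ArmModel.synthetic()


def _seg(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"])


def _diploid_fill(rows, arm_model):
    """Complete a partial profile with diploid segments."""
    out = []
    by_chrom = {}
    for r in rows:
        by_chrom.setdefault(r[0], []).append(r)
    for chrom, L in arm_model.chrom_length.items():
        placed = sorted(by_chrom.get(chrom, []), key=lambda r: r[1])
        pos = 1
        for r in placed:
            if r[1] > pos:
                out.append((chrom, pos, r[1] - 1, 2, 1))
            out.append(r)
            pos = r[2] + 1
        if pos <= L:
            out.append((chrom, pos, L, 2, 1))
    return _seg(out)


class TestTMB:
    def _maf(self, classes):
        return pd.DataFrame(
            {
                "sample": "s1", "chrom": "chr1", "pos": 1, "ref": "A", "alt": "T",
                "variant_classification": classes, "gene": "TP53",
            }
        )

    def test_division(self):
        maf = self._maf(["Missense_Mutation"] * 76)
        assert tmb(maf, coding_mb=38.0) == pytest.approx(2.0)

    def test_silent_only_zero(self):
        assert tmb(self._maf(["Silent"] * 10)) == 0.0

    def test_unknown_class_counts_synonymous(self, caplog):
        with caplog.at_level("WARNING", logger="trfscape.instability"):
            val = tmb(self._maf(["Weird_Class"] * 5), coding_mb=1.0)
        assert val == 0.0
        assert any("unknown" in r.getMessage() for r in caplog.records)

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            tmb(self._maf(["Silent"]), coding_mb=0.0)


class TestLOH:
    def test_large_interior_loh_counts_once(self, arm_model):
        # 20 Mb copy-neutral LOH in the middle of chr1p (95 Mb arm)
        prof = _diploid_fill([("chr1", 30 * MB, 50 * MB - 1, 2, 0)], arm_model)
        assert loh_large(prof, arm_model) == 1

    def test_arm_level_loh_excluded(self, arm_model):
        # LOH covering all of chr1p
        prof = _diploid_fill([("chr1", 1, 95 * MB, 1, 0)], arm_model)
        assert loh_large(prof, arm_model) == 0

    def test_short_loh_excluded(self, arm_model):
        prof = _diploid_fill([("chr1", 30 * MB, 40 * MB, 2, 0)], arm_model)
        assert loh_large(prof, arm_model) == 0

    def test_contiguous_run_merged(self, arm_model):
        # two adjacent 10 Mb LOH segments merge into one 20 Mb run
        prof = _diploid_fill(
            [("chr1", 30 * MB, 40 * MB - 1, 2, 0), ("chr1", 40 * MB, 50 * MB - 1, 1, 0)],
            arm_model,
        )
        assert loh_large(prof, arm_model) == 1


class TestLST:
    def test_two_large_segments_one_break(self, arm_model):
        # chr1p split into 40 Mb at cn 3 and 55 Mb diploid
        prof = _diploid_fill([("chr1", 1, 40 * MB, 3, 1)], arm_model)
        assert lst(prof, arm_model) == 1

    def test_uniform_diploid_zero(self, arm_model):
        prof = _diploid_fill([], arm_model)
        assert lst(prof, arm_model) == 0

    def test_small_flank_not_counted(self, arm_model):
        # 8 Mb gained segment at the telomere: flank below 10 Mb
        prof = _diploid_fill([("chr1", 1, 8 * MB, 3, 1)], arm_model)
        assert lst(prof, arm_model) == 0

    def test_smoothing_removes_small_interruption(self, arm_model):
        # 2 Mb blip inside a diploid arm disappears; its neighbors merge
        prof = _diploid_fill([("chr1", 40 * MB, 42 * MB - 1, 3, 1)], arm_model)
        assert lst(prof, arm_model) == 0


class TestNtAI:
    def test_q_terminal_ai(self, arm_model):
        L = arm_model.chrom_length["chr1"]
        prof = _diploid_fill([("chr1", L - 8 * MB + 1, L, 3, 1)], arm_model)
        assert ntai(prof, arm_model) == 1

    def test_whole_chromosome_ai_crosses_centromere(self, arm_model):
        L = arm_model.chrom_length["chr1"]
        prof = _seg([("chr1", 1, L, 3, 1)])
        assert ntai(prof, arm_model) == 0

    def test_interior_ai_not_counted(self, arm_model):
        prof = _diploid_fill([("chr1", 30 * MB, 40 * MB, 3, 1)], arm_model)
        assert ntai(prof, arm_model) == 0

    def test_balanced_terminal_segment_not_counted(self, arm_model):
        prof = _diploid_fill([("chr1", 1, 8 * MB, 4, 2)], arm_model)
        assert ntai(prof, arm_model) == 0


class TestAneuploidy:
    def test_single_arm_gain(self, arm_model):
        prof = _diploid_fill([("chr2", 1, 85 * MB, 3, 1)], arm_model)
        res = aneuploidy_score(prof, arm_model)
        assert res == {"ploidy": 2, "gains": 1, "losses": 0, "aneuploidy_score": 1}

    def test_genome_doubled_scores_zero(self, arm_model):
        rows = [
            (c, 1, L, 4, 2) for c, L in arm_model.chrom_length.items()
        ]
        res = aneuploidy_score(_seg(rows), arm_model)
        assert res["ploidy"] == 4
        assert res["aneuploidy_score"] == 0

    def test_arm_loss(self, arm_model):
        prof = _diploid_fill([("chr3", 1, 75 * MB, 1, 0)], arm_model)
        res = aneuploidy_score(prof, arm_model)
        assert res["losses"] == 1 and res["gains"] == 0


class TestInvariances:
    def _random_planted(self, rng, arm_model):
        from trfscape.simulate import plant_segment_profile

        counts = {
            "loh": int(rng.integers(0, 3)), "lst": int(rng.integers(0, 4)),
            "ntai": int(rng.integers(0, 3)), "gains": int(rng.integers(0, 2)),
            "losses": int(rng.integers(0, 2)),
        }
        return counts, plant_segment_profile(counts, arm_model, rng)

    @staticmethod
    def _split_segments(prof, rng, min_piece=3 * MB):
        # split only above the LST smoothing scale: halves below 3 Mb are
        # (by design) smoothed away and can genuinely change the landscape
        rows = []
        for r in prof.itertuples(index=False):
            length = r.end - r.start + 1
            if length >= 2 * min_piece and rng.random() < 0.7:
                cut = r.start + int(rng.integers(min_piece, length - min_piece + 1))
                rows.append((r.chrom, r.start, cut - 1, r.total_cn, r.minor_cn))
                rows.append((r.chrom, cut, r.end, r.total_cn, r.minor_cn))
            else:
                rows.append(tuple(r))
        return pd.DataFrame(rows, columns=prof.columns)

    def test_segment_splitting_invariance(self, arm_model, rng):
        """Splitting a segment into equal-state halves (each above the
        smoothing scale) changes no HRD component and no AS, but does
        change segment_count."""
        for _ in range(25):
            counts, prof = self._random_planted(rng, arm_model)
            split = self._split_segments(prof, rng)
            assert hrd_score(prof, arm_model) == hrd_score(split, arm_model)
            assert aneuploidy_score(prof, arm_model) == aneuploidy_score(split, arm_model)
            assert segment_count(split) > segment_count(prof)

    def test_chromosome_order_invariance(self, arm_model, rng):
        _, prof = self._random_planted(rng, arm_model)
        shuffled = prof.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert hrd_score(prof, arm_model) == hrd_score(shuffled, arm_model)


class TestDriverTables:
    def test_printed_erg_table(self):
        """Worked example: 2x4 ERG fusion table from the published counts."""
        labels = pd.Series(
            np.repeat(["tF-1", "tF-2", "tF-3", "tF-4"], [89, 52, 38, 147]),
            index=[f"s{i}" for i in range(326)],
        )
        yes = {"tF-1": 34, "tF-2": 12, "tF-3": 16, "tF-4": 84}
        status = []
        for g in ["tF-1", "tF-2", "tF-3", "tF-4"]:
            n = (labels == g).sum()
            status += [True] * yes[g] + [False] * (n - yes[g])
        status = pd.DataFrame({"ERG": status}, index=labels.index)
        out = driver_frequency_tables(labels, status)["ERG"]
        assert out["p_value"] == pytest.approx(1.24e-4, rel=5e-3)
        assert out["percent"].loc["yes", "tF-4"] == pytest.approx(57.14, abs=0.01)

    def test_equal_proportions_p_one(self):
        labels = pd.Series(["a"] * 40 + ["b"] * 40, index=[f"s{i}" for i in range(80)])
        status = pd.DataFrame(
            {"G": [True] * 10 + [False] * 30 + [True] * 10 + [False] * 30},
            index=labels.index,
        )
        out = driver_frequency_tables(labels, status)["G"]
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)


class TestGroupComparison:
    def test_identical_groups_ns(self, rng):
        vals = np.tile(rng.normal(size=30), 3)
        scores = pd.Series(vals, index=[f"s{i}" for i in range(90)])
        labels = pd.Series(np.repeat(["a", "b", "c"], 30), index=scores.index)
        res = group_score_comparison(scores, labels)
        assert (res["pairwise"]["stars"] == "ns").all()

    def test_planted_ordering_detected(self, rng):
        hrd = np.concatenate([rng.poisson(2, 50), rng.poisson(8, 50)])
        scores = pd.Series(hrd, index=[f"s{i}" for i in range(100)])
        labels = pd.Series(["tF-1"] * 50 + ["tF-2"] * 50, index=scores.index)
        res = group_score_comparison(scores, labels)
        assert res["kruskal_p"] < 1e-4
        assert res["pairwise"]["stars"].iloc[0] in ("***", "****")


def test_seg_logratio_dialect(tmp_path):
    from trfscape.instability import call_gains_losses, read_seg_logratio

    path = tmp_path / "cn.seg"
    path.write_text(
        "ID\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n"
        "s1\tchr1\t1\t1000000\t50\t0.45\n"
        "s1\tchr1\t1000001\t2000000\t50\t-0.6\n"
        "s1\tchr2\t1\t500000\t20\t0.05\n"
        "s2\tchr1\t1\t2000000\t80\t0.0\n"
    )
    seg = read_seg_logratio(path)
    calls = call_gains_losses(seg, threshold=0.3)
    assert calls.loc["s1"].to_dict() == {
        "gained_segments": 1, "lost_segments": 1, "n_segments": 3,
    }
    assert calls.loc["s2", "n_segments"] == 1


def test_arm_model_validation():
    bad = pd.DataFrame(
        {"chrom": ["c1"], "length": [100], "cen_start": [150], "cen_end": [160]}
    )
    with pytest.raises(ValueError):
        ArmModel(bad)


def test_arm_model_round_trip(tmp_path, arm_model):
    arm_model.to_tsv(tmp_path / "arms.tsv")
    back = ArmModel.from_tsv(tmp_path / "arms.tsv")
    assert back.chrom_length == arm_model.chrom_length
    assert back.centromere == arm_model.centromere
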
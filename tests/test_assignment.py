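import numpy as np
import pandas as pd
import pytest

from foramtax.assignment import (
    RankBands,
    assign_clade,
    build_rank_bands,
    classify_novelty,
    flag_chimera,
    pair_rank_level,
    summarize_dataset,
)
from foramtax.synthetic_data import make_chimera


class TestPairRankLevel:
    def test_each_pair_contributes_to_exactly_one_level(self):
        base = {"clade": "C", "morphospecies": "M", "lvl1": "L", "lvl2": "G", "lvl3": "B"}
        cases = [
            (dict(base), "intra_basegroup"),
            (dict(base, lvl3="B2"), "inter_basegroup"),
            (dict(base, lvl3="B2", lvl2="G2"), "inter_genotype"),
            (dict(base, lvl3="B2", lvl2="G2", lvl1="L2"), "inter_lineage"),
            (
                dict(base, lvl3="B2", lvl2="G2", lvl1="L2", morphospecies="M2"),
                "congeneric_morphospecies",
            ),
            (
                dict(base, lvl3="B2", lvl2="G2", lvl1="L2", morphospecies="M2", clade="C2"),
                "inter_clade",
            ),
        ]
        for other, expected in cases:
            assert pair_rank_level(base, other) == expected


class TestAssignClade:
    def test_identical_otu_gets_clade_and_zero_distance(self, default_survey):
        res = default_survey["result"]
        ref_id = res.basetypes[0].basetype_id
        aln = res.alignment
        clade, nearest, d, margin = assign_clade(aln[ref_id], aln, res.clades, min_sites=50)
        assert clade == res.clades[ref_id]
        assert d == 0.0
        assert margin > 0

    def test_synthetic_otus_recover_true_clade(self, default_survey):
        truth = default_survey["truth"]
        asg = default_survey["assignments"]
        for otu_id, info in truth.otu_truth.items():
            assert asg.loc[otu_id, "clade"] == info["true_clade"]

    def test_all_masked_is_unassignable(self):
        clade, nearest, d, _ = assign_clade(
            "ACGT" * 5, {"r1": "ACGT" * 5}, {"r1": "Basal"}, min_sites=100
        )
        assert clade == "unassignable" and np.isnan(d)


class TestRankBands:
    def test_identical_references_degenerate_at_zero(self):
        tax = pd.DataFrame(
            {
                "morphospecies": ["M", "M", "M"],
                "lvl1": ["L", "L", "L"],
                "lvl2": ["G", "G", "G"],
                "lvl3": ["B", "B", "B"],
            },
            index=["r1", "r2", "r3"],
        )
        aln = {k: "ACGT" * 60 for k in tax.index}
        clades = {k: "Basal" for k in tax.index}
        bands = build_rank_bands(aln, tax, clades, min_sites=50)
        assert bands.stats["intra_basegroup"]["max"] == 0.0
        assert not bands.available("inter_clade")

    def test_band_medians_ordered_on_synthetic_reference(self, default_survey):
        bands = default_survey["bands"]
        present = [
            lvl
            for lvl in (
                "intra_basegroup",
                "inter_basegroup",
                "inter_genotype",
                "inter_lineage",
                "congeneric_morphospecies",
                "inter_clade",
            )
            if bands.available(lvl)
        ]
        assert len(present) >= 4
        medians = [bands.stats[lvl]["median"] for lvl in present]
        assert all(a < b for a, b in zip(medians, medians[1:]))



    def test_alternative_metric_matrix_banding(self):
        """A supplied square distance table (e.g. patristic) is banded by
        the same shared-rank rule instead of recomputing K80."""
        import pandas as pd

        tax = pd.DataFrame(
            {
                "morphospecies": ["M", "M", "M"],
                "lvl1": ["L", "L", "L"],
                "lvl2": ["G", "G", "G2"],
                "lvl3": ["B", "B2", "B3"],
            },
            index=["r1", "r2", "r3"],
        )
        aln = {k: "ACGT" * 60 for k in tax.index}
        clades = {k: "Basal" for k in tax.index}
        metric = pd.DataFrame(
            [[0.0, 0.01, 0.1], [0.01, 0.0, 0.1], [0.1, 0.1, 0.0]],
            index=tax.index, columns=tax.index,
        )
        bands = build_rank_bands(aln, tax, clades, metric_matrix=metric, min_pairs=1)
        assert bands.metric == "patristic"
        assert bands.stats["inter_basegroup"]["max"] == 0.01
        assert bands.stats["inter_genotype"]["max"] == 0.1


class TestClassifyNovelty:
    BANDS = RankBands(
        stats={
            "inter_basegroup": {"max": 0.03},
            "inter_genotype": {"max": 0.10},
            "inter_lineage": {"max": 0.30},
        }
    )

    @pytest.mark.parametrize(
        "d, expected",
        [
            (0.0, "known_basegroup"),
            (0.02, "known_basegroup"),
            (0.06, "new_genotype"),
            (0.2, "new_lineage"),
            (0.5, "exceeds_morphospecies"),
        ],
    )
    def test_ladder(self, d, expected):
        assert classify_novelty(d, self.BANDS) == expected

    def test_unavailable_band_falls_through_with_warning(self):
        bands = RankBands(stats={"inter_basegroup": {"max": 0.03},
                                 "inter_lineage": {"max": 0.30}})
        with pytest.warns(UserWarning, match="inter_genotype"):
            assert classify_novelty(0.06, bands) == "new_lineage"

    def test_masked_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_novelty(float("nan"), self.BANDS)


class TestChimeraFlag:
    def test_cross_clade_splice_flagged(self, default_survey):
        res = default_survey["result"]
        by_clade = {}
        for bt_id, clade in res.clades.items():
            by_clade.setdefault(clade, bt_id)
        (c1, r1), (c2, r2) = sorted(by_clade.items())[:2]
        aln = res.alignment
        splice = make_chimera(aln[r1], aln[r2])
        assert flag_chimera(splice, aln, res.clades) is True

    def test_intact_reference_not_flagged(self, default_survey):
        res = default_survey["result"]
        aln = res.alignment
        for ref_id in list(aln)[:5]:
            assert flag_chimera(aln[ref_id], aln, res.clades) is False


class TestSummarize:
    def _frame(self):
        asg = pd.DataFrame(
            {
                "clade": ["Basal", "Basal", "Spinose", "Benthic"],
                "novelty": [
                    "known_basegroup",
                    "new_genotype",
                    "exceeds_morphospecies",
                    "benthic_affinity",
                ],
            },
            index=pd.Index(["o1", "o2", "o3", "o4"], name="otu_id"),
        )
        reads = pd.DataFrame(
            {
                "S1|pico": [70, 20, 5, 5],
                "S1|meso": [0, 10, 0, 0],
            },
            index=asg.index,
        )
        return asg, reads

    def test_percentages_arithmetic(self):
        asg, reads = self._frame()
        s = summarize_dataset(asg, reads)
        assert s["pct_otus_attributed"] == pytest.approx(50.0)
        # attributed reads: (70+0) + (20+10) = 100 of 110
        assert s["pct_reads_attributed"] == pytest.approx(100 * 100 / 110)

    def test_all_known_equals_hundred_percent(self):
        asg, reads = self._frame()
        asg["novelty"] = "known_basegroup"
        s = summarize_dataset(asg, reads)
        assert s["pct_otus_attributed"] == 100.0
        assert s["pct_reads_attributed"] == 100.0

    def test_clade_shares_sum_to_hundred_per_fraction(self, default_survey):
        shares = default_survey["summary"]["clade_share_by_fraction"]
        assert np.allclose(shares.sum(axis=1), 100.0, atol=1e-9)

    def test_chimeras_excluded_from_totals(self):
        asg, reads = self._frame()
        asg.loc["o3", "novelty"] = "chimera_flag"
        s = summarize_dataset(asg, reads)
        assert s["n_otus"] == 3
        assert s["pct_otus_attributed"] == pytest.approx(100 * 2 / 3)

    def test_zero_read_dataset_rejected(self):
        asg, reads = self._frame()
        with pytest.raises(ValueError, match="zero-read"):
            summarize_dataset(asg, reads * 0)


def test_references_fed_back_as_otus_return_known(default_survey):
    """Every reference, re-presented as an environmental OTU, must come
    back with its own clade, distance 0 and novelty known_basegroup."""
    from foramtax.assignment import assign_all

    res = default_survey["result"]
    aln = res.alignment
    some_refs = dict(list(aln.items())[::5])
    asg = assign_all(some_refs, aln, res.clades, res.taxonomy, default_survey["bands"],
                     min_sites=50)
    assert (asg["d_k80"] == 0.0).all()
    assert (asg["novelty"] == "known_basegroup").all()
    for ref_id in some_refs:
        assert asg.loc[ref_id, "clade"] == res.clades[ref_id]
        assert asg.loc[ref_id, "motu_lvl3"] == res.taxonomy.loc[ref_id, "lvl3"]
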
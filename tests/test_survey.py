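"""Survey statistics: ANOVA, Tukey HSD, proportion tests, presence screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mpnflux.survey import (BLAST_COLUMNS, count_by_ocean, ocean_enrichment,
                            oneway_anova, records_to_frame, screen_presence,
                            tukey_hsd, two_proportion_test)


class TestOnewayAnova:
    def test_equal_group_means_give_f_zero(self):
        f, p = oneway_anova({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert f == 0.0 and p == 1.0

    def test_matches_scipy_on_textbook_fixture(self):
        groups = {"g1": [6.0, 8.0, 4.0], "g2": [8.0, 12.0, 9.0], "g3": [13.0, 9.0, 11.0]}
        f, p = oneway_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups.values())
        assert f == pytest.approx(f_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_hand_computed_sums_of_squares(self):
        # groups (1,2,3), (2,3,4): grand mean 2.5, SSB = 1.5, SSW = 4,
        # F = (1.5/1)/(4/4) = 1.5
        f, _ = oneway_anova({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0]})
        assert f == pytest.approx(1.5, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova({"only": [1.0, 2.0]})


class TestTukeyHsd:
    def test_identical_groups_not_significant(self):
        comps = tukey_hsd({"a": [3.0, 3.1, 2.9], "b": [3.0, 3.1, 2.9]})
        assert len(comps) == 1
        assert comps[0].p == pytest.approx(1.0, abs=1e-6)
        assert not comps[0].significant

    def test_formate_pattern_mpn_vs_reference(self):
        # per-cell formate means like the published pattern: MPn/HMPn ~48,
        # Pi/phosphite ~27, triplicates with small SD
        rng = np.random.default_rng(0)
        groups = {
            "MPn": (48 + rng.normal(0, 0.2, 3)).tolist(),
            "HMPn": (48 + rng.normal(0, 0.2, 3)).tolist(),
            "Pi": (27 + rng.normal(0, 0.8, 3)).tolist(),
            "phosphite": (27 + rng.normal(0, 0.8, 3)).tolist(),
        }
        comps = {(c.group1, c.group2): c for c in tukey_hsd(groups)}
        assert comps[("HMPn", "MPn")].significant is False
        assert comps[("Pi", "phosphite")].significant is False
        for pair in [("MPn", "Pi"), ("MPn", "phosphite"),
                     ("HMPn", "Pi"), ("HMPn", "phosphite")]:
            key = tuple(sorted(pair))
            assert comps[key].significant

    def test_matches_statsmodels_oracle(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(loc, 1.0, 5).tolist()
                  for g, loc in [("a", 0.0), ("b", 1.5), ("c", 3.0)]}
        ours = {(c.group1, c.group2): c for c in tukey_hsd(groups)}
        values = np.concatenate([groups[g] for g in sorted(groups)])
        labels = np.repeat(sorted(groups), 5)
        res = statsmodels.pairwise_tukeyhsd(values, labels)
        import itertools
        pairs = list(itertools.combinations(sorted(groups), 2))
        for (g1, g2), padj in zip(pairs, res.pvalues):
            assert ours[(g1, g2)].p == pytest.approx(padj, abs=1e-6)

    def test_significance_monotone_in_mean_difference(self):
        base = np.array([0.0, 0.5, -0.5, 0.25, -0.25])
        ps = []
        for delta in (0.5, 1.5, 3.0, 6.0):
            comps = tukey_hsd({"a": base.tolist(), "b": (base + delta).tolist()})
            ps.append(comps[0].p)
        assert ps == sorted(ps, reverse=True)


class TestTwoProportion:
    def test_printed_enrichment_statistic(self):
        res = two_proportion_test(14, 219, 1, 187, alternative="greater")
        assert round(res.chi2, 2) == 8.15
        assert res.p == pytest.approx(0.002151, abs=5e-7)
        assert res.df == 1

    def test_identical_proportions(self):
        res = two_proportion_test(5, 10, 5, 10)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_swap_symmetric_chi2_mirrored_one_sided_p(self):
        a = two_proportion_test(14, 219, 1, 187, alternative="greater")
        b = two_proportion_test(1, 187, 14, 219, alternative="greater")
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)
        assert a.p + b.p == pytest.approx(1.0, rel=1e-9)
        c = two_proportion_test(1, 187, 14, 219, alternative="less")
        assert c.p == pytest.approx(a.p, rel=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(data=st.data())
    def test_uncorrected_equals_direct_2x2_chi_square(self, data):
        n1 = data.draw(st.integers(2, 200))
        n2 = data.draw(st.integers(2, 200))
        x1 = data.draw(st.integers(1, n1 - 1))
        x2 = data.draw(st.integers(1, n2 - 1))
        res = two_proportion_test(x1, n1, x2, n2, continuity=False)
        # brute-force oracle: sum (O - E)^2 / E over the 2x2 table
        obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        direct = ((obs - expected) ** 2 / expected).sum()
        assert res.chi2 == pytest.approx(direct, rel=1e-12)
        chi2_ref, p_ref, _, _ = sps.chi2_contingency(obs, correction=False)
        assert res.chi2 == pytest.approx(chi2_ref, rel=1e-9)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_yates_matches_scipy_correction(self):
        res = two_proportion_test(14, 219, 1, 187)
        obs = [[14, 205], [1, 186]]
        chi2_ref, p_ref, _, _ = sps.chi2_contingency(obs, correction=True)
        assert res.chi2 == pytest.approx(chi2_ref, rel=1e-9)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(11, 10, 1, 10)


class TestPresenceScreen:
    def test_published_table_counts(self, survey_fixture):
        aln, meta, refs, _ = survey_fixture
        records = screen_presence(aln, meta, reference_ids=refs)
        non_ref_present = [r for r in records if r.present and not r.is_reference]
        assert len(non_ref_present) == 16
        counts = count_by_ocean(records)
        assert counts == {"NAO": 12, "RS": 3, "NPO": 1}

    def test_threshold_raised_keeps_only_exact_matches(self, survey_fixture):
        aln, meta, refs, _ = survey_fixture
        records = screen_presence(aln, meta, id_threshold=99.9, reference_ids=refs)
        present = {r.genome_id for r in records if r.present}
        assert present == {"MIT9301", "MIT9303"}  # the 100/100 self-hits

    def test_empty_alignments_nothing_present(self, survey_fixture):
        _, meta, refs, _ = survey_fixture
        empty = pd.DataFrame(columns=list(BLAST_COLUMNS))
        records = screen_presence(empty, meta, reference_ids=refs)
        assert not any(r.present for r in records)

    def test_order_independent_and_idempotent(self, survey_fixture):
        aln, meta, refs, _ = survey_fixture
        shuffled = aln.sample(frac=1.0, random_state=3).reset_index(drop=True)
        r1 = screen_presence(aln, meta, reference_ids=refs)
        r2 = screen_presence(shuffled, meta, reference_ids=refs)
        assert records_to_frame(r1).equals(records_to_frame(r2))

    def test_require_both_proteins(self, survey_fixture):
        aln, meta, refs, _ = survey_fixture
        only_y = aln[aln["qseqid"].str.contains("PhnY")]
        records = screen_presence(only_y, meta, reference_ids=refs)
        assert not any(r.present for r in records)
        records_any = screen_presence(only_y, meta, require_both=False,
                                      reference_ids=refs)
        assert sum(r.present for r in records_any) == 18

    def test_best_hit_prefers_bitscore_then_identity(self, survey_fixture):
        _, meta, refs, _ = survey_fixture
        rows = []
        for prot in ("PhnY", "PhnZ"):
            # a low-identity high-bitscore decoy must lose to nothing: best
            # hit is the max-bitscore row
            rows.append(dict(qseqid=f"{prot}_MIT9301", sseqid="MIT9302",
                             pident=99.0, length=190, mismatch=0, gapopen=0,
                             qstart=1, qend=190, sstart=1, send=190,
                             evalue=1e-100, bitscore=400.0))
            rows.append(dict(qseqid=f"{prot}_MIT9301", sseqid="MIT9302",
                             pident=50.0, length=190, mismatch=0, gapopen=0,
                             qstart=1, qend=190, sstart=1, send=190,
                             evalue=1e-10, bitscore=100.0))
        records = screen_presence(pd.DataFrame(rows), meta, reference_ids=refs)
        rec = {r.genome_id: r for r in records}["MIT9302"]
        assert rec.identity_phnY == 99.0 and rec.present


class TestOceanCounts:
    def test_empty_records(self):
        assert count_by_ocean([]) == {}

    def test_enrichment_reproduces_printed_proportions(self, survey_fixture):
        aln, meta, refs, totals = survey_fixture
        records = screen_presence(aln, meta, reference_ids=refs)
        props, test = ocean_enrichment(records, totals)
        assert round(props["NAO"] * 100, 1) == 6.4
        assert round(props["NPO"] * 100, 1) == 0.5
        assert round(test.chi2, 2) == 8.15

    def test_zero_presence_both_oceans(self):
        props, test = ocean_enrichment([], {"NAO": 50, "NPO": 40})
        assert props == {"NAO": 0.0, "NPO": 0.0}
        assert test.chi2 == 0.0
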
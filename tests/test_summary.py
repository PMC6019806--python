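import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methexpr import (ValidationError, build_lists, classify_gene_length,
                      coeff_filter, intersect_final, merge_long_short,
                      summarize_gene)
from methexpr.model import PairFit
from methexpr.summary import summarize_all_genes
from methexpr.types import GeneAnnotation


def make_fit(gene="G", beta1=1.0, p=0.01, status="ok", ps="ps1", pr="pr1"):
    return PairFit(gene=gene, probeset_id=ps, probe_id=pr, beta1=beta1,
                   beta1_p=p, status=status)


def make_fits(gene, beta1s, ps):
    return [make_fit(gene, b, p, pr=f"pr{i}") for i, (b, p) in
            enumerate(zip(beta1s, ps))]


fit_lists = st.lists(
    st.tuples(st.floats(-3, 3), st.floats(0, 1)), min_size=1, max_size=40,
).map(lambda rows: make_fits("G", [r[0] for r in rows], [r[1] for r in rows]))


class TestClassifyGeneLength:
    @pytest.mark.parametrize("m,n,expected", [
        (3, 5, "long"),    # m strictly above the 2-probeset cut
        (1, 21, "long"),   # n strictly above the 20-probe cut
        (2, 20, "short"),  # boundary: neither strict inequality holds
        (1, 1, "short"),
    ])
    def test_rule(self, m, n, expected):
        assert classify_gene_length(m, n) == expected

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            classify_gene_length(0, 5)


class TestSummarizeGene:
    def test_long_gene_fraction_passes_strictly(self):
        fits = make_fits("G", [1.0] * 20, [0.01] * 4 + [0.5] * 16)
        s = summarize_gene(fits, m=4, n=5)  # long (m > 2)
        assert s.length_class == "long"
        assert s.frac_sig == pytest.approx(0.20)
        assert s.passes_frac_threshold  # 0.20 > 0.15

    def test_exact_half_signs_gives_no_direction(self):
        fits = make_fits("G", [1.0] * 5 + [-1.0] * 5, [0.01] * 10)
        s = summarize_gene(fits, m=2, n=5)
        assert s.direction == "none"

    def test_short_gene_boundary_fraction_fails(self):
        fits = make_fits("G", [1.0] * 10, [0.01] * 3 + [0.5] * 7)
        s = summarize_gene(fits, m=2, n=5)  # short
        assert s.frac_sig == pytest.approx(0.30)
        assert not s.passes_frac_threshold  # NOT > 0.30

    def test_degenerate_fits_excluded_from_both_counts(self):
        fits = make_fits("G", [1.0] * 4, [0.01] * 4)
        fits += [make_fit("G", status="degenerate", pr="prX"),
                 make_fit("G", status="degenerate", pr="prY")]
        s = summarize_gene(fits, m=1, n=6)
        assert s.n_pairs == 4 and s.n_sig_pairs == 4 and s.n_degenerate == 2
        assert s.frac_sig == 1.0

    def test_zero_coefficient_counts_for_neither_sign(self):
        fits = make_fits("G", [0.0, 1.0, -1.0], [0.5] * 3)
        s = summarize_gene(fits, m=1, n=3)
        assert s.n_pos_coeff == 1 and s.n_neg_coeff == 1
        assert s.direction == "none"

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValidationError):
            summarize_gene([make_fit("A"), make_fit("B")], m=1, n=2)

    @given(fit_lists, st.sampled_from([0.15, 0.3, 0.5]))
    def test_raising_fraction_cut_never_grows_passing_set(self, fits, frac):
        lo = summarize_gene(fits, m=1, n=len(fits), long_frac=frac,
                            short_frac=frac)
        hi = summarize_gene(fits, m=1, n=len(fits), long_frac=frac + 0.2,
                            short_frac=frac + 0.2)
        assert hi.passes_frac_threshold <= lo.passes_frac_threshold


class TestCoeffFilter:
    def test_worked_example_cut_half(self):
        fits = make_fits("G", [0.6, 0.4, 1.2], [0.01] * 3)
        assert coeff_filter(fits, 0.5, "pos").n_pairs == 2
        assert coeff_filter(fits, 1.0, "pos").n_pairs == 1

    def test_requires_significance_too(self):
        fits = make_fits("G", [2.0, 2.0], [0.01, 0.2])
        assert coeff_filter(fits, 0.5, "pos").n_pairs == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(17)
        fits = [make_fit(f"G{i % 11}", b, p, pr=f"pr{i}")
                for i, (b, p) in enumerate(zip(rng.normal(0, 1, 50),
                                               rng.random(50)))]
        for cut in (0.5, 1.0):
            for sign in ("pos", "neg"):
                res = coeff_filter(fits, cut, sign)
                brute = {f.gene for f in fits
                         if f.beta1_p < 0.05
                         and ((f.beta1 > cut) if sign == "pos"
                              else (f.beta1 < -cut))}
                n_brute = sum(1 for f in fits
                              if f.beta1_p < 0.05
                              and ((f.beta1 > cut) if sign == "pos"
                                   else (f.beta1 < -cut)))
                assert set(res.genes) == brute
                assert res.n_pairs == n_brute
                assert len(res.genes) <= res.n_pairs  # unique-gene bound

    @given(fit_lists)
    def test_raising_cut_is_monotone(self, fits):
        lo = coeff_filter(fits, 0.5, "pos")
        hi = coeff_filter(fits, 1.0, "pos")
        assert hi.n_pairs <= lo.n_pairs
        assert hi.genes <= lo.genes


class TestListArithmetic:
    def test_merge_and_intersect_set_identities(self):
        long_set = {f"L{i}" for i in range(10)}
        short_set = {f"S{i}" for i in range(7)}
        merged = merge_long_short(long_set, short_set)
        assert merged == long_set | short_set and len(merged) == 17
        assert merge_long_short(set(), set()) == set()
        assert intersect_final({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}
        assert intersect_final({"A"}, {"B"}) == set()

    def test_merge_rejects_overlap(self):
        with pytest.raises(ValidationError):
            merge_long_short({"A", "B"}, {"B", "C"})


class TestBuildLists:
    def _run(self, dataset):
        from methexpr import fit_all_pairs
        fits = fit_all_pairs(dataset.expression, dataset.methylation,
                             dataset.phenotypes, dataset.annotations)
        summaries = summarize_all_genes(fits, dataset.annotations)
        return fits, summaries, build_lists(summaries, fits)

    def test_matches_end_to_end_brute_force(self, small_dataset):
        fits, summaries, lists = self._run(small_dataset)
        ann = {a.gene: a for a in small_dataset.annotations}

        # independent scripted recomputation from the raw fit list
        by_gene = {}
        for f in fits:
            by_gene.setdefault(f.gene, []).append(f)
        expect = {"pos_long": set(), "pos_short": set(),
                  "neg_long": set(), "neg_short": set()}
        for g, gf in by_gene.items():
            ok = [f for f in gf if f.status == "ok"]
            if not ok:
                continue
            length = ("long" if ann[g].m > 2 or ann[g].n > 20 else "short")
            frac = sum(f.beta1_p < 0.05 for f in ok) / len(ok)
            if not frac > (0.15 if length == "long" else 0.30):
                continue
            npos = sum(f.beta1 > 0 for f in ok)
            nneg = sum(f.beta1 < 0 for f in ok)
            if npos > len(ok) / 2:
                expect[f"pos_{length}"].add(g)
            elif nneg > len(ok) / 2:
                expect[f"neg_{length}"].add(g)
        coeff_pos = {f.gene for f in fits if f.status == "ok"
                     and f.beta1_p < 0.05 and f.beta1 > 0.5}
        coeff_neg = {f.gene for f in fits if f.status == "ok"
                     and f.beta1_p < 0.05 and f.beta1 < -0.5}
        assert lists.pos_long == expect["pos_long"]
        assert lists.pos_short == expect["pos_short"]
        assert lists.neg_long == expect["neg_long"]
        assert lists.neg_short == expect["neg_short"]
        assert lists.pos_merged == expect["pos_long"] | expect["pos_short"]
        assert lists.pos_final == coeff_pos & lists.pos_merged
        assert lists.neg_final == coeff_neg & lists.neg_merged
        assert lists.all_final == lists.pos_final | lists.neg_final

    def test_direction_partition(self, small_dataset):
        _, summaries, lists = self._run(small_dataset)
        assert all(s.direction in ("positive", "negative", "none")
                   for s in summaries)
        assert not lists.pos_final & lists.neg_final

    def test_no_passing_gene_gives_empty_lists(self):
        fits = make_fits("G", [1.0] * 10, [0.9] * 10)
        summaries = summarize_all_genes(
            fits, [GeneAnnotation("G", ("ps1",), tuple(f"pr{i}" for i in range(10)))])
        lists = build_lists(summaries, fits)
        assert lists.all_final == set() and lists.pos_merged == set()
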
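"""PSSM scoring, percentile selection, overlap counting, score correlation."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinmotif import (
    CandidateSite,
    NoiseModel,
    SiteScore,
    build_scoring_matrix,
    cap_acceptor_like_residues,
    filter_sites,
    make_true_motif,
    overlap_analysis,
    percentile_select,
    run_motif_pipeline,
    score_correlation,
    score_site,
    score_sites,
    simulate_spot_grids,
)
from kinmotif.alphabet import AMINO_ACIDS
from kinmotif.errors import AlphabetError, InputError, ParameterError, StageError

from .conftest import make_motif


def _matrix(seed=0, **kw):
    t = make_true_motif("K", seed=seed, **kw)
    return build_scoring_matrix(cap_acceptor_like_residues(t.as_motif_matrix()))


class TestBuildScoringMatrix:
    def test_flat_motif_all_entries_one(self, flat_motif):
        matrix = build_scoring_matrix(flat_motif)
        assert (matrix.entries.to_numpy() == 1.0).all()

    def test_rejects_log2_stage(self, flat_motif):
        from kinmotif import log_transform

        with pytest.raises(StageError):
            build_scoring_matrix(log_transform(flat_motif))

    def test_entries_below_floor_clamped(self):
        m = make_motif(np.ones((9, 22)), stage="capped")
        m.values.at[-1, "W"] = 0.0
        matrix = build_scoring_matrix(m)
        assert matrix.entries.at[-1, "W"] == pytest.approx(2.0**-6)

    def test_missing_cells_get_neutral_value(self):
        m = make_motif(np.ones((9, 22)), stage="capped")
        m.values.at[2, "C"] = np.nan
        matrix = build_scoring_matrix(m)
        assert matrix.entries.at[2, "C"] == 1.0

    def test_max_entry_per_position_at_least_one(self, random_grid):
        capped, _ = run_motif_pipeline([random_grid, random_grid])
        matrix = build_scoring_matrix(capped)
        assert (matrix.entries.max(axis=1) >= 1.0 - 1e-9).all()


class TestScoreSite:
    def test_optimal_window_scores_zero(self):
        matrix = _matrix(seed=1, n_selective_positions=6, preference_strength=10)
        site = CandidateSite("P", 1, "S", matrix.optimal_window())
        assert score_site(matrix, site).score == 0.0

    def test_flat_matrix_scores_everything_zero(self, flat_motif):
        matrix = build_scoring_matrix(flat_motif)
        for window in ("AAAAAAAAA", "WYWYWYWYW", "LKCMNPQRS"):
            assert score_site(matrix, CandidateSite("P", 1, "S", window)).score == 0.0

    def test_exhaustive_two_position_enumeration_matches_bruteforce(self):
        """All 400 windows varying at two positions rank identically to a
        brute-force oracle; the minimum is 0 exactly once (unique argmax)."""
        rng = np.random.default_rng(2)
        m = make_motif(np.ones((9, 22)), stage="capped")
        col_a = rng.uniform(0.1, 1.0, 20)
        col_b = rng.uniform(0.1, 1.0, 20)
        col_a[4], col_b[11] = 3.0, 2.0  # unique maxima
        for i, aa in enumerate(AMINO_ACIDS):
            m.values.at[-2, aa] = col_a[i]
            m.values.at[1, aa] = col_b[i]
        matrix = build_scoring_matrix(m)
        base = list(matrix.optimal_window())
        scores, oracle = [], []
        for ra, rb in product(AMINO_ACIDS, repeat=2):
            window = base.copy()
            window[3], window[5] = ra, rb  # indices of positions -2 and +1
            s = score_site(matrix, CandidateSite("P", 1, "S", "".join(window))).score
            scores.append(s)
            expected = (
                math.log2(col_a.max()) - math.log2(col_a[AMINO_ACIDS.index(ra)])
                + math.log2(col_b.max()) - math.log2(col_b[AMINO_ACIDS.index(rb)])
            ) / 9
            oracle.append(expected)
        assert np.allclose(scores, oracle, atol=1e-12)
        assert np.argsort(scores).tolist() == np.argsort(oracle).tolist()
        assert sum(s == 0.0 for s in scores) == 1

    def test_rescaling_columns_leaves_scores_unchanged(self):
        matrix = _matrix(seed=3)
        scaled = _matrix(seed=3)
        scaled.entries.loc[-2] *= 37.0
        scaled.entries.loc[3] *= 0.01
        rng = np.random.default_rng(4)
        for _ in range(20):
            window = "".join(rng.choice(list(AMINO_ACIDS), 9))
            site = CandidateSite("P", 1, "S", window)
            assert score_site(matrix, site).score == pytest.approx(
                score_site(scaled, site).score, abs=1e-12
            )

    def test_padding_excluded_from_mean(self):
        matrix = _matrix(seed=5, n_selective_positions=0)
        m = make_motif(np.ones((9, 22)), stage="capped")
        m.values.at[1, "L"] = 4.0
        matrix = build_scoring_matrix(m)
        # window with only position +1 scored (rest padding): deviation is full log2(4)
        window = "_____A___"
        assert score_site(matrix, CandidateSite("P", 1, "S", window)).score == pytest.approx(2.0)

    def test_modified_residue_uses_phospho_column(self):
        m = make_motif(np.ones((9, 22)), stage="capped")
        m.values.at[-1, "pY"] = 1.0
        m.values.at[-1, "A"] = 4.0
        matrix = build_scoring_matrix(m)
        window = list("AAAAAAAAA")
        window[4] = "y"  # phospho-Tyr at -1
        score_mod = score_site(matrix, CandidateSite("P", 1, "S", "".join(window))).score
        assert score_mod == pytest.approx(2.0 / 9)  # log2(4/1)/9

    def test_unknown_character_rejected(self):
        matrix = _matrix(seed=6)
        with pytest.raises(AlphabetError):
            score_site(matrix, CandidateSite("P", 1, "S", "AAAA#AAAA"))

    def test_score_nonnegative_random_windows(self):
        matrix = _matrix(seed=7, n_selective_positions=5, preference_strength=8)
        rng = np.random.default_rng(8)
        for _ in range(50):
            window = "".join(rng.choice(list(AMINO_ACIDS), 9))
            assert score_site(matrix, CandidateSite("P", 1, "S", window)).score >= 0.0


class TestFilterSites:
    def test_wrong_acceptor_removed_and_dupes_dropped(self):
        matrix = _matrix(seed=9)  # acceptor_set {S, T}
        sites = [CandidateSite(f"P{i}", 10, "S", "AAAAAAAAA") for i in range(7)]
        sites.append(CandidateSite("P0", 10, "S", "AAAAAAAAA"))  # dup of P0
        sites.append(CandidateSite("P1", 10, "T", "AAAAAAAAA"))  # dup key, diff acceptor
        sites.append(CandidateSite("PY", 10, "Y", "AAAAAAAAA"))  # wrong acceptor
        kept = filter_sites(sites, matrix, dedupe=True)
        assert len(kept) == 7
        assert all(s.acceptor_residue in ("S", "T") for s in kept)


class TestPercentileSelect:
    def test_exact_count_without_ties(self):
        scores = [SiteScore(f"P{i}", i, "K", i / 100) for i in range(100)]
        assert len(percentile_select(scores, 0.10)) == 10

    def test_fraction_one_selects_all(self):
        scores = [SiteScore(f"P{i}", i, "K", i / 10) for i in range(10)]
        assert len(percentile_select(scores, 1.0)) == 10

    def test_boundary_ties_all_included(self):
        values = [0.0, 0.1, 0.1, 0.1, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        scores = [SiteScore(f"P{i}", i, "K", v) for i, v in enumerate(values)]
        chosen = percentile_select(scores, 0.2)  # ceil(2) but 3-way tie at 0.1
        assert len(chosen) == 4
        assert {s.score for s in chosen} == {0.0, 0.1}

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        f1=st.floats(min_value=0.01, max_value=1.0),
        f2=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_monotone_in_fraction(self, f1, f2):
        rng = np.random.default_rng(10)
        scores = [SiteScore(f"P{i}", i, "K", float(v)) for i, v in enumerate(rng.uniform(size=40))]
        lo, hi = sorted([f1, f2])
        small = {s.key for s in percentile_select(scores, lo)}
        large = {s.key for s in percentile_select(scores, hi)}
        assert small <= large

    def test_invalid_fraction_rejected(self):
        scores = [SiteScore("P", 1, "K", 0.5)]
        for f in (0.0, 1.5, -0.1):
            with pytest.raises(ParameterError):
                percentile_select(scores, f)


class TestOverlap:
    def test_identical_sets_single_region(self):
        s = {("P", i) for i in range(7)}
        result = overlap_analysis({"A": set(s), "B": set(s), "C": set(s), "D": set(s)})
        assert result["regions"] == {"A&B&C&D": 7}
        assert result["total"] == 7

    def test_disjoint_sets_singleton_regions(self):
        result = overlap_analysis({"A": {1, 2}, "B": {3}, "C": {4, 5, 6}})
        assert result["regions"] == {"A": 2, "B": 1, "C": 3}

    def test_counts_match_bruteforce_and_sum_to_union(self):
        rng = np.random.default_rng(11)
        universe = list(range(200))
        sets = {k: set(rng.choice(universe, 60, replace=False).tolist()) for k in "ABCD"}
        result = overlap_analysis(sets)
        # brute-force oracle: classify every element by its membership pattern
        oracle: dict[str, int] = {}
        for e in set().union(*sets.values()):
            key = "&".join(k for k in sorted(sets) if e in sets[k])
            oracle[key] = oracle.get(key, 0) + 1
        assert result["regions"] == oracle
        assert sum(result["regions"].values()) == len(set().union(*sets.values()))

    def test_reference_shared_fraction(self):
        result = overlap_analysis({"A": {1, 2, 3, 4}, "B": {3, 4, 9}}, reference="A")
        assert result["reference_shared_fraction"] == pytest.approx(0.5)

    def test_set_count_bounds(self):
        with pytest.raises(ParameterError):
            overlap_analysis({"A": {1}})
        with pytest.raises(ParameterError):
            overlap_analysis({k: {1} for k in "ABCDEFG"})


class TestScoreCorrelation:
    def test_self_correlation_is_one(self):
        scores = [SiteScore(f"P{i}", i, "K", float(i)) for i in range(10)]
        r, _ = score_correlation(scores, scores)
        assert r == pytest.approx(1.0)

    def test_same_truth_higher_than_different_truth(self):
        """Two kinases screened from the same motif correlate more strongly in
        site scores than kinases from unrelated motifs."""
        truth_a = make_true_motif("A", n_selective_positions=5, preference_strength=8, seed=12)
        truth_b = make_true_motif("B", n_selective_positions=5, preference_strength=8, seed=13)
        from kinmotif import SiteDatabaseSpec, simulate_site_database

        sites = simulate_site_database(SiteDatabaseSpec(n_background=300, n_implanted_per_kinase=0, seed=14), [])

        def recovered_scores(truth, noise_seed):
            grids = simulate_spot_grids(truth, NoiseModel(0.15, seed=noise_seed), 2)
            capped, _ = run_motif_pipeline(grids)
            return score_sites(build_scoring_matrix(capped), sites)

        a1 = recovered_scores(truth_a, 15)
        a2 = recovered_scores(truth_a, 16)
        b1 = recovered_scores(truth_b, 17)
        r_same, _ = score_correlation(a1, a2)
        r_diff, _ = score_correlation(a1, b1)
        assert r_same > r_diff

    def test_key_mismatch_rejected(self):
        a = [SiteScore("P1", 1, "K", 0.1), SiteScore("P2", 2, "K", 0.4)]
        b = [SiteScore("P1", 1, "K", 0.2), SiteScore("P3", 3, "K", 0.5)]
        with pytest.raises(InputError):
            score_correlation(a, b)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(18)
        x, y = rng.uniform(size=30), rng.uniform(size=30)
        a = [SiteScore(f"P{i}", i, "K", float(v)) for i, v in enumerate(x)]
        b = [SiteScore(f"P{i}", i, "K", float(v)) for i, v in enumerate(y)]
        r, _ = score_correlation(a, b)
        oracle = float(np.corrcoef(x, y)[0, 1])
        assert r == pytest.approx(oracle, abs=1e-12)
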
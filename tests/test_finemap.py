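"""Recombinant analysis, progeny test and substitution mapping."""

import numpy as np
import pandas as pd
import pytest

from qtlhotspot.finemap import (
    HIGH,
    LOW,
    delimit_interval,
    diagnostic_marker_score,
    enumerate_genotype_classes,
    find_recombinants,
    genome_recovery,
    graphical_genotype,
    progeny_test_classify,
)
from qtlhotspot.io_formats import MarkerMatrix


def make_matrix(calls_rows, bps, chrom="Ca4", ids=None, cms=None):
    markers = [f"M{i}" for i in range(1, len(bps) + 1)]
    ids = ids or [f"I{i}" for i in range(1, len(calls_rows) + 1)]
    mm = pd.DataFrame({
        "chrom": chrom,
        "cm": cms if cms is not None else np.linspace(0, 1, len(bps)),
        "bp": bps,
    }, index=pd.Index(markers, name="marker"))
    calls = pd.DataFrame([list(r) for r in calls_rows], index=ids, columns=markers)
    return MarkerMatrix(calls=calls, marker_map=mm)


class TestGraphicalGenotype:
    def test_uniform_calls_give_one_segment(self):
        m = make_matrix(["AAA"], [100, 200, 300])
        gg = graphical_genotype(m, "I1")
        assert gg.segments["Ca4"] == [("A", 100, 300)]

    def test_boundary_at_midpoint_between_discordant_markers(self):
        m = make_matrix(["AB"], [100, 300])
        gg = graphical_genotype(m, "I1")
        assert gg.segments["Ca4"] == [("A", 100, 200), ("B", 201, 300)]

    def test_missing_between_agreeing_neighbours_imputed(self):
        m = make_matrix(["A-A"], [100, 200, 300])
        gg = graphical_genotype(m, "I1")
        assert gg.segments["Ca4"] == [("A", 100, 300)]

    def test_missing_between_disagreeing_neighbours_is_unknown(self):
        m = make_matrix(["A-B"], [100, 200, 300])
        gg = graphical_genotype(m, "I1")
        states = [s for s, _, _ in gg.segments["Ca4"]]
        assert states == ["A", "unknown", "B"]

    def test_all_missing_chromosome_is_an_error(self):
        m = make_matrix(["--"], [100, 200])
        with pytest.raises(ValueError, match="all markers missing"):
            graphical_genotype(m, "I1")

    def test_segments_reconstruct_calls_at_marker_positions(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(2, 9))
            row = "".join(rng.choice(list("ABH"), size=n))
            bps = sorted(rng.choice(np.arange(100, 5000), size=n, replace=False))
            m = make_matrix([row], [int(b) for b in bps])
            gg = graphical_genotype(m, "I1")
            for marker, call in zip(m.markers, row):
                bp = int(m.marker_map.loc[marker, "bp"])
                assert gg.state_at("Ca4", bp) == call


class TestGenotypeClasses:
    def test_identical_individuals_form_one_class(self):
        m = make_matrix(["AB", "AB", "AB"], [100, 200])
        out = enumerate_genotype_classes(m, ["M1", "M2"])
        assert len(out) == 1
        assert out.loc[0, "count"] == 3

    def test_hand_enumeration_of_three_classes(self):
        m = make_matrix(["AA", "AB", "AB", "BB"], [100, 200])
        out = enumerate_genotype_classes(m, ["M1", "M2"])
        assert list(out["count"]) == [2, 1, 1]
        assert out.loc[0, "genotype"] == "AB"

    def test_missing_is_its_own_symbol(self):
        m = make_matrix(["A-", "AA"], [100, 200])
        out = enumerate_genotype_classes(m, ["M1", "M2"])
        assert len(out) == 2

    def test_unknown_marker_rejected(self):
        m = make_matrix(["AA"], [100, 200])
        with pytest.raises(KeyError, match="M9"):
            enumerate_genotype_classes(m, ["M9"])


class TestRecombinants:
    def test_uniform_region_not_recombinant(self):
        m = make_matrix(["AAAA", "BBBB"], [100, 200, 300, 400])
        assert find_recombinants(m, "M1", "M4") == []

    def test_discordant_flanks_are_recombinant(self):
        m = make_matrix(["AAAB"], [100, 200, 300, 400])
        assert find_recombinants(m, "M1", "M4") == ["I1"]

    def test_internal_state_change_detected(self):
        m = make_matrix(["AABB"], [100, 200, 300, 400])
        assert find_recombinants(m, "M1", "M4") == ["I1"]

    def test_flanks_on_different_chromosomes_rejected(self):
        markers = ["M1", "M2"]
        mm = pd.DataFrame({"chrom": ["Ca1", "Ca2"], "cm": [0.0, 0.0],
                           "bp": [100, 100]},
                          index=pd.Index(markers, name="marker"))
        calls = pd.DataFrame([["A", "A"]], index=["I1"], columns=markers)
        m = MarkerMatrix(calls=calls, marker_map=mm)
        with pytest.raises(ValueError, match="different chromosomes"):
            find_recombinants(m, "M1", "M2")


class TestProgenyTest:
    def test_split_at_largest_gap_matches_observed_groups(self):
        # family means spanning the observed group ranges (high
        # 16.88-20.23 g, low 14.12-14.95 g): the largest gap falls at the
        # 16.88 / 14.95 boundary once within-group spread is populated
        means = {"f1": 20.23, "f2": 18.6, "f3": 16.88,
                 "f4": 14.95, "f5": 14.5, "f6": 14.12}
        res = progeny_test_classify(means)
        assert res.classes == {"f1": HIGH, "f2": HIGH, "f3": HIGH,
                               "f4": LOW, "f5": LOW, "f6": LOW}
        assert res.gap == pytest.approx(16.88 - 14.95)

    def test_two_families(self):
        res = progeny_test_classify({"a": 10.0, "b": 20.0})
        assert res.classes == {"a": LOW, "b": HIGH}
        assert res.separation_ratio == float("inf")

    def test_equal_means_demand_external_threshold(self):
        with pytest.raises(ValueError, match="external threshold"):
            progeny_test_classify({"a": 5.0, "b": 5.0, "c": 5.0})

    def test_se_scale_noise_recovers_planted_labels(self):
        from qtlhotspot.simulate import (
            simulate_family_means,
            simulate_recombinant_families,
        )

        rng = np.random.default_rng(123)
        for _ in range(100):
            fam = simulate_recombinant_families(rng=rng)
            means = simulate_family_means(fam.classes, rng=rng)
            res = progeny_test_classify(means)
            assert res.classes == fam.classes


def brute_force_interval(matrix, classes):
    """Oracle: per-marker cosegregation by explicit loops, then an explicit
    scan over all contiguous marker windows for maximal all-cosegregating
    runs."""
    names = matrix.markers
    coseg = []
    for m in names:
        ok = True
        for fam, cls in classes.items():
            call = matrix.calls.at[fam, m]
            if call != ("B" if cls == HIGH else "A"):
                ok = False
        coseg.append(ok)
    runs = []
    n = len(names)
    for i in range(n):
        for j in range(i, n):
            window_ok = all(coseg[i:j + 1])
            left_max = i == 0 or not coseg[i - 1]
            right_max = j == n - 1 or not coseg[j + 1]
            if window_ok and left_max and right_max:
                runs.append((i, j))
    return coseg, runs


class TestDelimitInterval:
    def test_toy_six_marker_example(self, toy_matrix):
        # F4 carries a donor segment at M1-M2, so those markers cannot
        # cosegregate; the run is M3-M4 flanked by M2 and M5
        classes = {"F1": HIGH, "F2": HIGH, "F3": LOW, "F4": LOW}
        iv = delimit_interval(toy_matrix, classes)
        assert (iv.left_marker, iv.right_marker) == ("M2", "M5")
        assert iv.inner_markers == ["M3", "M4"]

    def test_inner_run_with_flanks(self):
        # high families donor-homozygous at markers 3-4 only
        m = make_matrix(
            ["AABBAA", "AABBAA", "AAAAAA", "AAAAAA"],
            [100, 300, 500, 700, 900, 1100],
            ids=["H1", "H2", "L1", "L2"],
        )
        classes = {"H1": HIGH, "H2": HIGH, "L1": LOW, "L2": LOW}
        iv = delimit_interval(m, classes)
        assert (iv.left_marker, iv.right_marker) == ("M2", "M5")
        assert iv.inner_markers == ["M3", "M4"]
        assert iv.span_bp == 900 - 300

    def test_all_markers_cosegregating_spans_terminal_markers(self):
        m = make_matrix(["BBB", "AAA"], [100, 500, 900], ids=["H1", "L1"])
        iv = delimit_interval(m, {"H1": HIGH, "L1": LOW})
        assert (iv.left_marker, iv.right_marker) == ("M1", "M3")
        assert iv.inner_markers == ["M1", "M2", "M3"]

    def test_heterozygous_family_rejected(self):
        m = make_matrix(["BHB", "AAA"], [100, 500, 900], ids=["H1", "L1"])
        with pytest.raises(ValueError, match="not homozygous"):
            delimit_interval(m, {"H1": HIGH, "L1": LOW})

    def test_single_class_rejected(self):
        m = make_matrix(["BBB", "BBB"], [100, 500, 900], ids=["H1", "H2"])
        with pytest.raises(ValueError, match="both phenotype classes"):
            delimit_interval(m, {"H1": HIGH, "H2": HIGH})

    def test_disjoint_runs_surface_as_error(self):
        # markers 1 and 3 cosegregate, marker 2 does not
        m = make_matrix(["BAB", "AAA"], [100, 500, 900], ids=["H1", "L1"])
        with pytest.raises(ValueError, match="disjoint"):
            delimit_interval(m, {"H1": HIGH, "L1": LOW})

    def test_matches_bruteforce_scan_on_random_matrices(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(400):
            n_mark = int(rng.integers(2, 11))
            n_fam = int(rng.integers(2, 9))
            rows = ["".join(rng.choice(list("AB"), size=n_mark))
                    for _ in range(n_fam)]
            bps = [int(b) for b in
                   sorted(rng.choice(np.arange(100, 9000), n_mark, replace=False))]
            m = make_matrix(rows, bps)
            classes = {f"I{i + 1}": (HIGH if rng.random() < 0.5 else LOW)
                       for i in range(n_fam)}
            if len(set(classes.values())) < 2:
                continue
            _, runs = brute_force_interval(m, classes)
            if len(runs) != 1:
                with pytest.raises(ValueError):
                    delimit_interval(m, classes)
                continue
            iv = delimit_interval(m, classes)
            a, b = runs[0]
            names = m.markers
            assert iv.inner_markers == names[a:b + 1]
            assert iv.left_marker == names[max(a - 1, 0)]
            assert iv.right_marker == names[min(b + 1, len(names) - 1)]
            checked += 1
        assert checked > 50

    def test_added_cosegregating_marker_never_widens_interval(self):
        m = make_matrix(
            ["AABBAA", "AABBAA", "AAAAAA", "AAAAAA"],
            [100, 300, 500, 700, 900, 1100],
            ids=["H1", "H2", "L1", "L2"],
        )
        classes = {"H1": HIGH, "H2": HIGH, "L1": LOW, "L2": LOW}
        before = delimit_interval(m, classes)
        # insert a cosegregating marker at 600 bp, inside the run
        calls = m.calls.copy()
        calls.insert(3, "MX", ["B", "B", "A", "A"])
        mm = m.marker_map.copy()
        mm.loc["MX"] = {"chrom": "Ca4", "cm": 0.5, "bp": 600}
        m2 = MarkerMatrix(calls=calls, marker_map=mm)
        after = delimit_interval(m2, classes)
        assert after.span_bp <= before.span_bp
        # a non-cosegregating marker inside instead splits the run
        calls2 = m.calls.copy()
        calls2.insert(3, "MX", ["B", "B", "B", "A"])
        m3 = MarkerMatrix(calls=calls2, marker_map=mm)
        with pytest.raises(ValueError, match="disjoint"):
            delimit_interval(m3, classes)


class TestDiagnosticMarker:
    def test_perfect_marker_scores_one(self):
        m = make_matrix(["B", "B", "A", "A"], [100],
                        ids=["H1", "H2", "L1", "L2"])
        classes = {"H1": HIGH, "H2": HIGH, "L1": LOW, "L2": LOW}
        assert diagnostic_marker_score("M1", m, classes) == 1.0

    def test_nine_of_ten_families(self):
        ids = [f"F{i}" for i in range(10)]
        rows = ["B"] * 5 + ["A"] * 4 + ["B"]  # last family mismatches
        m = make_matrix(rows, [100], ids=ids)
        classes = {f"F{i}": (HIGH if i < 5 else LOW) for i in range(10)}
        assert diagnostic_marker_score("M1", m, classes) == pytest.approx(0.9)

    def test_missing_calls_excluded_from_denominator(self):
        m = make_matrix(["B", "-", "A"], [100], ids=["H1", "H2", "L1"])
        classes = {"H1": HIGH, "H2": HIGH, "L1": LOW}
        assert diagnostic_marker_score("M1", m, classes) == 1.0

    def test_all_missing_is_an_error(self):
        m = make_matrix(["-", "-"], [100], ids=["H1", "L1"])
        with pytest.raises(ValueError, match="missing"):
            diagnostic_marker_score("M1", m, {"H1": HIGH, "L1": LOW})

    def test_marker_inside_true_interval_is_diagnostic_in_simulation(self):
        from qtlhotspot.simulate import simulate_recombinant_families

        rng = np.random.default_rng(9)
        fam = simulate_recombinant_families(n_families=40, rng=rng)
        assert diagnostic_marker_score(fam.qtl_marker, fam.matrix,
                                       fam.classes) == 1.0
        # terminal markers are separated from the QTL by many breakpoints
        edge = fam.matrix.markers[0]
        assert diagnostic_marker_score(edge, fam.matrix, fam.classes) < 1.0


class TestGenomeRecovery:
    def test_all_recipient_is_full_recovery(self):
        m = make_matrix(["AAAA"], [100, 200, 300, 400])
        assert genome_recovery(m, "I1") == 100.0

    def test_one_donor_marker_in_fifty(self):
        m = make_matrix(["A" * 49 + "B"], list(range(100, 100 + 50 * 10, 10)))
        assert genome_recovery(m, "I1") == pytest.approx(98.0)

    def test_heterozygote_counts_as_half(self):
        m = make_matrix(["A" * 49 + "H"], list(range(100, 100 + 50 * 10, 10)))
        assert genome_recovery(m, "I1") == pytest.approx(99.0)

    def test_target_region_markers_excluded(self):
        m = make_matrix(["AAB"], [100, 200, 300])
        assert genome_recovery(m, "I1", exclude_markers=["M3"]) == 100.0

    def test_all_missing_is_an_error(self):
        m = make_matrix(["--"], [100, 200])
        with pytest.raises(ValueError, match="non-missing"):
            genome_recovery(m, "I1")
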
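"""Unit and oracle tests for conserved-window scanning and in-silico PCR."""

import numpy as np
import pytest

from methylosip.primers import (
    AlignmentMatrix,
    ScanParameters,
    conservation_profile,
    consensus_primer,
    predict_amplicons,
    rank_windows,
    reverse_complement,
    scan_conserved_windows,
)
from methylosip.simulate import simulate_alignment


def naive_scan(alignment, params):
    """Independent brute-force window enumerator (start, length, n_variable)."""
    cols = [alignment.column(j) for j in range(alignment.n_cols)]
    out = []
    for start in range(alignment.n_cols):
        for length in range(params.min_len, params.max_len + 1):
            window = cols[start:start + length]
            if len(window) < length:
                continue
            if any(not col <= set("ACGT") for col in window):
                continue
            n_var = sum(len(col) > 1 for col in window)
            if n_var <= params.max_nonconserved:
                out.append((start, length, n_var))
    return out


def random_alignment(rng):
    n_seqs = int(rng.integers(2, 11))
    n_cols = int(rng.integers(10, 201))
    chars = np.array(list("ACGT"))
    base = chars[rng.integers(0, 4, size=n_cols)]
    matrix = np.tile(base, (n_seqs, 1))
    # perturb a random subset of cells, with occasional gaps/Ns
    mask = rng.uniform(size=(n_seqs, n_cols)) < 0.08
    repl = np.array(list("ACGTACGTN-"))
    matrix[mask] = repl[rng.integers(0, len(repl), size=mask.sum())]
    return AlignmentMatrix(
        [f"s{i}" for i in range(n_seqs)], ["".join(r) for r in matrix]
    )


class TestAlignmentMatrix:
    def test_case_folded_and_validated(self):
        aln = AlignmentMatrix(["a", "b"], ["acgt", "ACGT"])
        assert aln.row(0) == "ACGT"

    def test_rejects_single_sequence(self):
        with pytest.raises(ValueError):
            AlignmentMatrix(["a"], ["ACGT"])

    def test_rejects_ragged_rows(self):
        with pytest.raises(ValueError):
            AlignmentMatrix(["a", "b"], ["ACGT", "ACG"])

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            AlignmentMatrix(["a", "b"], ["ACGU", "ACGT"])


class TestConservationProfile:
    def test_identical_rows_all_conserved(self):
        aln = AlignmentMatrix(["a", "b", "c"], ["ACGT"] * 3)
        assert conservation_profile(aln).all()

    def test_gap_breaks_conservation(self):
        aln = AlignmentMatrix(["a", "b"], ["ACGT", "A-GT"])
        assert list(conservation_profile(aln)) == [True, False, True, True]

    def test_two_bases_not_conserved(self):
        aln = AlignmentMatrix(["a", "b"], ["AA", "AG"])
        assert list(conservation_profile(aln)) == [True, False]

    def test_simulated_alignment_profile(self):
        aln = simulate_alignment(5, 40, {0, 7}, seed=3)
        prof = conservation_profile(aln)
        assert not prof[0] and not prof[7]
        assert prof[[j for j in range(40) if j not in (0, 7)]].all()


class TestScanConservedWindows:
    def test_fully_conserved_30_columns_yields_36(self):
        aln = simulate_alignment(5, 30, set(), seed=1)
        assert len(scan_conserved_windows(aln)) == 36  # 13 + 12 + 11

    def test_spread_variable_columns_yield_none(self):
        """Variable columns every 4 positions: any 18-20 nt window covers >= 4."""
        aln = simulate_alignment(6, 20, {0, 4, 8, 12, 16}, seed=2)
        assert scan_conserved_windows(aln) == []

    def test_short_alignment_warns_and_returns_empty(self):
        aln = AlignmentMatrix(["a", "b"], ["ACGT", "ACGT"])
        with pytest.warns(UserWarning):
            assert scan_conserved_windows(aln) == []

    def test_gap_column_disqualifies_window(self):
        rows = ["A" * 30, "A" * 14 + "-" + "A" * 15]
        aln = AlignmentMatrix(["a", "b"], rows)
        for w in scan_conserved_windows(aln):
            assert not (w.start <= 14 < w.start + w.length)

    def test_oracle_equivalence_on_random_alignments(self):
        rng = np.random.default_rng(1234)
        params = ScanParameters()
        for _ in range(30):
            aln = random_alignment(rng)
            got = [(w.start, w.length, w.nonconserved_count)
                   for w in scan_conserved_windows(aln, params)]
            assert sorted(got) == sorted(naive_scan(aln, params))

    def test_monotone_in_budget_and_min_len(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            aln = random_alignment(rng)
            keys = lambda ws: {(w.start, w.length) for w in ws}
            loose = keys(scan_conserved_windows(aln, ScanParameters(max_nonconserved=4)))
            tight = keys(scan_conserved_windows(aln, ScanParameters(max_nonconserved=2)))
            assert tight <= loose
            shorter = keys(scan_conserved_windows(aln, ScanParameters(min_len=16)))
            default = keys(scan_conserved_windows(aln, ScanParameters()))
            assert default <= shorter

    def test_consensus_round_trip(self):
        """Every row restricted to a reported window matches its consensus."""
        from methylosip.primers import CODE_TO_SET

        rng = np.random.default_rng(7)
        for _ in range(10):
            aln = random_alignment(rng)
            for w in scan_conserved_windows(aln)[:20]:
                for i in range(aln.n_seqs):
                    segment = aln.row(i)[w.start:w.start + w.length]
                    assert all(
                        b in CODE_TO_SET[c] for b, c in zip(segment, w.consensus)
                    )

    def test_ranking_prefers_conserved_low_degeneracy(self):
        aln = simulate_alignment(5, 60, {25}, seed=5)
        ranked = rank_windows(scan_conserved_windows(aln))
        assert ranked[0].nonconserved_count == 0
        assert ranked[0].degeneracy == 1


class TestConsensusPrimer:
    def test_single_base_column(self):
        aln = AlignmentMatrix(["a", "b"], ["A" * 18, "A" * 18])
        consensus, degeneracy = consensus_primer(aln, 0, 18)
        assert consensus == "A" * 18 and degeneracy == 1

    def test_two_base_column_is_R(self):
        aln = AlignmentMatrix(["a", "b"], ["AAA", "AGA"])
        consensus, degeneracy = consensus_primer(aln, 0, 3)
        assert consensus == "ARA" and degeneracy == 2

    def test_degeneracy_product(self):
        aln = AlignmentMatrix(["a", "b", "c", "d"],
                              ["ACA", "GTC", "ACG", "GTT"])
        consensus, degeneracy = consensus_primer(aln, 0, 3)
        assert consensus == "RYN" and degeneracy == 2 * 2 * 4

    def test_gap_in_window_rejected(self):
        aln = AlignmentMatrix(["a", "b"], ["A-A", "AAA"])
        with pytest.raises(ValueError, match="gap"):
            consensus_primer(aln, 0, 3)


class TestPredictAmplicons:
    @staticmethod
    def _template(rng, length=700):
        return "".join(rng.choice(list("ACGT"), size=length))

    def test_exact_product_on_constructed_template(self):
        """Primer sites at 100 and ending at 580 give a ~500 bp product."""
        rng = np.random.default_rng(11)
        tpl = self._template(rng)
        fwd = tpl[100:120]
        rev = reverse_complement(tpl[560:580])
        preds = predict_amplicons(fwd, rev, {"pos": tpl})
        assert len(preds) == 1
        p = preds[0]
        assert p.product_length == 480
        assert p.total_mismatches == 0
        assert (p.forward_position, p.reverse_position) == (100, 560)

    def test_no_reverse_site_means_no_product(self):
        rng = np.random.default_rng(12)
        tpl = self._template(rng)
        fwd = tpl[100:120]
        rev = reverse_complement(self._template(np.random.default_rng(13), 20))
        assert predict_amplicons(fwd, rev, {"neg": tpl}) == []

    def test_degenerate_code_matches_covered_base(self):
        """An R in the primer matches template G without counting a mismatch."""
        rng = np.random.default_rng(14)
        tpl = self._template(rng)
        site = tpl[100:120]
        assert "G" in site[:10]
        i = site.index("G")
        fwd = site[:i] + "R" + site[i + 1:]
        rev = reverse_complement(tpl[560:580])
        preds = predict_amplicons(fwd, rev, {"pos": tpl})
        assert len(preds) == 1 and preds[0].total_mismatches == 0

    def test_three_prime_mismatch_always_fatal(self):
        rng = np.random.default_rng(15)
        tpl = self._template(rng)
        site = tpl[100:120]
        last = site[-1]
        flipped = {"A": "C", "C": "A", "G": "T", "T": "G"}[last]
        fwd = site[:-1] + flipped
        rev = reverse_complement(tpl[560:580])
        assert predict_amplicons(fwd, rev, {"pos": tpl}, max_mismatches=5) == []

    def test_internal_mismatch_allowed_within_budget(self):
        rng = np.random.default_rng(16)
        tpl = self._template(rng)
        site = tpl[100:120]
        flipped = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[5]]
        fwd = site[:5] + flipped + site[6:]
        rev = reverse_complement(tpl[560:580])
        assert predict_amplicons(fwd, rev, {"pos": tpl}, max_mismatches=0) == []
        preds = predict_amplicons(fwd, rev, {"pos": tpl}, max_mismatches=1)
        assert len(preds) == 1 and preds[0].total_mismatches == 1

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            predict_amplicons("ACGX", "ACGT", {"t": "ACGT" * 100})

    def test_specificity_screen_design(self):
        """Primers from conserved windows of an alignment amplify templates
        carrying the windows and not templates with the windows disrupted."""
        rng = np.random.default_rng(21)
        aln = simulate_alignment(5, 120, {30, 75}, seed=8)
        windows = scan_conserved_windows(aln)
        fwd_w = next(w for w in windows if w.start + w.length <= 25)
        rev_w = next(w for w in windows if w.start >= 90)
        fwd = fwd_w.consensus
        rev = reverse_complement(rev_w.consensus)
        flank5 = "".join(rng.choice(list("ACGT"), 200))
        flank3 = "".join(rng.choice(list("ACGT"), 200))
        positive = flank5 + aln.row(0) + flank3
        disrupted = (flank5 + "".join(rng.choice(list("ACGT"), aln.n_cols)) + flank3)
        preds = predict_amplicons(fwd, rev, {"pos": positive, "neg": disrupted},
                                  product_range=(50, 600))
        assert {p.template_id for p in preds} == {"pos"}
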
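"""PWM scanning, the count matrix and its symmetry/monotonicity contracts."""

import numpy as np
import pandas as pd
import pytest

from promotif.io import PromoterSet
from promotif.matrices import BASES, pfm_to_pwm, reverse_complement, score_window
from promotif.scan import build_count_matrix, presence_vector, scan_sequence
from promotif.synthetic import generate_promoters, plant_sites, random_panel, random_pfm


def naive_count(pwm, sequence, threshold, strands="both"):
    """Independent quadratic re-scan: substring scoring per offset."""
    L = pwm.length
    span = pwm.s_max - pwm.s_min
    count = 0
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        if "N" in window:
            continue
        rel = (score_window(pwm, window) - pwm.s_min) / span
        if rel > threshold:
            count += 1
        if strands == "both":
            rel_rc = (score_window(pwm, reverse_complement(window)) - pwm.s_min) / span
            if rel_rc > threshold:
                count += 1
    return count


class TestScanSequence:
    def test_sequence_shorter_than_motif_is_empty(self, strong_pfm):
        pwm = pfm_to_pwm(strong_pfm)
        assert scan_sequence(pwm, "g", "ACGT") == []

    def test_spliced_consensus_found_once(self, strong_pfm):
        """Consensus planted at offset 10 in an all-C background: one + hit."""
        pwm = pfm_to_pwm(strong_pfm)
        seq = "C" * 10 + strong_pfm.consensus + "C" * (60 - 10 - strong_pfm.length)
        hits = scan_sequence(pwm, "g1", seq, threshold=0.95)
        assert len(hits) == 1
        (hit,) = hits
        assert (hit.start, hit.strand) == (10, "+")
        assert hit.relative_score == pytest.approx(1.0, abs=1e-12)
        assert hit.end - hit.start == strong_pfm.length

    def test_reverse_complement_mirror(self, small_pwms):
        """RC of the whole sequence: same relative scores, strands swapped,
        start s mapped to |seq| - L - s."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(BASES), size=300))
        for pwm in small_pwms:
            fwd = scan_sequence(pwm, "g", seq, threshold=0.8)
            rev = scan_sequence(pwm, "g", reverse_complement(seq), threshold=0.8)
            a = sorted(
                (len(seq) - pwm.length - h.start, {"+": "-", "-": "+"}[h.strand],
                 round(h.relative_score, 9))
                for h in fwd
            )
            b = sorted((h.start, h.strand, round(h.relative_score, 9)) for h in rev)
            assert a == b

    def test_hits_ordered_start_then_strand(self, small_pwms):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list(BASES), size=500))
        for pwm in small_pwms:
            hits = scan_sequence(pwm, "g", seq, threshold=0.5)
            keys = [(h.start, 0 if h.strand == "+" else 1) for h in hits]
            assert keys == sorted(keys)

    def test_windows_containing_n_are_skipped(self, strong_pfm):
        pwm = pfm_to_pwm(strong_pfm)
        core = strong_pfm.consensus
        seq = "C" * 5 + core[:4] + "N" + core[5:] + "C" * 5
        assert scan_sequence(pwm, "g", seq, threshold=0.0) != []  # sanity: scannable
        assert all(
            not (h.start <= 9 < h.end) for h in scan_sequence(pwm, "g", seq, 0.0)
        )

    def test_raw_and_relative_consistent(self, small_pwms):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(BASES), size=200))
        for pwm in small_pwms:
            for h in scan_sequence(pwm, "g", seq, threshold=0.6):
                rel = (h.raw_score - pwm.s_min) / (pwm.s_max - pwm.s_min)
                assert h.relative_score == pytest.approx(rel, abs=1e-9)


class TestCountMatrix:
    def test_zero_promoters(self, small_pwms):
        counts = build_count_matrix(small_pwms, PromoterSet([]))
        assert counts.shape == (0, len(small_pwms))

    def test_threshold_one_with_strict_comparison_empties_counts(self, small_pwms):
        promoters = generate_promoters(5, 200, seed=1)
        counts = build_count_matrix(small_pwms, promoters, threshold=1.0)
        assert (counts.to_numpy() == 0).all()

    def test_three_planted_consensus_sites_count_exactly(self):
        pfm = random_pfm(seed=21, motif_id="M1", length=10)
        promoters = generate_promoters(4, 300, seed=2)
        # three consensus sites in the first gene only, fixed placements
        gene = promoters.gene_ids[0]
        for s in range(100):  # first deterministic seed whose Poisson draw is 3
            planted, truth = plant_sites(
                promoters.subset([gene]), pfm, rate=3.0, seed=s, consensus_only=True
            )
            if len(truth) == 3:
                break
        else:
            pytest.fail("no seed below 100 planted exactly 3 sites")
        merged = promoters.with_sequences({gene: planted[gene]})
        counts = build_count_matrix([pfm_to_pwm(pfm)], merged, threshold=0.95)
        assert counts.loc[gene, "M1"] == 3
        assert counts.drop(index=gene).to_numpy().sum() == 0

    def test_monotone_nonincreasing_in_threshold(self, small_pwms):
        promoters = generate_promoters(10, 300, seed=8)
        prev = None
        for thr in (0.7, 0.8, 0.9, 0.95, 1.0):
            counts = build_count_matrix(small_pwms, promoters, threshold=thr)
            if prev is not None:
                assert (counts.to_numpy() <= prev.to_numpy()).all()
            prev = counts

    def test_strand_symmetry_of_counts(self, small_pwms):
        promoters = generate_promoters(8, 250, seed=12)
        a = build_count_matrix(small_pwms, promoters, threshold=0.85)
        b = build_count_matrix(small_pwms, promoters.reverse_complement(), threshold=0.85)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_forward_only_mode_counts_at_most_both_strands(self, small_pwms):
        promoters = generate_promoters(6, 200, seed=13)
        both = build_count_matrix(small_pwms, promoters, threshold=0.8, strands="both")
        fwd = build_count_matrix(small_pwms, promoters, threshold=0.8, strands="forward")
        assert (fwd.to_numpy() <= both.to_numpy()).all()

    def test_matches_naive_quadratic_oracle(self):
        """Short motifs (L <= 4) on short sequences: exact agreement with an
        independent per-substring re-scan, N runs included."""
        rng = np.random.default_rng(17)
        pfms = [random_pfm(seed=rng, motif_id=f"M{i}", length=int(rng.integers(3, 5)))
                for i in range(3)]
        pwms = [pfm_to_pwm(p) for p in pfms]
        records = []
        for i in range(6):
            seq = "".join(rng.choice(list(BASES + "N"), size=int(rng.integers(20, 200)),
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            records.append((f"g{i}", seq))
        promoters = PromoterSet(records)
        for strands in ("both", "forward"):
            for thr in (0.7, 0.9):
                counts = build_count_matrix(pwms, promoters, thr, strands)
                for g, seq in records:
                    for pwm in pwms:
                        assert counts.loc[g, pwm.motif_id] == naive_count(
                            pwm, seq, thr, strands
                        ), (g, pwm.motif_id, thr, strands)


class TestPresence:
    def test_presence_from_counts(self):
        counts = pd.DataFrame(
            {"m1": [0, 2, 1], "m2": [0, 0, 0]},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
        assert presence_vector(counts, "m1").tolist() == [False, True, True]
        assert presence_vector(counts, "m2").tolist() == [False, False, False]
        assert presence_vector(counts, "m1").sum() == (counts["m1"] > 0).sum()

    def test_unknown_motif_rejected(self):
        counts = pd.DataFrame({"m1": [1]}, index=["g1"])
        with pytest.raises(ValueError, match="unknown motif"):
            presence_vector(counts, "nope")
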
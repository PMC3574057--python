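"""PWM log-odds scoring against brute-force and Biopython oracles."""

import numpy as np
import pytest

from peakspec.motifs import (
    BASES,
    PWM,
    Background,
    genome_background,
    information_content,
    logodds_matrix,
    max_pwm_score,
    rescore_with_allele,
    reverse_complement,
    select_pwm,
)

UNIFORM = Background(np.full(4, 0.25))


def random_pwm(rng, width=6, name="m"):
    return PWM(name, rng.integers(0, 20, size=(4, width)).astype(float))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_best(matrix, seq):
    """Enumerate every offset on both strands; smaller offset, '+' first."""
    w = matrix.shape[1]
    idx = {b: i for i, b in enumerate(BASES)}
    best = None
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for off in range(len(seq) - w + 1):
            window = s[off : off + w]
            if any(b not in idx for b in window):
                continue
            score = sum(matrix[idx[b], j] for j, b in enumerate(window))
            fwd_off = off if strand == "+" else len(seq) - off - w
            key = (-score, fwd_off, strand)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return (-best[0], best[1], best[2])


class TestGenomeBackground:
    def test_uniform(self):
        bg = genome_background(["ACGT"])
        assert np.allclose(bg.freq, 0.25)

    def test_n_ignored_and_floor_applied(self):
        bg = genome_background(["AANA"])
        assert bg.freq[0] > 0.99
        assert np.all(bg.freq > 0)
        assert bg.freq.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_bases_rejected(self):
        with pytest.raises(ValueError):
            genome_background(["NNN"])

    def test_matches_counting(self, rng):
        seq = random_seq(rng, 2000)
        bg = genome_background([seq])
        counts = np.array([seq.count(b) for b in BASES], dtype=float)
        assert np.allclose(bg.freq, counts / counts.sum(), atol=1e-6)


class TestLogoddsMatrix:
    def test_uniform_column_is_zero(self):
        pwm = PWM("u", np.full((4, 3), 5.0))
        m = logodds_matrix(pwm, UNIFORM)
        assert np.allclose(m, 0.0)

    def test_closed_form_column(self):
        pwm = PWM("c", np.array([[9.0], [0.0], [0.0], [0.0]]))
        m = logodds_matrix(pwm, UNIFORM)
        assert m[0, 0] == pytest.approx(np.log2((10 / 13) / 0.25), abs=1e-12)
        assert m[1, 0] == pytest.approx(np.log2((1 / 13) / 0.25), abs=1e-12)

    def test_finite_for_zero_counts(self, rng):
        pwm = PWM("z", np.zeros((4, 5)))
        assert np.all(np.isfinite(logodds_matrix(pwm, UNIFORM)))

    def test_flattening_shrinks_magnitudes(self, rng):
        pwm = random_pwm(rng)
        flat = PWM("f", pwm.counts + 50.0)
        m1 = logodds_matrix(pwm, UNIFORM)
        m2 = logodds_matrix(flat, UNIFORM)
        assert np.abs(m2).sum() < np.abs(m1).sum()


class TestMaxPwmScore:
    def test_consensus_hit_at_origin(self, rng):
        pwm = random_pwm(rng, width=8)
        m = logodds_matrix(pwm, UNIFORM)
        seq = pwm.consensus() + "T" * 4  # consensus planted at offset 0
        hit = max_pwm_score(m, seq)
        expected = m.max(axis=0).sum()
        if hit.score == pytest.approx(expected):
            assert hit.offset == 0 or hit.strand in "+-"
        assert hit.score >= m[
            [BASES.index(b) for b in pwm.consensus()], range(pwm.width)
        ].sum() - 1e-9

    def test_palindrome_tiebreak_prefers_plus(self):
        # a matrix symmetric under reverse complement scores both strands equally
        counts = np.array(
            [[8, 0, 0, 8], [0, 8, 8, 0], [0, 8, 8, 0], [8, 0, 0, 8]], dtype=float
        )
        m = logodds_matrix(PWM("pal", counts), UNIFORM)
        assert np.allclose(m, m[::-1, ::-1])
        hit = max_pwm_score(m, "ACGTACGT")
        assert hit.strand == "+"

    def test_too_short_sequence_rejected(self, rng):
        m = logodds_matrix(random_pwm(rng, width=6), UNIFORM)
        with pytest.raises(ValueError):
            max_pwm_score(m, "ACG")

    def test_all_windows_with_n_returns_none(self, rng):
        m = logodds_matrix(random_pwm(rng, width=4), UNIFORM)
        assert max_pwm_score(m, "ACNGT") is None

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, width=int(rng.integers(4, 10)))
        m = logodds_matrix(pwm, UNIFORM)
        seq = list(random_seq(rng, int(rng.integers(pwm.width, 60))))
        for i in rng.integers(0, len(seq), size=len(seq) // 10):  # sprinkle Ns
            seq[i] = "N"
        seq = "".join(seq)
        hit = max_pwm_score(m, seq)
        oracle = brute_best(m, seq)
        if oracle is None:
            assert hit is None
        else:
            assert hit.score == pytest.approx(oracle[0], abs=1e-9)
            assert (hit.offset, hit.strand) == (oracle[1], oracle[2])

    @pytest.mark.parametrize("seed", range(10))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        m = logodds_matrix(random_pwm(rng, width=6), UNIFORM)
        seq = random_seq(rng, 50)
        h1 = max_pwm_score(m, seq)
        h2 = max_pwm_score(m, reverse_complement(seq))
        assert h1.score == pytest.approx(h2.score, abs=1e-9)

    def test_agrees_with_biopython_pssm(self, rng):
        """Independent oracle: Bio.motifs PSSM with the same pseudocounts."""
        from Bio import motifs
        from Bio.motifs.matrix import FrequencyPositionMatrix
        from Bio.Seq import Seq

        pwm = random_pwm(rng, width=7, name="bp")
        counts = {b: list(pwm.counts[i]) for i, b in enumerate(BASES)}
        motif = motifs.Motif(counts=FrequencyPositionMatrix("ACGT", counts))
        motif.pseudocounts = 1.0
        motif.background = {b: 0.25 for b in "ACGT"}
        pssm = motif.pssm
        m = logodds_matrix(pwm, UNIFORM)
        for _ in range(20):
            seq = Seq(random_seq(rng, 40))
            fwd = pssm.calculate(seq)
            rev = pssm.reverse_complement().calculate(seq)
            expected = max(float(np.max(fwd)), float(np.max(rev)))
            assert max_pwm_score(m, str(seq)).score == pytest.approx(expected, abs=1e-4)


class TestRescoreWithAllele:
    def test_noop_substitution(self, rng):
        m = logodds_matrix(random_pwm(rng, width=5), UNIFORM)
        seq = random_seq(rng, 40)
        hit = max_pwm_score(m, seq)
        assert rescore_with_allele(m, seq, 10, seq[10]) == hit

    def test_disrupting_consensus_lowers_best_window_score(self, rng):
        pwm = PWM("d", np.array([[18, 1, 18], [1, 18, 1], [1, 1, 1], [1, 1, 1]], dtype=float))
        m = logodds_matrix(pwm, UNIFORM)
        seq = "TTTT" + "ACA" + "TTTT"
        base = max_pwm_score(m, seq)
        worst = BASES[int(np.argmin(m[:, 1]))]
        edited = rescore_with_allele(m, seq, 5, worst)
        assert edited.score < base.score

    def test_substitution_outside_best_window(self, rng):
        m = logodds_matrix(random_pwm(rng, width=4), UNIFORM)
        seq = random_seq(rng, 30)
        hit = max_pwm_score(m, seq)
        pos = (hit.offset + 10) % len(seq)
        if hit.offset <= pos < hit.offset + 4:
            pos = (hit.offset + 20) % len(seq)
        if not (hit.offset <= pos < hit.offset + 4):
            edited = rescore_with_allele(m, seq, pos, "A")
            assert edited.score >= hit.score - 1e-9 or edited.score == pytest.approx(
                brute_best(m, seq[:pos] + "A" + seq[pos + 1 :])[0], abs=1e-9
            )

    def test_out_of_range_rejected(self, rng):
        m = logodds_matrix(random_pwm(rng, width=4), UNIFORM)
        with pytest.raises(ValueError):
            rescore_with_allele(m, "ACGTACGT", 99, "A")


class TestPwmSelection:
    def test_higher_information_matrix_wins(self):
        sharp = PWM("sharp", np.array([[30, 30], [0, 0], [0, 0], [0, 0]], dtype=float))
        flat = PWM("flat", np.full((4, 2), 7.5))
        assert select_pwm([flat, sharp]).name == "sharp"
        assert information_content(sharp) > information_content(flat)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_pwm([])
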
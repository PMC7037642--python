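"""Three-step affinity model: term scores, best-window minimum, calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tatashift.affinity import (
    AffinityModelParams,
    DINUCLEOTIDES,
    bending_term,
    calibrate_model,
    estimate_affinity,
    pwm_consensus,
    recognition_term,
    sliding_term,
    window_lnkd,
)

SEQS = st.text(alphabet="ACGT", min_size=15, max_size=200)


def naive_estimate(seq, params):
    """Independent oracle: explicit loop over every window."""
    W = params.window_len
    best, best_start = None, None
    for s in range(len(seq) - W + 1):
        v = window_lnkd(seq[s : s + W], params)
        if best is None or v < best - 1e-15:
            best, best_start = v, s
    return best, best_start


def test_sliding_term_constant_table():
    table = {d: 2.5 for d in DINUCLEOTIDES}
    assert sliding_term("ACGTACGT", table) == pytest.approx(2.5)


def test_sliding_term_hand_sum():
    table = {d: 0.0 for d in DINUCLEOTIDES}
    table["AT"], table["TA"] = -1.0, -3.0
    assert sliding_term("ATA", table) == pytest.approx(-2.0)


def test_sliding_term_rejects_short_or_invalid():
    table = {d: 0.0 for d in DINUCLEOTIDES}
    with pytest.raises(ValueError):
        sliding_term("A", table)
    with pytest.raises(ValueError):
        sliding_term("ANA", table)


def test_recognition_term_zero_matrix_and_consensus_max():
    pwm = np.zeros((4, 4))
    assert recognition_term("ACGT", pwm) == 0.0
    rng = np.random.default_rng(1)
    pwm = rng.normal(size=(3, 4))
    consensus = pwm_consensus(pwm)
    best = max(
        recognition_term("".join(w), pwm)
        for w in itertools.product("ACGT", repeat=3)
    )
    assert recognition_term(consensus, pwm) == pytest.approx(best)


def test_recognition_term_length_mismatch():
    with pytest.raises(ValueError):
        recognition_term("ACGTA", np.zeros((4, 4)))


def test_bending_term_matches_loop_oracle(toy_params):
    w = "ACGT"
    expected = np.mean([toy_params.bend_table[w[i : i + 2]] for i in range(3)])
    assert bending_term(w, toy_params.bend_table) == pytest.approx(expected)


def test_window_lnkd_degenerate_coefficients(toy_params):
    from dataclasses import replace

    only_b0 = replace(toy_params, coeffs=(4.2, 0, 0, 0))
    assert window_lnkd("ACG", only_b0) == pytest.approx(4.2)
    only_slide = replace(toy_params, coeffs=(0, 1, 0, 0))
    assert window_lnkd("ACG", only_slide) == pytest.approx(
        sliding_term("ACG", toy_params.slide_table)
    )


def test_window_lnkd_term_by_term(toy_params):
    w = "TAG"
    b0, b1, b2, b3 = toy_params.coeffs
    expected = (
        b0
        + b1 * sliding_term(w, toy_params.slide_table)
        + b2 * recognition_term(w, toy_params.pwm)
        + b3 * bending_term(w, toy_params.bend_table)
    )
    assert window_lnkd(w, toy_params) == pytest.approx(expected)


def test_estimate_single_window_equals_window_lnkd(toy_params):
    seq = "TAT"
    est = estimate_affinity(seq, toy_params)
    assert est.ln_kd == pytest.approx(window_lnkd(seq, toy_params))
    assert est.best_window_start == 0
    assert est.se == toy_params.residual_se


def test_estimate_shorter_than_window_errors(toy_params):
    with pytest.raises(ValueError):
        estimate_affinity("AT", toy_params)


def test_planting_consensus_lowers_lnkd(default_params):
    rng = np.random.default_rng(3)
    background = "".join(rng.choice(list("ACGT"), size=70))
    consensus = pwm_consensus(default_params.pwm)
    planted = background[:20] + consensus + background[20 + len(consensus):]
    assert (
        estimate_affinity(planted, default_params).ln_kd
        <= estimate_affinity(background, default_params).ln_kd + 1e-12
    )


@settings(max_examples=40, deadline=None)
@given(seq=SEQS)
def test_estimate_matches_naive_all_windows_minimum(seq, default_params):
    est = estimate_affinity(seq, default_params)
    best, best_start = naive_estimate(seq, default_params)
    assert est.ln_kd == pytest.approx(best, abs=1e-9)
    assert est.best_window_start == best_start


def test_leftmost_tie_break(toy_params):
    # two identical windows -> leftmost argmin reported
    from dataclasses import replace

    flat = replace(
        toy_params,
        slide_table={d: 0.0 for d in DINUCLEOTIDES},
        bend_table={d: 0.0 for d in DINUCLEOTIDES},
        pwm=np.zeros((3, 4)),
    )
    est = estimate_affinity("ACGTACGT", flat)
    assert est.best_window_start == 0


def test_translation_invariance(default_params):
    """Prepending bases that do not create a better window keeps ln_kd."""
    seq = "TTGCGGGCTATAAAAGGGGGTGGG"
    base = estimate_affinity(seq, default_params)
    # prepend G/C-rich junk, weakest possible recognition context
    extended = "GCGCGC" + seq
    ext = estimate_affinity(extended, default_params)
    assert ext.ln_kd <= base.ln_kd + 1e-12
    if ext.best_window_start == base.best_window_start + 6:
        assert ext.ln_kd == pytest.approx(base.ln_kd)


def _simulate_pairs(params, n, noise_sd, rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=38)) for _ in range(n)]
    kds = [
        float(
            np.exp(
                estimate_affinity(s, params).ln_kd + rng.normal(0.0, noise_sd)
            )
        )
        for s in seqs
    ]
    return list(zip(seqs, kds))


def test_calibration_recovers_planted_coefficients(default_params):
    rng = np.random.default_rng(11)
    pairs = _simulate_pairs(default_params, 40, 0.0, rng)
    fitted = calibrate_model(pairs, default_params)
    assert np.allclose(fitted.coeffs, default_params.coeffs, atol=1e-6)
    assert fitted.residual_se <= 1e-5


def test_calibration_constant_response(default_params):
    rng = np.random.default_rng(12)
    seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(12)]
    pairs = [(s, 10.0) for s in seqs]
    fitted = calibrate_model(pairs, default_params)
    b0, b1, b2, b3 = fitted.coeffs
    preds = [estimate_affinity(s, fitted).ln_kd for s in seqs]
    assert np.allclose(preds, np.log(10.0), atol=1e-8)


def test_calibration_needs_at_least_8_pairs(default_params):
    with pytest.raises(ValueError, match="at least 8"):
        calibrate_model([("ACGTACGTACGTACGTA", 1.0)] * 3, default_params)


def test_calibration_rmse_shrinks_with_n(default_params):
    rng = np.random.default_rng(13)
    sigma = 0.4
    rmses = {}
    for n in (20, 320):
        errs = []
        for rep in range(3):
            pairs = _simulate_pairs(default_params, n, sigma, rng)
            fitted = calibrate_model(pairs, default_params)
            errs.append(
                np.sqrt(
                    np.mean(
                        (np.array(fitted.coeffs) - np.array(default_params.coeffs))
                        ** 2
                    )
                )
            )
        rmses[n] = np.mean(errs)
    assert rmses[320] < rmses[20]


def test_params_validation():
    good = {d: 0.0 for d in DINUCLEOTIDES}
    with pytest.raises(ValueError, match="lacks"):
        AffinityModelParams({"AA": 0.0}, np.zeros((15, 4)), good, (0, 0, 0, 0), 0.3)
    with pytest.raises(ValueError, match="residual_se"):
        AffinityModelParams(good, np.zeros((15, 4)), good, (0, 0, 0, 0), 0.0)
    with pytest.raises(ValueError, match="width"):
        AffinityModelParams(good, np.zeros((10, 4)), good, (0, 0, 0, 0), 0.3, window_len=15)
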
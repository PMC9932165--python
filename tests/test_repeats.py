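"""Periodicity, repeat-region inference, motif counting, architecture calls."""

import re

import numpy as np
import pytest
from hypothesis import given, assume, settings, strategies as st

from silkatlas._alphabet import AlphabetError
from silkatlas.repeats import (InsufficientLengthError, EmptyInputError,
                               call_architecture, composition, count_motifs,
                               find_repeat_region, periodicity)
from silkatlas.align import LocalAlignment
from silkatlas.grammar import DEFAULT_GRAMMARS
from silkatlas.synthetic import (library_by_type, load_terminal_library,
                                 make_decoy, make_spidroin)


def motif_oracle(seq):
    """Independent hand-scan oracle: maximal non-overlapping left-to-right
    matches per class, written without regular expressions."""
    out = {"polyA_runs": 0, "polyA_residues": 0, "ga_arrays": 0,
           "ggx": 0, "gpgxx": 0, "xqq": 0}
    spans = []
    i = 0  # (A)n: maximal runs of >= 4 alanines
    while i < len(seq):
        if seq[i] == "A":
            j = i
            while j < len(seq) and seq[j] == "A":
                j += 1
            if j - i >= 4:
                out["polyA_runs"] += 1
                out["polyA_residues"] += j - i
                spans.append((i, j))
            i = j
        else:
            i += 1
    i = 0  # (GA)n: >= 2 consecutive GA dyads
    while i + 1 < len(seq):
        k = 0
        while seq[i + 2 * k:i + 2 * k + 2] == "GA":
            k += 1
        if k >= 2:
            out["ga_arrays"] += 1
            spans.append((i, i + 2 * k))
            i += 2 * k
        else:
            i += 1
    for name, width, check in (
            ("ggx", 3, lambda w: w[0] == "G" and w[1] == "G"),
            ("gpgxx", 5, lambda w: w[:3] == "GPG"),
            ("xqq", 3, lambda w: w[1] == "Q" and w[2] == "Q")):
        i = 0
        while i + width <= len(seq):
            w = seq[i:i + width]
            if check(w):
                out[name] += 1
                spans.append((i, i + width))
                i += width
            else:
                i += 1
    covered = set()
    for s, e in spans:
        covered.update(range(s, e))
    out["coverage"] = len(covered) / len(seq) if seq else 0.0
    return out


def assert_matches_oracle(seq):
    got = count_motifs(seq).as_dict()
    want = motif_oracle(seq)
    assert got == pytest.approx(want)


# ---------------------------------------------------------------- periodicity

def test_perfect_tandem_array_has_unit_match_one():
    unit = "GPGGYGPGQQLAGSSA"[:10]
    prof = periodicity(unit * 8)
    assert prof.match_fraction[prof.lags == 10][0] == 1.0
    assert prof.best_lag() == 10


def test_period_multiples_dominate_non_multiples():
    rng = np.random.default_rng(2)
    unit = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 12))
    prof = periodicity(unit * 10)
    lags = prof.lags
    m = prof.match_fraction
    multiples = m[(lags % 12 == 0)]
    non = m[(lags % 12 != 0)]
    assert multiples.min() >= non.max()


def test_random_sequence_has_low_periodicity():
    rng = np.random.default_rng(0)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))
        prof = periodicity(seq)
        assert prof.match_fraction.max() < 0.25


def test_too_short_sequence_rejected():
    with pytest.raises(InsufficientLengthError):
        periodicity("AAAA", min_lag=5)


# ---------------------------------------------------------------- repeat region

def test_repeat_region_recovers_truth_span():
    lib = library_by_type(load_terminal_library())
    g = DEFAULT_GRAMMARS["MaSp1"]
    from dataclasses import replace
    g30 = replace(g, unit_len=(30, 30))
    prot, truth = make_spidroin("MaSp1", 20, lib, substitution_rate=0.0,
                                rng=np.random.default_rng(4), grammar=g30)
    region = find_repeat_region(prot)
    assert region is not None
    assert region.unit_length == 30
    assert abs(region.copy_number - 20) <= 1
    assert abs(region.start - truth.repeat_start) <= 5
    assert abs(region.end - truth.repeat_end) <= 5


def test_globular_decoy_has_no_repeat_region():
    rng = np.random.default_rng(9)
    for _ in range(5):
        seq = make_decoy(300, 0.0, rng)
        assert find_repeat_region(seq) is None


def test_single_unit_is_not_an_array():
    lib = library_by_type(load_terminal_library())
    prot, truth = make_spidroin("MaSp1", 1, lib, substitution_rate=0.0,
                                rng=np.random.default_rng(1))
    region = find_repeat_region(prot)
    if region is not None:  # any detected span must not be the single unit
        assert region.end - region.start >= 2 * region.unit_length


def test_copy_number_consistent_with_span():
    unit = "GGAGQGGYGA"
    region = find_repeat_region(unit * 12)
    assert region is not None
    assert abs(region.copy_number - (region.end - region.start)
               / region.unit_length) <= 0.5


# ---------------------------------------------------------------- motifs

def test_empty_sequence_counts_zero():
    c = count_motifs("")
    assert c.as_dict() == {"ga_arrays": 0, "polyA_runs": 0, "polyA_residues": 0,
                           "ggx": 0, "gpgxx": 0, "xqq": 0, "coverage": 0.0}


def test_worked_motif_examples():
    c = count_motifs("GPGGYGPGQQ")
    assert (c.gpgxx, c.ggx, c.xqq, c.ga_arrays, c.polyA_runs) == (2, 1, 1, 0, 0)
    c = count_motifs("AAAAGAGAGA")
    assert (c.polyA_runs, c.polyA_residues, c.ga_arrays, c.ggx) == (1, 4, 1, 0)


def test_motifs_match_oracle_on_random_strings():
    rng = np.random.default_rng(12)
    alphabet = list("GAPQSYA")  # silk-biased, motif-dense
    for _ in range(200):
        n = int(rng.integers(0, 120))
        assert_matches_oracle("".join(rng.choice(alphabet, n)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="GAPQS", max_size=60), st.text(alphabet="GAPQS", max_size=60))
def test_counts_additive_across_neutral_junction(a, b):
    """Counting is additive when no match straddles the W-spacer junction."""
    joined = a + "W" * 6 + b
    spans = [(m.start(), m.end()) for p in
             (re.compile(r"A{4,}"), re.compile(r"(?:GA){2,}"),
              re.compile(r"GG."), re.compile(r"GPG.."), re.compile(r".QQ"))
             for m in p.finditer(joined)]
    junction = set(range(len(a), len(a) + 6))
    assume(all(not (set(range(s, e)) & junction) for s, e in spans))
    total = count_motifs(joined)
    left, right = count_motifs(a), count_motifs(b)
    s = left + right
    assert (total.ga_arrays, total.polyA_runs, total.polyA_residues,
            total.ggx, total.gpgxx, total.xqq) == \
        (s.ga_arrays, s.polyA_runs, s.polyA_residues, s.ggx, s.gpgxx, s.xqq)


def test_invalid_residue_rejected():
    with pytest.raises(AlphabetError):
        count_motifs("GPG1X")


# ---------------------------------------------------------------- composition

def test_composition_simple_cases():
    assert composition("G")["G"] == 1.0
    c = composition("GAGA")
    assert c["G"] == 0.5 and c["A"] == 0.5
    assert sum(c.values()) == pytest.approx(1.0, abs=1e-9)


def test_composition_empty_input_rejected():
    with pytest.raises(EmptyInputError):
        composition("")


def test_repeat_region_gly_fraction_matches_grammar_expectation():
    g = DEFAULT_GRAMMARS["MaSp1"]
    lib = library_by_type(load_terminal_library())
    rng = np.random.default_rng(3)
    fracs = []
    for _ in range(20):
        prot, truth = make_spidroin("MaSp1", 20, lib, substitution_rate=0.0,
                                    rng=rng, grammar=g)
        rep = prot[truth.repeat_start:truth.repeat_end]
        fracs.append(composition(rep)["G"])
    assert abs(np.mean(fracs) - g.expected_fraction("G")) < 0.05


# ---------------------------------------------------------------- architecture

def _th(terminus, qspan):
    return LocalAlignment(query="g", ref="r", score=500, bits=200, identity=95,
                          qspan=qspan, rspan=(0, 120), evalue=1e-60,
                          terminus=terminus, sptype="MaSp1")


def test_full_synthetic_spidroin_called_full_length():
    lib = library_by_type(load_terminal_library())
    prot, _ = make_spidroin("MaSp1", 18, lib, rng=np.random.default_rng(8))
    hits = [_th("N", (0, 120)), _th("C", (len(prot) - 120, len(prot)))]
    call = call_architecture(prot, hits, find_repeat_region(prot))
    assert call.classification == "full-length"
    assert call.has_N and call.has_C and call.has_repeat


def test_missing_C_terminus_called_partial():
    lib = library_by_type(load_terminal_library())
    prot, truth = make_spidroin("MaSp1", 18, lib, rng=np.random.default_rng(8))
    trunc = prot[:truth.repeat_end - 100]  # C domain gone
    hits = [_th("N", (0, 120))]
    call = call_architecture(trunc, hits, find_repeat_region(trunc))
    assert call.classification == "partial"
    assert call.has_N and not call.has_C


def test_decoy_with_no_evidence_is_non_spidroin():
    seq = make_decoy(300, 0.0, np.random.default_rng(10))
    call = call_architecture(seq, [], find_repeat_region(seq))
    assert call.classification == "non-spidroin"
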
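"""miRNA discovery: scan, precursor extraction, folding thermodynamics and
threshold filtering."""

import sys

import numpy as np
import pandas as pd
import pytest

from batmirnet import datasets, mirna

import _oracles as oracles

LET7 = "TGAGGTAGTAGGTTGTATAGTTT"


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_exact_mature_copy_yields_single_clean_hit():
    hits = mirna.scan_matches({"nc1": "GGAACC" + LET7 + "TTGGAA"},
                              {"let-7-5p": LET7})
    assert len(hits) == 1
    h = hits[0]
    assert (h.length, h.mismatches) == (23, 0)
    assert (h.start, h.end) == (6, 6 + 23)


def test_short_matures_cannot_hit():
    assert mirna.scan_matches({"n": "ACGT" * 30}, {"m": "ACGTACGTACGTACGTA"}) == []


def test_invalid_characters_rejected_with_record_name():
    with pytest.raises(ValueError, match="badrec"):
        mirna.scan_matches({"badrec": "ACGTNACGT" * 5}, {"m": LET7})


def test_scan_equals_exhaustive_hamming_scan(rng):
    matures = {f"m{i}": "".join(rng.choice(list("ACGU"), size=int(rng.integers(18, 25))))
               for i in range(10)}
    ncrna = "".join(rng.choice(list("ACGU"), size=500))
    # plant two copies to guarantee non-trivial hits
    m0 = matures["m0"]
    ncrna = ncrna[:50] + m0 + ncrna[50 + len(m0):]
    ncrna = ncrna[:300] + m0 + ncrna[300 + len(m0):]
    hits = mirna.scan_matches({"n": ncrna}, matures)
    for mid, mseq in matures.items():
        raw = oracles.hamming_scan(ncrna, mseq, 2)
        expected = oracles.collapse_overlaps(raw, len(mseq))
        got = sorted((h.start, h.mismatches) for h in hits if h.mature_id == mid)
        assert got == sorted(expected), mid


# ---------------------------------------------------------------------------
# precursor windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("start,end,n,expected", [
    (60, 83, 200, (10, 133)),   # interior hit: symmetric 50 nt flanks
    (5, 28, 200, (0, 78)),      # left clamp
    (173, 196, 200, (123, 200)),  # right clamp
])
def test_precursor_window_arithmetic(start, end, n, expected):
    seq = "ACGT" * (n // 4)
    hit = mirna.MatureHit("n", "m", start, end, end - start, 0)
    cand = mirna.extract_precursor(seq, hit, flank=50)
    assert (cand.window_start, cand.window_end) == expected
    assert cand.precursor_seq == seq[expected[0]:expected[1]].replace("T", "U")


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def test_unpairable_and_too_short_sequences_fold_open():
    assert mirna.fold_mfe("AAAAAAAAAA") == (0.0, "." * 10)
    assert mirna.fold_mfe("GCGC") == (0.0, "....")


def test_mfe_matches_enumeration_on_random_sequences(rng):
    """DP optimum equals full structure enumeration for short sequences,
    and the reported dot-bracket achieves the reported energy."""
    for _ in range(40):
        seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(6, 15))))
        mfe, db = mirna.fold_mfe(seq)
        expected, _, _, _ = oracles.brute_thermo(seq, mirna.DEFAULT_MODEL)
        assert mfe == pytest.approx(expected, abs=1e-9), seq
        pairs = _db_pairs(db)
        assert oracles.score_structure(seq, pairs, mirna.DEFAULT_MODEL) \
            == pytest.approx(mfe, abs=1e-9)


def _db_pairs(db):
    stack, pairs = [], set()
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.add((stack.pop(), i))
    assert not stack
    return pairs


def test_bp_probabilities_match_boltzmann_enumeration(rng):
    for _ in range(15):
        seq = "".join(rng.choice(list("ACGU"), size=12))
        probs = mirna.partition_bp_probs(seq)
        _, expected, ed_expected, _ = oracles.brute_thermo(seq, mirna.DEFAULT_MODEL)
        assert np.abs(probs - expected).max() < 1e-9, seq
        assert mirna.ensemble_diversity(probs) == pytest.approx(ed_expected, abs=1e-9)


def test_unpairable_sequence_has_empty_ensemble():
    assert not mirna.partition_bp_probs("AAAAAAAAAAAA").any()


def test_bp_probability_row_sums_bounded(rng):
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGU"), size=30))
        p = mirna.partition_bp_probs(seq)
        full = p + p.T
        assert full.sum(axis=1).max() <= 1.0 + 1e-9


def test_zero_temperature_limit_concentrates_on_mfe_structure():
    seq = "GGGGGAAAACCCCC"
    cold = mirna.EnergyModel(temperature=20.0)
    probs = mirna.partition_bp_probs(seq, cold)
    _, db = mirna.fold_mfe(seq, cold)
    for i, j in _db_pairs(db):
        assert probs[i, j] > 0.999


def test_partition_free_energy_never_below_mfe(rng):
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGU"), size=40))
        mfe, _ = mirna.fold_mfe(seq)
        assert mirna.ensemble_free_energy(seq) <= mfe + 1e-9


def test_ensemble_diversity_closed_forms():
    assert mirna.ensemble_diversity(np.zeros((8, 8))) == 0.0
    m = np.zeros((8, 8))
    m[2, 6] = 0.5
    assert mirna.ensemble_diversity(m) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# filtering and reporting
# ---------------------------------------------------------------------------

def _report(**overrides):
    base = {"mirna": ["x"], "sequence": [LET7], "length": [23],
            "mismatch": [0], "mfe": [-25.0], "ed": [5.0]}
    base.update({k: [v] for k, v in overrides.items()})
    return pd.DataFrame(base)


def test_mfe_boundary_is_strict():
    assert not mirna.apply_report_filters(_report(mfe=-19.9)).iloc[0]
    assert mirna.apply_report_filters(_report(mfe=-20.0)).iloc[0]


def test_ed_direction_flag():
    high = _report(ed=20.0)
    assert not mirna.apply_report_filters(high).iloc[0]
    assert mirna.apply_report_filters(high, ed_direction="ge").iloc[0]


def test_filtering_is_monotone_in_thresholds(rng):
    rep = pd.DataFrame({
        "mirna": [f"c{i}" for i in range(100)],
        "sequence": ["ACGT"] * 100,
        "length": rng.integers(15, 26, size=100),
        "mismatch": rng.integers(0, 4, size=100),
        "mfe": rng.uniform(-40, -5, size=100),
        "ed": rng.uniform(0, 30, size=100),
    })
    tight = mirna.apply_report_filters(rep, mfe_max=-25, ed_threshold=10)
    loose = mirna.apply_report_filters(rep, mfe_max=-15, ed_threshold=20)
    assert (tight <= loose).all()


def test_reported_candidate_table_fully_retained_under_le_direction():
    rep = datasets.novel_mirna_candidates()
    mask = mirna.apply_report_filters(rep, ed_direction="le")
    assert int(mask.sum()) == 19
    # the printed direction "ge" would retain none of them
    assert int(mirna.apply_report_filters(rep, ed_direction="ge").sum()) == 0


def test_empty_candidate_list_filters_to_empty():
    retained, report = mirna.filter_candidates([])
    assert retained == [] and len(report) == 0


def test_candidate_names_deduplicate_with_letter_suffixes():
    hit = mirna.MatureHit("n", "miR-1302", 0, 21, 21, 0)
    cands = [mirna.PrecursorCandidate(hit, 0, 21, "A" * 21) for _ in range(3)]
    assert mirna.candidate_names(cands) == \
        ["dro-miR-1302", "dro-miR-1302b", "dro-miR-1302c"]


def test_external_fold_engine_contract(tmp_path):
    script = tmp_path / "engine.py"
    script.write_text(
        "import sys\n"
        "data = sys.stdin.read().splitlines()\n"
        "name = data[0][1:]\n"
        "seq = data[1]\n"
        "print(f'{name}\\t-21.5\\t{\".\" * len(seq)}\\t3.2')\n")
    eng = mirna.ExternalFoldEngine(f"{sys.executable} {script}")
    mfe, db, ed = eng.fold("ACGUACGU")
    assert (mfe, db, ed) == (-21.5, "........", 3.2)
    assert eng.name.startswith("external:")
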
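"""Lowest-Bin scoring: the minimum over six flank lookups rules the motif."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmeopl import (
    FLANK_OFFSETS,
    RESIDUES,
    KCenteredMotif,
    ProteomeRecord,
    annotate_with_abundance,
    count_at_or_above,
    extract_motifs,
    lob_score,
    predict_optimal_sequence,
    predict_worst_sequence,
    score_proteome,
)

from conftest import make_profile


def brute_force_lob(raw: pd.DataFrame, window: str) -> float:
    """Independent oracle: explicit six lookups, then Python's min."""
    values = []
    for offset in (-3, -2, -1, 1, 2, 3):
        values.append(raw.loc[offset, window[3 + offset]])
    return min(values)


# ---------------------------------------------------------------- extraction

def test_extract_exact_fit_sequence():
    out = extract_motifs([ProteomeRecord("p", "GGGKGGG")])
    assert len(out) == 1
    motif, pid, kpos, reason = out[0]
    assert (motif.window, kpos, reason) == ("GGGKGGG", 4, None)


def test_extract_near_terminus():
    out = extract_motifs([ProteomeRecord("p", "KAAAA")])
    assert len(out) == 1
    assert out[0][0] is None and out[0][3] == "near_terminus"


def test_extract_flanking_lysine_allowed():
    out = extract_motifs([ProteomeRecord("p", "GGKKGGG")])
    by_pos = {kpos: (m, reason) for m, _, kpos, reason in out}
    assert by_pos[3][1] == "near_terminus"
    motif, reason = by_pos[4]
    assert reason is None and motif.residue_at(-1) == "K"


@pytest.mark.parametrize(
    "seq,reason",
    [("GGCKGGG", "contains_C"), ("GGXKGGG", "ambiguous_residue")],
)
def test_extract_flags_unmeasurable_windows(seq, reason):
    out = extract_motifs([ProteomeRecord("p", seq)])
    assert out[0][3] == reason


def test_extract_empty_proteome_warns():
    with pytest.warns(UserWarning, match="empty proteome"):
        assert extract_motifs([]) == []


# ------------------------------------------------------------------- scoring

def test_lob_score_constant_profile(uniform_profile):
    for window in ["AAAKAAA", "WYIKKYR", "TARKSTG"]:
        assert lob_score(uniform_profile, KCenteredMotif(window)) == 250.0


def test_lob_score_matches_bruteforce_oracle(rng):
    cols = ["A", "G", "K"]
    for _ in range(10):
        prof = make_profile(rng.uniform(0, 1000, (6, 3)), columns=cols)
        flanks = rng.choice(cols, 6)
        window = "".join(flanks[:3]) + "K" + "".join(flanks[3:])
        assert lob_score(prof, KCenteredMotif(window)) == brute_force_lob(
            prof.raw, window
        )


def test_zero_cell_dominates():
    mat = np.full((6, 19), 500.0)
    prof = make_profile(mat)
    prof.raw.at[2, "D"] = 0.0  # acidic residue disfavored at P+2
    assert lob_score(prof, KCenteredMotif("AAAKADA")) == 0.0


def test_lob_score_refuses_excluded_motif(uniform_profile):
    with pytest.raises(ValueError, match="contains_C"):
        lob_score(uniform_profile, KCenteredMotif("AACKAAA"))


def test_min_property_and_equality_at_some_position(rng):
    prof = make_profile(rng.uniform(0, 1000, (6, 19)))
    flanks = rng.choice(list(RESIDUES), 6)
    window = "".join(flanks[:3]) + "K" + "".join(flanks[3:])
    score = lob_score(prof, KCenteredMotif(window))
    cells = [prof.value(p, window[3 + p]) for p in FLANK_OFFSETS]
    assert all(score <= c for c in cells)
    assert any(score == c for c in cells)


def test_raising_a_cell_never_decreases_scores(rng):
    prof = make_profile(rng.uniform(0, 1000, (6, 19)))
    proteome = [ProteomeRecord("p", "".join(rng.choice(list(RESIDUES), 80)) + "KAAAKGG")]
    before = score_proteome(prof, proteome).set_index(["protein_id", "k_position"])
    prof.raw.at[-1, "A"] += 500.0
    bumped = make_profile(prof.raw.to_numpy())
    after = score_proteome(bumped, proteome).set_index(["protein_id", "k_position"])
    joined = before.join(after, lsuffix="_lo", rsuffix="_hi")
    scored = joined[~joined["excluded_lo"]]
    assert (scored["lob_score_hi"] >= scored["lob_score_lo"]).all()


# ------------------------------------------------------------------- ranking

def _toy_proteome(rng, n=8, length=60):
    return [
        ProteomeRecord(f"p{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), length)))
        for i in range(n)
    ]


def test_score_proteome_rank_and_norm(rng):
    prof = make_profile(rng.uniform(1, 1000, (6, 19)))
    results = score_proteome(prof, _toy_proteome(rng))
    scored = results[~results["excluded"]]
    assert scored["norm_score"].max() == 1.0
    top = scored.loc[scored["rank"] == 1.0, "lob_score"]
    assert (top == scored["lob_score"].max()).all()
    # min-rank ties: rank of k-th best equals 1 + number strictly above it
    for _, row in scored.iterrows():
        assert row["rank"] == 1 + (scored["lob_score"] > row["lob_score"]).sum()


def test_score_proteome_order_invariant(rng):
    prof = make_profile(rng.uniform(1, 1000, (6, 19)))
    proteome = _toy_proteome(rng)
    a = score_proteome(prof, proteome)
    b = score_proteome(prof, proteome[::-1])
    pd.testing.assert_frame_equal(a, b)


def test_score_proteome_zero_profile_refuses_ranking(rng):
    prof = make_profile(np.zeros((6, 19)))
    with pytest.warns(UserWarning, match="no binding signal"):
        results = score_proteome(prof, _toy_proteome(rng))
    scored = results[~results["excluded"]]
    assert (scored["lob_score"] == 0).all()
    assert scored["rank"].isna().all()


# ------------------------------------------------- optimal / worst sequences

def test_predict_sequences_from_toy_profile():
    mat = np.ones((6, 19))
    best, worst = "GAGSTG", "WYIKYR"  # flanks only; central K implied
    for i, (b, w) in enumerate(zip(best, worst)):
        mat[i, RESIDUES.index(b)] = 10.0
        mat[i, RESIDUES.index(w)] = 0.1
    prof = make_profile(mat)
    assert predict_optimal_sequence(prof).sequence == "GAGKSTG"
    assert predict_worst_sequence(prof).sequence == "WYIKKYR"


def test_predict_ties_and_unconstrained():
    mat = np.ones((6, 19))
    prof = make_profile(mat)
    pred = predict_optimal_sequence(prof)
    assert pred.unconstrained == (-3, -2, -1, 1, 2, 3)
    assert pred.ties[-3] == tuple(RESIDUES)
    assert pred.sequence == "AAAKAAA"  # lexicographically smallest


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_optimal_sequence_is_exhaustive_argmax_small_alphabet(seed):
    """On a 4-letter alphabet the argmax seven-mer beats all 4^6 candidates."""
    cols = ["A", "G", "S", "T"]
    rng = np.random.default_rng(seed)
    prof = make_profile(rng.uniform(0, 100, (6, 4)), columns=cols)
    pred = predict_optimal_sequence(prof)
    best_score = lob_score(prof, KCenteredMotif(pred.sequence))
    from itertools import product

    exhaustive = max(
        brute_force_lob(prof.raw, "".join(f[:3]) + "K" + "".join(f[3:]))
        for f in product(cols, repeat=6)
    )
    assert best_score == exhaustive


def test_rank_is_scale_invariant(rng):
    prof = make_profile(rng.uniform(1, 1000, (6, 19)))
    proteome = _toy_proteome(rng)
    raw_ranks = score_proteome(prof, proteome)["rank"]
    norm_ranks = score_proteome(prof.normalized(), proteome)["rank"]
    pd.testing.assert_series_equal(raw_ranks, norm_ranks)


# ----------------------------------------------- counting and abundance join

def test_count_at_or_above(rng):
    prof = make_profile(rng.uniform(1, 1000, (6, 19)))
    proteome = _toy_proteome(rng, n=5)
    results = score_proteome(prof, proteome)
    scored = results[~results["excluded"]]
    top = scored.iloc[0]
    assert count_at_or_above(results, (top["protein_id"], top["k_position"])) == 0
    ref = scored.iloc[min(10, len(scored) - 1)]
    expected = sum(
        s >= ref["lob_score"] for s in scored["lob_score"]
    ) - 1  # brute force, minus the reference itself
    assert count_at_or_above(results, (ref["protein_id"], ref["k_position"])) == expected


def test_count_all_tied_uniform_profile(uniform_profile, rng):
    results = score_proteome(uniform_profile, _toy_proteome(rng, n=4))
    scored = results[~results["excluded"]]
    ref = scored.iloc[0]
    assert (
        count_at_or_above(results, (ref["protein_id"], ref["k_position"]))
        == len(scored) - 1
    )


def test_count_missing_reference(uniform_profile, rng):
    results = score_proteome(uniform_profile, _toy_proteome(rng, n=2))
    with pytest.raises(KeyError):
        count_at_or_above(results, ("nope", 1))


def test_annotate_with_abundance_reproduces_histone_fold():
    """33e6 H3.1 copies vs 29e3 Sideroflexin-4 copies -> ~1,100-fold."""
    results = pd.DataFrame(
        {
            "protein_id": ["SFXN4", "H3-1", "UNKNOWN"],
            "k_position": [10, 4, 7],
            "window": ["AAAKAAA"] * 3,
            "lob_score": [784.25, 738.5, 100.0],
            "norm_score": [1.0, 0.94, 0.13],
            "rank": [1.0, 2.0, 3.0],
            "excluded": [False] * 3,
            "reason": [None] * 3,
        }
    )
    abundance = pd.DataFrame(
        {
            "protein_id": ["SFXN4", "H3-1"],
            "copy_number": [29e3, 33e6],
            "sd": [6.5e3, 4.3e6],
        }
    )
    out = annotate_with_abundance(results, abundance, reference_protein="H3-1")
    fold = out.set_index("protein_id")["fold_abundance"]
    assert float(f"{fold['SFXN4']:.2g}") == 1100.0
    assert fold["H3-1"] == 1.0
    assert out.set_index("protein_id").at["UNKNOWN", "abundance_missing"]
    with pytest.raises(KeyError):
        annotate_with_abundance(results, abundance, reference_protein="H4")
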
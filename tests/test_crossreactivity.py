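import itertools

import numpy as np
import pandas as pd
import pytest

from phipkit import crossreactivity as xr
from phipkit.errors import AlphabetError, PreconditionError
from phipkit.io import AA_ALPHABET

GONNET = xr.gonnet_pam250()


def _proteome(seqs: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"description": list(seqs), "aa_seq": list(seqs.values())},
        index=pd.Index(list(seqs), name="protein_id"),
    )


def enumerate_local_score(a, b, matrix, gap_open=10.0, gap_extend=0.2):
    """Exhaustive enumeration of every local alignment path.

    Walks every monotone path from every start cell, charging gap_open for a
    gap's first column and gap_extend for each subsequent one; the local
    optimum is the best prefix score seen anywhere (never below 0).
    """
    best = 0.0

    def rec(i, j, prev, score):
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "A", score - (gap_extend if prev == "A" else gap_open))
        if j < len(b):
            rec(i, j + 1, "B", score - (gap_extend if prev == "B" else gap_open))

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0, j0, "start", 0.0)
    return best


# ------------------------------------------------------------- symbols & score

def test_identical_residues_are_stars():
    for a in AA_ALPHABET:
        assert xr.pair_symbol(a, a) == "*"
        assert xr.column_conservation(a, a) == 11


def test_symbol_thresholds_follow_matrix_exhaustively():
    """Every non-identical pair falls in the branch its published Gonnet
    score dictates: ':' above 0.5, '.' in (0, 0.5], space at <= 0."""
    seen = set()
    for a, b in itertools.product(AA_ALPHABET, repeat=2):
        if a == b:
            continue
        s = GONNET[a, b]
        sym = xr.pair_symbol(a, b)
        if s > 0.5:
            assert sym == ":"
        elif s > 0:
            assert sym == "."
        else:
            assert sym == " "
        seen.add(sym)
    assert seen == {":", ".", " "}  # all three branches exercised


def test_known_pairs():
    assert xr.pair_symbol("L", "L") == "*"
    assert GONNET["I", "V"] > 0.5 and xr.pair_symbol("I", "V") == ":"
    assert GONNET["W", "D"] <= 0 and xr.pair_symbol("W", "D") == " "


def test_gap_columns_are_blank():
    assert xr.pair_symbol("-", "L") == " "
    assert xr.pair_symbol("A", "-") == " "
    assert xr.column_conservation("-", "K") == 0


def test_unknown_residue_raises():
    with pytest.raises(AlphabetError):
        xr.pair_symbol("A", "Z")
    with pytest.raises(AlphabetError):
        xr.column_conservation("B", "A")


def test_conservation_matches_property_counting_exhaustively():
    """All 400 pairs: score is the number of the ten property classes on
    which the residues agree (shared membership or shared absence), 11 iff
    identical."""
    for a, b in itertools.product(AA_ALPHABET, repeat=2):
        expected = 11 if a == b else sum(
            (a in members) == (b in members)
            for members in xr.PROPERTY_TABLE.values()
        )
        assert xr.column_conservation(a, b) == min(expected, 11)


def test_fully_conserved_nonidentical_pair_scores_ten():
    # I and L agree on every one of the ten property classes
    assert xr.column_conservation("I", "L") == 10


# ----------------------------------------------------------------------- scans

QUERY = "MKVLAWTSERGFDNIH"  # 16 residues


def test_exact_substring_is_top_hit_all_stars():
    target = "GGGPPP" + QUERY + "CCDD"
    prot = _proteome({"viral1": target, "viral2": "AAAA" + "W" * 20})
    hits = xr.scan_proteome(QUERY, prot, mode="ungapped_window", top_k=3)
    top = hits[0]
    assert top.protein_id == "viral1"
    assert top.offset == 6
    assert top.symbols == "*" * len(QUERY)
    assert top.conservation == (11,) * len(QUERY)
    self_score = sum(GONNET[c, c] for c in QUERY)
    assert top.score == pytest.approx(self_score)


def test_ungapped_score_matches_per_column_summation():
    rng = np.random.default_rng(8)
    t = "".join(rng.choice(list(AA_ALPHABET), size=40))
    prot = _proteome({"p": t})
    hits = xr.scan_proteome(QUERY, prot, mode="ungapped_window", top_k=5)
    for h in hits:
        direct = sum(GONNET[qa, ta] for qa, ta in zip(h.query_aln, h.target_aln))
        assert h.score == pytest.approx(direct)
        assert h.target_aln == t[h.offset : h.offset + len(QUERY)]


def test_local_score_at_least_ungapped():
    rng = np.random.default_rng(15)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        t = "".join(rng.choice(list(AA_ALPHABET), size=30))
        prot = _proteome({"p": t})
        ung = xr.scan_proteome(QUERY, prot, mode="ungapped_window", top_k=1)[0]
        loc = xr.scan_proteome(QUERY, prot, mode="local", top_k=1)[0]
        assert loc.score >= ung.score - 1e-9


def test_reversed_query_and_target_same_ungapped_score():
    rng = np.random.default_rng(21)
    t = "".join(rng.choice(list(AA_ALPHABET), size=30))
    prot_f = _proteome({"p": t})
    prot_r = _proteome({"p": t[::-1]})
    f = xr.scan_proteome(QUERY, prot_f, mode="ungapped_window", top_k=1)[0]
    r = xr.scan_proteome(QUERY[::-1], prot_r, mode="ungapped_window", top_k=1)[0]
    assert f.score == pytest.approx(r.score)


def test_smith_waterman_matches_exhaustive_enumeration():
    """Local alignment score equals brute-force path enumeration on short
    random sequences."""
    aligner = xr._local_aligner(xr._matrix_with_x(), 10.0, 0.2)
    rng = np.random.default_rng(33)
    for _ in range(6):
        a = "".join(rng.choice(list(AA_ALPHABET), size=rng.integers(4, 7)))
        b = "".join(rng.choice(list(AA_ALPHABET), size=rng.integers(4, 7)))
        expected = enumerate_local_score(a, b, GONNET)
        alns = aligner.align(a, b)
        got = alns.score if len(alns) else 0.0
        assert got == pytest.approx(expected, abs=1e-9)


def test_scan_preconditions():
    prot = _proteome({"p": "ACDEFGHIKLMNP"})
    with pytest.raises(PreconditionError, match="8 residues"):
        xr.scan_proteome("ACDE", prot)
    with pytest.raises(PreconditionError, match="empty"):
        xr.scan_proteome(QUERY, prot.iloc[0:0])


def test_rank_ties_broken_by_protein_then_offset():
    seq = QUERY + "GG" + QUERY  # two identical loci in each protein
    prot = _proteome({"pB": seq, "pA": seq})
    hits = xr.scan_proteome(QUERY, prot, mode="ungapped_window", top_k=4)
    assert [(h.protein_id, h.offset) for h in hits] == [
        ("pA", 0), ("pA", len(QUERY) + 2), ("pB", 0), ("pB", len(QUERY) + 2)
    ]


def test_conservation_string_encoding():
    target = "GG" + QUERY
    prot = _proteome({"p": target})
    top = xr.scan_proteome(QUERY, prot, top_k=1)[0]
    assert top.conservation_string == "*" * len(QUERY)
    assert xr.hits_to_frame([top]).loc[0, "symbol_string"] == "*" * len(QUERY)
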
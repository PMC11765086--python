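import numpy as np
import pytest

from _oracles import brute_window_qualifies
from cesa.alignment import SiteAlignmentContext
from cesa.conservation import (
    is_conservative_substitution,
    longest_identical_run,
    score_site,
    score_windows,
    window_qualifies,
)
from conftest import TABLE1

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize("name,human,fly,expected", TABLE1, ids=[r[0] for r in TABLE1])
def test_validated_epitopes_reproduce_conserved_region_lengths(name, human, fly, expected):
    """The 12 human/fly epitope pairs with experimentally validated
    cross-reactivity have known identical-stretch lengths."""
    assert longest_identical_run(human, fly) == expected


def test_run_is_zero_when_site_differs():
    assert longest_identical_run("AAAAAAAYAAAAAAA", "AAAAAAASAAAAAAA") == 0


def test_run_requires_15mer_windows():
    with pytest.raises(ValueError):
        longest_identical_run("SHORT", "SHORT")


def test_run_is_case_insensitive_and_padding_never_matches():
    assert longest_identical_run("aaaaaaaYaaaaaaa", "AAAAAAAYAAAAAAA") == 15
    assert longest_identical_run("______MSGRGKGGK", "______MSGRGKGGK", site_index=8) == 9


@pytest.mark.parametrize(
    "a,b,expected",
    [("K", "R", True), ("H", "L", False), ("A", "A", False), ("S", "T", True),
     ("X", "X", False), ("K", "U", False)],
)
def test_conservative_substitution_rule(a, b, expected):
    assert is_conservative_substitution(a, b) is expected
    assert is_conservative_substitution(b, a) is expected  # symmetric


def test_akt1_pair_qualifies_only_at_length_six():
    human, fly = "RPHFPQFSYSASGTA", "EPLFPQFSYQGDMAS"
    assert window_qualifies(human, fly, length=6)[0] is True
    assert window_qualifies(human, fly, length=7)[0] is False


def test_long_identical_run_qualifies_all_lengths():
    human, fly = "SDGEFLRTSCGSPNY", "LDGEFLRTSCGSPNY"
    for length in range(6, 12):
        assert window_qualifies(human, fly, length=length)[0] is True


def test_one_conservative_substitution_away_from_site_qualifies():
    q = "AWDEKGHYILMNPQR"  # K at site-3 (position 5)
    s = q[:4] + "R" + q[5:]  # K->R, a conservative replacement
    ok, note = window_qualifies(q, s, length=8)
    assert ok and note == (5, "K", "R")


def test_substitution_adjacent_to_site_disqualifies():
    # a window containing an adjacent substitution never qualifies; windows
    # that stop short of it still can, so flanking the site on both sides
    # with conservative replacements defeats every window
    q = "AWDEFGKYDLMNPQR"  # K at site-1, D at site+1
    s = q[:6] + "R" + q[7] + "E" + q[9:]  # K->R and D->E, both conservative
    for length in range(6, 12):
        assert window_qualifies(q, s, length=length)[0] is False
    # a single adjacent substitution disqualifies exactly the windows that
    # contain it: at L=11 every window containing the site also contains
    # site+1, so qualification fails there
    q2 = "AWDEFGHYKLMNPQR"
    s2 = q2[:8] + "R" + q2[9:]  # K->R at site+1
    assert window_qualifies(q2, s2, length=11)[0] is False
    assert window_qualifies(q2, s2, length=6)[0] is True  # window ending at the site


def test_window_length_bounds():
    q = "A" * 15
    with pytest.raises(ValueError):
        window_qualifies(q, q, length=5)


def _mutated_pairs(rng, n):
    for _ in range(n):
        q = "".join(AA[j] for j in rng.integers(0, 20, 15))
        rate = rng.uniform(0.0, 0.4)
        s = "".join(
            AA[rng.integers(0, 20)] if rng.uniform() < rate else c for c in q
        )
        yield q, s


def test_window_rule_matches_literal_enumeration():
    rng = np.random.default_rng(101)
    for q, s in _mutated_pairs(rng, 2000):
        for length in range(6, 12):
            assert window_qualifies(q, s, length=length)[0] == brute_window_qualifies(
                q, s, length
            ), (q, s, length)


def test_qualification_is_monotone_in_length():
    rng = np.random.default_rng(102)
    for q, s in _mutated_pairs(rng, 1500):
        res = score_windows(q, s)
        flags = [res.qualified_lengths[L] for L in range(6, 12)]
        for shorter, longer in zip(flags, flags[1:]):
            assert shorter or not longer  # qualified(L) implies qualified(L-1)
        if res.longest_identical_run >= 6:
            assert res.qualified_lengths[6]
        if not res.site_identical:
            assert res.longest_identical_run == 0 and not any(flags)


def test_zero_substitution_limit():
    """With the conservative-replacement allowance disabled, qualification
    collapses to the identical run: max qualifying L = min(11, run) when the
    run reaches 6, else 0."""
    rng = np.random.default_rng(103)
    for q, s in _mutated_pairs(rng, 800):
        res = score_windows(q, s, allow_substitution=False)
        run = res.longest_identical_run
        expected = min(11, run) if run >= 6 else 0
        assert res.max_qualified_length == expected


def _identity_context(window):
    return SiteAlignmentContext(
        aligned_query=window,
        aligned_subject=window,
        site_column=7,
        subject_site_position=8,
        subject_site_residue=window[7],
        alignment_score=0.0,
    )


def test_score_site_identity_alignment():
    res = score_site(_identity_context("MILLSELSRRRIRSI"))
    assert res.longest_identical_run == 15
    assert res.max_qualified_length == 11
    assert all(res.qualified_lengths.values())


def test_score_site_gap_at_site_column():
    ctx = SiteAlignmentContext(
        aligned_query="MILLSELSRRRIRSI",
        aligned_subject="MILLSEL-RRRIRSI",
        site_column=7,
        subject_site_position=None,
        subject_site_residue="-",
        alignment_score=0.0,
    )
    res = score_site(ctx)
    assert not res.site_identical
    assert res.longest_identical_run == 0
    assert not any(res.qualified_lengths.values())


def test_score_site_embedded_gap_free_pair():
    # p38 MAP kinase activation-loop epitope: run of 6 through the site
    query = "GGGGG" + "RQADSEMTGYVVTRW" + "GGGGG"
    subject = "GGGGG" + "RPTENEMTGYVATRW" + "GGGGG"
    ctx = SiteAlignmentContext(query, subject, 12, 13, "T", 0.0)
    res = score_site(ctx)
    assert res.longest_identical_run == 6
    assert res.qualified_lengths[6] is True


def test_score_site_pads_past_alignment_ends():
    # site two columns from the alignment start: the slice is padded with
    # gap sentinels, which never match but do not crash
    window = "MSGRGKGGKGLGKGG"
    ctx = SiteAlignmentContext(window, window, 1, 2, "S", 0.0)
    res = score_site(ctx)
    assert res.site_identical
    assert res.longest_identical_run == 9  # columns 0..8 of the slice exist
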
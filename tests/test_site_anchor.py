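import numpy as np
import pytest

from _oracles import brute_locate
from cesa.catalog_io import PhosphoSiteRecord
from cesa.reference_store import GeneIdMap, ProteinRecord, ProteinStore
from cesa.site_anchor import anchor_site, locate_peptide

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, n):
    return "".join(AA[j] for j in rng.integers(0, 20, n))


def test_locate_interior_peptide():
    seq = "M" * 9 + "MILLSELSRRRIRSI" + "W" * 5
    assert locate_peptide("MILLSELSRRRIRSI", seq) == [17]  # 10 + 8 - 1


def test_locate_n_terminal_padding_matches_only_at_start():
    seq = "MSGRGKGGKAAAAAA" + "MSGRGKGGK"  # core also occurs internally
    assert locate_peptide("______MSGRGKGGK", seq) == [2]


def test_locate_c_terminal_padding_matches_only_at_end():
    seq = "AAAAAAA" + "GKGGKARS"
    assert locate_peptide("GKGGKARS_______", seq) == [len(seq)]


def test_locate_reports_every_occurrence():
    window = "ACDEFGHSKLMNPQR"
    seq = "W" * 4 + window + "W" * 6 + window + "W" * 3
    assert locate_peptide(window, seq) == [12, 33]


def test_locate_agrees_with_naive_oracle_on_random_sequences():
    rng = np.random.default_rng(77)
    for _ in range(150):
        seq = _random_seq(rng, int(rng.integers(20, 120)))
        # a true window of the sequence must be recovered (completeness)
        start = int(rng.integers(0, len(seq) - 15 + 1))
        window = seq[start : start + 15]
        assert start + 8 in locate_peptide(window, seq)
        assert locate_peptide(window, seq) == brute_locate(window, seq)
        # and a random probe window agrees with the oracle too
        probe = _random_seq(rng, 15)
        assert locate_peptide(probe, seq) == brute_locate(probe, seq)


def test_locate_terminal_padding_agrees_with_oracle():
    rng = np.random.default_rng(78)
    for _ in range(60):
        seq = _random_seq(rng, int(rng.integers(15, 60)))
        n_pad = int(rng.integers(1, 8))
        n_term = "_" * n_pad + seq[: 15 - n_pad]
        c_term = seq[-(15 - n_pad) :] + "_" * n_pad
        for flank in (n_term, c_term):
            assert locate_peptide(flank, seq) == brute_locate(flank, seq)


# ---------------------------------------------------------------------------
# anchoring cascade


def _record(accession="NP_1.1", position=30, flank=None, symbol="GENEA"):
    return PhosphoSiteRecord(
        source_species="human",
        gene_symbol=symbol,
        protein_accession=accession,
        residue="Y",
        position=position,
        flank_peptide=flank,
        antibody_ids=("CST1",),
    )


@pytest.fixture()
def setting():
    rng = np.random.default_rng(5)
    window = "ACDEFGHYKLMNPQR"  # site Y at index 8
    seq = _random_seq(rng, 22) + window + _random_seq(rng, 25)
    assert seq.count(window) == 1
    site_pos = 22 + 8  # 1-based
    store = ProteinStore("human")
    store.add(ProteinRecord("NP_1.1", "human", 42, seq))
    idmap = GeneIdMap()
    idmap.add("symbol", "GENEA", 42)
    return store, idmap, window, seq, site_pos


def test_anchor_direct(setting):
    store, idmap, window, seq, pos = setting
    res = anchor_site(_record(position=pos, flank=window), store, idmap)
    assert res.status == "anchored_direct" and res.site_position == pos


def test_anchor_shifted_when_catalog_position_is_stale(setting):
    store, idmap, window, seq, pos = setting
    stated = next(p for p in range(1, len(seq) + 1) if seq[p - 1] != "Y")
    res = anchor_site(_record(position=stated, flank=window), store, idmap)
    assert res.status == "anchored_shifted" and res.site_position == pos


def test_anchor_rescued_by_symbol_when_accession_is_stale(setting):
    store, idmap, window, seq, pos = setting
    res = anchor_site(_record(accession="NP_GONE.1", position=pos, flank=window), store, idmap)
    assert res.status == "rescued_by_symbol"
    assert res.protein.accession == "NP_1.1" and res.site_position == pos


def test_anchor_fails_without_protein_or_symbol(setting):
    store, idmap, window, seq, pos = setting
    res = anchor_site(
        _record(accession="NP_GONE.1", position=pos, flank=window, symbol="NOSYM"),
        store,
        idmap,
    )
    assert res.status == "failed" and res.failure_reason == "no_protein"


def test_anchor_fails_when_peptide_absent(setting):
    store, idmap, window, seq, pos = setting
    absent = "WWWWWWWYWWWWWWW"
    res = anchor_site(_record(position=pos, flank=absent), store, idmap)
    assert res.status == "failed" and res.failure_reason == "peptide_not_found"


def test_anchor_fails_on_ambiguous_peptide():
    window = "ACDEFGHYKLMNPQR"
    seq = "W" * 10 + window + "W" * 10 + window + "W" * 10
    store = ProteinStore("human")
    store.add(ProteinRecord("NP_1.1", "human", 42, seq))
    res = anchor_site(_record(position=1, flank=window), store, None)
    assert res.status == "failed" and res.failure_reason == "ambiguous_peptide"


def test_anchor_rescue_fails_on_ambiguous_gene():
    window = "ACDEFGHYKLMNPQR"
    store = ProteinStore("human")
    store.add(ProteinRecord("NP_1.1", "human", 42, "W" * 8 + window + "W" * 8))
    store.add(ProteinRecord("NP_2.1", "human", 43, "M" * 8 + window + "M" * 8))
    idmap = GeneIdMap()
    idmap.add("symbol", "GENEA", 42)
    idmap.add("symbol", "GENEA", 43)
    res = anchor_site(_record(accession="NP_GONE.1", position=16, flank=window), store, idmap)
    assert res.status == "failed" and res.failure_reason == "ambiguous_gene"


def test_anchor_is_deterministic_and_idempotent(setting):
    store, idmap, window, seq, pos = setting
    record = _record(position=pos, flank=window)
    first = anchor_site(record, store, idmap)
    second = anchor_site(record, store, idmap)
    assert first == second
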
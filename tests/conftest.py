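import pandas as pd
import pytest

from cesa import FixtureSpec, config_for_fixture, make_fixture, run_pipeline

#: Table of validated cross-reactive antibody epitopes: human 15-mer, fly
#: ortholog 15-mer, and the length of the identical stretch through the site.
TABLE1 = [
    ("AKT1", "RPHFPQFSYSASGTA", "EPLFPQFSYQGDMAS", 6),
    ("PRKAA1", "SDGEFLRTSCGSPNY", "LDGEFLRTSCGSPNY", 14),
    ("MAPK10a", "AGTSFMMTPYVVTRY", "AGTTFMMTPYVVTRY", 11),
    ("MAPK10b", "TSFMMTPYVVTRYYR", "TTFMMTPYVVTRYYR", 13),
    ("EIF2S1", "MILLSELSRRRIRSI", "MILLSELSRRRIRSI", 15),
    ("MAPK12a", "RQADSEMTGYVVTRW", "RPTENEMTGYVATRW", 6),
    ("MAPK12b", "ADSEMTGYVVTRWYR", "TENEMTGYVATRWYR", 6),
    ("MAPK1a", "HDHTGFLTEYVATRW", "HDHTGFLTEYVATRW", 15),
    ("MAPK1b", "HTGFLTEYVATRWYR", "HTGFLTEYVATRWYR", 15),
    ("RPS6KB1", "NQVFLGFTYVAPSVL", "NLIFQGFTYVAPSIL", 8),
    ("EIF4EBP1a", "PPGDYSTTPGGTLFS", "MPEVYSSTPGGTLYS", 6),
    ("EIF4EBP1b", "GGTLFSTTPGGTRII", "GGTLYSTTPGGTKLI", 7),
]

FIXTURE_SEED = 20240
FIXTURE_N_GENES = 57  # three full passes over the 19 conservation classes


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    make_fixture(FixtureSpec(seed=FIXTURE_SEED, n_genes=FIXTURE_N_GENES), d)
    return d


@pytest.fixture(scope="session")
def truth(fixture_dir):
    return pd.read_csv(fixture_dir / "truth.tsv", sep="\t", keep_default_na=False)


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir):
    return run_pipeline(config_for_fixture(fixture_dir))


def compare_to_truth(truth, result):
    """Check pipeline output against a fixture truth table.

    Returns a list of (site, field, got, expected) mismatches; empty means
    100% agreement on anchoring status, dispositions, site positions, run
    lengths and qualified window lengths."""
    mismatches = []
    anch = result.anchoring.set_index("gene_symbol")
    for _, t in truth.iterrows():
        gene = t["gene_symbol"]
        a = anch.loc[gene]
        for field, col in [
            ("status", "expected_status"),
            ("failure_reason", "expected_failure_reason"),
            ("disposition", "expected_disposition"),
        ]:
            if str(a[field]) != str(t[col]):
                mismatches.append((gene, field, a[field], t[col]))
        if t["expected_disposition"] != "scored":
            continue
        rows = result.report[
            (result.report["source_gene_symbol"] == gene)
            & (result.report["target_isoform_accession"] == t["isoform_accession"])
        ]
        if len(rows) != 1:
            mismatches.append((gene, "n_report_rows", len(rows), 1))
            continue
        r = rows.iloc[0]
        if int(r["site_position"]) != int(t["expected_site_position"]):
            mismatches.append((gene, "site_position", r["site_position"],
                               t["expected_site_position"]))
        if int(r["longest_identical_run"]) != int(t["expected_run"]):
            mismatches.append((gene, "run", r["longest_identical_run"], t["expected_run"]))
        got_qualified = ",".join(str(L) for L in range(6, 12) if r[f"qualified_{L}"])
        if got_qualified != str(t["expected_qualified_lengths"]):
            mismatches.append((gene, "qualified", got_qualified,
                               t["expected_qualified_lengths"]))
    return mismatches
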
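import pandas as pd
import pytest

from rorscreen import (
    deduplicate,
    link_tables,
    load_default_dictionary,
    make_paper_like_fixture,
)


def write_csv(path, header, rows):
    """Write a small CSV fixture file from a header and row tuples."""
    lines = [",".join(header)]
    lines += [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def demo_frame(rows):
    """Build a canonical DEMO frame from (case_id, version, year, quarter)."""
    return pd.DataFrame(
        [
            {
                "case_id": cid,
                "report_version": version,
                "sex": "female",
                "age_band": "60s",
                "weight_band": "50-59kg",
                "height_band": "150-159cm",
                "report_year": year,
                "report_quarter": quarter,
            }
            for cid, version, year, quarter in rows
        ]
    )


def drug_frame(rows):
    """Build a canonical DRUG frame from (case_id, drug_name, involvement)."""
    return pd.DataFrame(rows, columns=["case_id", "drug_name", "involvement"])


def reac_frame(rows):
    """Build a canonical REAC frame from (case_id, preferred_term)."""
    return pd.DataFrame(
        [(cid, pt, None) for cid, pt in rows],
        columns=["case_id", "preferred_term", "outcome"],
    )


@pytest.fixture(scope="session")
def default_dictionary():
    return load_default_dictionary()


@pytest.fixture(scope="session")
def paper_like():
    return make_paper_like_fixture()


@pytest.fixture(scope="session")
def paper_like_db(paper_like):
    return link_tables(
        deduplicate(paper_like.demo), paper_like.drug, paper_like.reac
    )
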
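"""Shared fixtures: small synthetic cohorts and derived pipeline objects."""

import pandas as pd
import pytest

from phenostrat import tag_corpus, vectorize
from phenostrat.synthetic_cohort import CohortConfig, dictionary_entries, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120 patients, 4 planted clusters, default noise."""
    return generate_cohort(CohortConfig(n_patients=120, k_clusters=4, seed=7))


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with no typos and no negations (lossless tagging expected)."""
    return generate_cohort(
        CohortConfig(n_patients=80, k_clusters=4, typo_rate=0.0, negation_rate=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def small_events(small_cohort):
    """Combined assigned + mined code events for the small cohort."""
    _, mined = tag_corpus(small_cohort.notes, dictionary_entries(small_cohort))
    return pd.concat([small_cohort.diagnoses, mined], ignore_index=True)


@pytest.fixture(scope="session")
def small_vectors(small_events):
    vectors, stats, empty = vectorize(small_events)
    return vectors


def events_frame(rows):
    """Build a code-event DataFrame from (patient, code, date[, source]) rows."""
    recs = []
    for row in rows:
        pid, code, date = row[:3]
        source = row[3] if len(row) > 3 else "assigned"
        recs.append({"patient_id": pid, "code": code, "date": date, "source": source})
    df = pd.DataFrame(recs)
    df["date"] = pd.to_datetime(df["date"])
    return df
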
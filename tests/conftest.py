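import pytest

import pestsafe as ps


@pytest.fixture(scope="session")
def model():
    return ps.build_default_model()


@pytest.fixture(scope="session")
def sample_records():
    """The ten published sample pesticides as PesticideRecords."""
    df = ps.load_fixture("pesticides")
    return [
        ps.PesticideRecord(
            name=row["name"],
            persistency=float(row["persistency_days"]),
            aeq=float(row["aeq"]),
            ld50_bee=float(row["ld50_ug_per_bee"]),
            likely_exposure=float(row["likely_exposure"]),
            mrl=float(row["mrl_mg_per_kg"]),
        )
        for _, row in df.iterrows()
    ]


@pytest.fixture(scope="session")
def expected_scores():
    df = ps.load_fixture("expected_scores")
    return dict(zip(df["name"], df["safety_level_point"]))


@pytest.fixture()
def sample_csv(tmp_path):
    """The sample pesticide table written as a CSV file."""
    df = ps.load_fixture("pesticides")
    path = tmp_path / "pesticides.csv"
    df.to_csv(path, index=False)
    return path
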
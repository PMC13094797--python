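import pytest
from hypothesis import settings

import studyflow as sf

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_config():
    return sf.load_demo_config()


@pytest.fixture()
def config():
    """A fresh (mutable) demo configuration per test."""
    return sf.load_demo_config()


@pytest.fixture()
def store(config, tmp_path):
    s = sf.open_store(tmp_path / "study.db", config)
    yield s
    s.close()


@pytest.fixture()
def small_study(config):
    sim = sf.SimConfig(seed=42, n_donors=60)
    return sim, sf.generate_study(sim, config)


def write_csv(path, header, rows):
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)
    return path
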
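import pytest

from pvsignals import (
    SyntheticConfig,
    assemble_reports,
    generate_dataset,
    read_quarter,
)


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """A moderately sized synthetic corpus with two injected signals,
    duplicates and co-medication, shared across the suite."""
    out = tmp_path_factory.mktemp("corpus")
    cfg = SyntheticConfig(
        n_cases=2000,
        signal_table={("IVIG", "Headache"): 15.0, ("IVIG", "Chills"): 8.0},
        duplicate_rate=0.2,
        comed_rate=0.3,
        seed=42,
    )
    quarters = generate_dataset(cfg, out)
    return out, cfg, quarters


@pytest.fixture(scope="session")
def reports(corpus_dir):
    _out, _cfg, quarters = corpus_dir
    tables = [read_quarter(q) for q in quarters]
    return assemble_reports(tables, ["IVIG"])
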
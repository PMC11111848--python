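"""Shared fixtures: one small synthetic FAERS corpus on disk, reused by
the ingest/disproportionality/pipeline tests."""

import pytest

from faers_signal import (
    DisproportionalityModel,
    SynthConfig,
    deduplicate,
    event_pairs,
    generate_quarters,
    load_quarters,
    map_events,
    read_meddra_map,
    select_cases,
)


def small_config(seed: int = 11, **overrides) -> SynthConfig:
    base = dict(
        seed=seed,
        n_background_reports=8_000,
        n_target_reports=600,
        quarters=("22Q1", "22Q2", "22Q3", "22Q4"),
        year_weights={2022: 1.0},
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """(directory, config, ground truth) for a small on-disk corpus."""
    out = tmp_path_factory.mktemp("synth")
    config = small_config()
    truth = generate_quarters(config, out)
    return out, config, truth


@pytest.fixture(scope="session")
def raw(corpus):
    out, _config, _truth = corpus
    return load_quarters(out)


@pytest.fixture(scope="session")
def survivors(raw):
    return deduplicate(raw.demo)


@pytest.fixture(scope="session")
def meddra(corpus):
    out, _, _ = corpus
    return read_meddra_map(out / "pt_soc_map.txt")


@pytest.fixture(scope="session")
def cases(corpus, raw, survivors, meddra):
    _, config, _ = corpus
    cs = select_cases(raw, [config.target_drug_name], "PS", survivors)
    return map_events(cs, meddra)


@pytest.fixture(scope="session")
def pt_results(raw, survivors, cases, meddra):
    pairs = event_pairs(raw, survivors)
    model = DisproportionalityModel(pairs, set(cases.report_ids), term_soc=meddra)
    return model.fit()
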
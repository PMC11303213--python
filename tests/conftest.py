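import textwrap
from types import SimpleNamespace

import pytest

from carrierprev import (
    FixtureSpec,
    generate_fixture,
    intersect,
    load_catalog,
    read_cohort_vcf,
    read_external_frequencies,
    read_panel,
    stratified_frequencies,
)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Default synthetic study fixture, generated once per session."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(seed=0), out)


@pytest.fixture(scope="session")
def bundle(fixture_paths):
    """The full pipeline state on the default fixture."""
    cohort = read_cohort_vcf(fixture_paths.cohort_vcf)
    panel = read_panel(fixture_paths.panel)
    catalog = load_catalog(fixture_paths.catalog)
    result = intersect(cohort, catalog)
    records = stratified_frequencies(cohort, panel, result.matched_keys)
    external = read_external_frequencies(fixture_paths.external_freq)
    return SimpleNamespace(
        paths=fixture_paths,
        cohort=cohort,
        panel=panel,
        catalog=catalog,
        result=result,
        records=records,
        external=external,
    )


@pytest.fixture
def write_vcf(tmp_path):
    """Write a dedented VCF body (with its own header) to a temp file."""

    def _write(body: str, name: str = "test.vcf"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(body).lstrip())
        return path

    return _write
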
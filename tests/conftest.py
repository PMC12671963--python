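import json

import pytest

from snpriority import generate_domain_fixture, generate_fixture, parse_variant_table


@pytest.fixture
def make_table(tmp_path):
    """Write a synthetic variant table and return its path."""

    def _make(n=10, seed=42, name="variants.tsv", **kwargs):
        path = tmp_path / name
        path.write_text(generate_fixture(n, seed=seed, **kwargs), encoding="utf-8")
        return path

    return _make


@pytest.fixture
def make_domain_fixture(tmp_path):
    """Write a JSON domain fixture matched to a parsed variant table."""

    def _make(table_path, seed=1, name="domains.json", **kwargs):
        table = parse_variant_table(table_path)
        fixture = generate_domain_fixture(
            [(r.gene, r.protein_length) for r in table.records], seed=seed, **kwargs
        )
        path = tmp_path / name
        path.write_text(json.dumps(fixture), encoding="utf-8")
        return path

    return _make
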
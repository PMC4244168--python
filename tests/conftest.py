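import pytest

from rtphylo.simulate import benchmark_config, generate


@pytest.fixture(scope="session")
def benchmark_truth():
    """The standard benchmark dataset: 8 groups x 12 sequences, within-group
    divergence 0.2 subs/site, between-group 1.0, motif retention 0.95."""
    return generate(benchmark_config(seed=42))


@pytest.fixture(scope="session")
def benchmark_split(benchmark_truth):
    """(representatives, labels, queries): the labeled initial members of
    each group versus the held-out rest."""
    meta = benchmark_truth.metadata
    records = {r.id: r for r in benchmark_truth.records}
    initial = [rid for rid in meta.ids if meta.table.at[rid, "initial_dataset"]]
    labels = {rid: meta.group_of(rid) for rid in initial}
    queries = [records[rid] for rid in meta.ids if rid not in set(initial)]
    return [records[rid] for rid in initial], labels, queries
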
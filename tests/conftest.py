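import pytest

from qualimpact import refdata
from qualimpact.benchmarks import load_benchmark_table, load_benchmark_tables


@pytest.fixture(scope="session")
def bench_csv():
    return refdata.benchmark_csv_path()


@pytest.fixture(scope="session")
def all_tables(bench_csv):
    return load_benchmark_tables(bench_csv)


@pytest.fixture(scope="session")
def medicare_crc(bench_csv):
    return load_benchmark_table(bench_csv, "crc_screening", "Medicare")


@pytest.fixture(scope="session")
def ca_bp(bench_csv):
    return load_benchmark_table(bench_csv, "bp_control", "CA-Marketplace")


@pytest.fixture(scope="session")
def marketplace_crc(bench_csv):
    return load_benchmark_table(bench_csv, "crc_screening", "Marketplace")
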
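import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def tiny_genome():
    from phagekit.sequence_io import GenomeRecord

    return GenomeRecord(id="g1", sequence="AAATGCATTT")


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text, name="test.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture
def gff_file(tmp_path):
    def _write(rows, name="test.gff3"):
        p = tmp_path / name
        lines = ["##gff-version 3"]
        lines += ["\t".join(str(x) for x in r) for r in rows]
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
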
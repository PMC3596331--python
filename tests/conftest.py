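import pytest

from xb3scan import GROUP_III_EXEMPLAR, ProteinRecord


@pytest.fixture
def exemplar_record() -> ProteinRecord:
    """A 40-residue group III RING region: ligands at 1,4,16,18,21,24,36,39."""
    return ProteinRecord(id="exemplar_III", seq=GROUP_III_EXEMPLAR)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text: str):
        path = tmp_path / "input.fasta"
        path.write_text(text)
        return path

    return _write
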
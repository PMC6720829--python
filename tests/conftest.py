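import numpy as np
import pytest

from tipin.io_formats import OntologyDag


@pytest.fixture
def chain_dag() -> OntologyDag:
    """root -> X -> Y, one namespace."""
    return OntologyDag(
        "BP", {"GO:0000001": set(), "GO:0000002": {"GO:0000001"},
               "GO:0000003": {"GO:0000002"}}
    )


@pytest.fixture
def chain_annotations() -> dict[str, frozenset[str]]:
    """Corpus of 10 proteins: 2 annotated under the leaf Y, 8 elsewhere."""
    ann = {f"L{i}": frozenset({"GO:0000003"}) for i in range(2)}
    ann.update({f"R{i}": frozenset({"GO:0000001"}) for i in range(8)})
    return ann


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def write_file(tmp_path):
    def _write(name, lines):
        p = tmp_path / name
        write_lines(p, lines)
        return p

    return _write
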
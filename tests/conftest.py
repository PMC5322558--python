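import numpy as np
import pytest

from ucekit import phylo


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tree6():
    return phylo.parse_newick(
        "(((A:0.1,B:0.15):0.05,(C:0.2,D:0.1):0.1):0.05,(E:0.3,F:0.25):0.1);"
    )


@pytest.fixture
def jc6(tree6):
    return phylo.PhyloModel(tree=tree6, kind="JC")


def make_maf_text(blocks_rows, ref_species="dm3"):
    """Build MAF text from a list of {species: (chrom, start, text)} dicts."""
    out = ["##maf version=1"]
    for rows in blocks_rows:
        out.append("")
        out.append("a score=0")
        for sp, (chrom, start, text) in rows.items():
            size = len(text) - text.count("-")
            out.append(f"s {sp}.{chrom} {start} {size} + 1000000 {text}")
    return "\n".join(out) + "\n"


@pytest.fixture
def maf_factory(tmp_path):
    def build(blocks_rows, name="test.maf"):
        path = tmp_path / name
        path.write_text(make_maf_text(blocks_rows))
        return path

    return build
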
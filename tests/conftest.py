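import pytest

from venomkit import proteome_io, synthetic
from venomkit.proteome_io import ProteinRecord, Proteome


@pytest.fixture(scope="session")
def small_design():
    return synthetic.SyntheticDesign.small(seed=7)


@pytest.fixture(scope="session")
def small_proteomes(small_design):
    return synthetic.make_proteomes(small_design)


@pytest.fixture(scope="session")
def focal_filtered(small_design, small_proteomes):
    return proteome_io.longest_isoform_filter(small_proteomes[small_design.focal])


@pytest.fixture(scope="session")
def venom_ids(small_design, focal_filtered):
    return synthetic.pick_venom_ids(small_design, focal_filtered)


@pytest.fixture
def toy_proteome():
    recs = [
        ProteinRecord("g1.t1", "g1", "sp", "MKAAAAAKRLLLLLL"),
        ProteinRecord("g1.t2", "g1", "sp", "MKAAAAAK"),
        ProteinRecord("g2.t1", "g2", "sp", "MSSSSSSR"),
    ]
    return Proteome(species_id="sp", records=recs)
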
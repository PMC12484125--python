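import pytest

from aadckit.catalog import Collection, ProteinRecord


def make_record(
    record_id="g1",
    species="Bacteroides fragilis",
    genus="Bacteroides",
    phylum="Bacteroidota",
    strain="NCTC 9343",
    ec="4.1.1.15",
    sequence="MSGHKD",
    collection=Collection.OTHER,
    complete_genome=False,
):
    return ProteinRecord(
        record_id=record_id,
        species=species,
        genus=genus,
        phylum=phylum,
        strain=strain,
        ec=ec,
        sequence=sequence,
        collection=collection,
        complete_genome=complete_genome,
    )


@pytest.fixture
def record_factory():
    return make_record
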
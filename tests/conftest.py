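import pytest

from varpharm.io_formats import ChangeType, VariantRecord, parse_variant_identifier


def make_record(
    gene="GENEX",
    variant_id="chr1:1000_A_G",
    change_type=ChangeType.MISSENSE,
    percents=None,
    **kwargs,
):
    """Construct a VariantRecord with terse defaults for tests."""
    return VariantRecord(
        gene=gene,
        locus=parse_variant_identifier(variant_id),
        change_type=change_type,
        percent_conversion=dict(percents or {}),
        **kwargs,
    )


@pytest.fixture
def panel4():
    return ["BR:MCF7", "CO:SW620", "CO:HCT116", "ME:LOXIMVI"]
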
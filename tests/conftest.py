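import pytest

from fcdbaudit.model import ComponentValue, FCDBPanel, SourceKind, ValueStatus


@pytest.fixture
def mini_panel() -> FCDBPanel:
    """One food in one database with the three value statuses, plus a second
    food/database pair, small enough to check counts by hand."""
    records = [
        ComponentValue("oilA", "db1", "SFA", ValueStatus.QUANTIFIED, 5.0, year=1979,
                       source_kind=SourceKind.DIRECT_ANALYSIS),
        ComponentValue("oilA", "db1", "MUFA", ValueStatus.ZERO_REPORTED, year=2003,
                       source_kind=SourceKind.LITERATURE),
        ComponentValue("oilA", "db1", "PUFA", ValueStatus.NOT_REPORTED),
        ComponentValue("oilA", "db2", "SFA", ValueStatus.QUANTIFIED, 4.5, year=2009),
        ComponentValue("oilB", "db1", "SFA", ValueStatus.QUANTIFIED, 12.0, year=2015),
    ]
    return FCDBPanel(records)
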
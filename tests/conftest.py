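from decimal import Decimal

import pytest

from wgcea import CostLedger, CostLineItem, load_all


@pytest.fixture(scope="session")
def trials():
    """All six packaged trials: {trial_id: (profile, reported)}."""
    return load_all()


def reconstructed_ledger(reported) -> CostLedger:
    """Two-line ledger carrying a trial's published start-up/implementation split."""
    impl = Decimal(str(reported.total_cost)) - Decimal(str(reported.startup_cost))
    return CostLedger.from_items(
        [
            CostLineItem(period=0, amount=Decimal(str(reported.startup_cost)),
                         category="staff", phase="startup"),
            CostLineItem(period=12, amount=impl, category="staff", phase="implementation"),
        ]
    )
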
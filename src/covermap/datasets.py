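"""Bundled reference datasets.

``regional_cca_ledger`` ships the published 2013-2019 regional
cover-crop acreage totals (government cost-shared and total
model-predicted acres per year) used by the demo pipeline, the
acceptance report, and the tests.  Voluntary acreage is always derived
at run time as total minus government.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .adoption import compute_voluntary


def regional_cca_ledger(with_voluntary: bool = True) -> pd.DataFrame:
    """Yearly acreage ledger (year, government_acres, total_acres
    [, voluntary_acres, negative_voluntary])."""
    ref = resources.files("covermap.data") / "regional_cca_2013_2019.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if with_voluntary:
        df = compute_voluntary(df[["year", "total_acres"]],
                               df[["year", "government_acres"]])
    return df
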
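"""Packaged reference datasets."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["seer_hl_monthly_counts", "SEER_EXCLUSION_CASCADE"]


def seer_hl_monthly_counts() -> np.ndarray:
    """Monthly Hodgkin-lymphoma diagnosis counts, SEER-18 registries, 1973–2012.

    Returns the 12 raw case counts (January..December) for the 41,405-case
    analysis cohort.  These are published aggregate counts, the only real
    registry data the package ships.
    """
    with resources.files("hlseason.data").joinpath(
        "seer_hl_monthly_counts.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return df.sort_values("month")["raw_count"].to_numpy(dtype=float)


#: Published case-selection cascade of the same cohort: starting from
#: 50,179 actively followed cases, sequential removals of death-certificate/
#: autopsy-only cases, unknown month of diagnosis, two small registries
#: (17 + 57 cases removed for low case numbers, one rule), missing age and
#: missing stage, leaving 41,405 analyzable cases.
SEER_EXCLUSION_CASCADE: tuple[int, tuple[tuple[str, int], ...]] = (
    50179,
    (
        ("dco-autopsy-only", 281),
        ("unknown-month", 257),
        ("excluded-registry(alaska-natives,rural-georgia)", 17 + 57),
        ("missing-age", 5),
        ("missing-stage", 8157),
    ),
)
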
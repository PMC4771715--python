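"""Small deterministic bench-assay calculators.

percent-of-input (ChIP-qPCR)
    The input sample is a known fraction f of the chromatin that went into
    the IP. Its Ct is first adjusted to represent 100% of input by
    subtracting log2(1/f) cycles (each doubling of template removes one
    cycle), then enrichment is 100 x 2^(adjusted input Ct - IP Ct),
    assuming amplification efficiency 2.0 per cycle (exposed as a
    parameter). Algebraically this equals 100 * f * E^(ct_input - ct_ip).

cumulative cell numbers
    Cells passaged at splitting ratio r keep 1/r of the culture each
    split, so the count at passage i underestimates growth by the product
    of all earlier split ratios. The cumulative number multiplies each
    raw count by the running product of the split ratios of the PRECEDING
    passages: C_0 = count_0, C_i = count_i * prod_{j<i} r_j. This is the
    reading under which an exponentially growing, repeatedly split culture
    yields a growing cumulative curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "QpcrRecord",
    "GrowthRecord",
    "percent_input",
    "cumulative_cell_numbers",
    "MYC_CHIP_AMPLICON",
]

#: ChIP-qPCR amplicon on the MYC promoter used as a worked-example fixture.
MYC_CHIP_AMPLICON = {
    "target": "MYC",
    "forward": "ACTCACAGGACAAGGATGCG",
    "reverse": "TGCTCCTCCGTAGCAGTACT",
}


@dataclass(frozen=True)
class QpcrRecord:
    """One ChIP-qPCR measurement: input and IP Ct for a target amplicon."""

    target: str
    ct_input: float
    ct_ip: float
    input_fraction: float  # fraction of chromatin used as input, in (0, 1]

    def __post_init__(self) -> None:
        if self.ct_input <= 0 or self.ct_ip <= 0:
            raise ValueError("Ct values must be > 0")
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GrowthRecord:
    passage: int
    count: float
    split_ratio: float  # r >= 1; cells kept each split = 1/r

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("cell count must be >= 0")
        if self.split_ratio < 1:
            raise ValueError("split ratio must be >= 1")


def percent_input(rec: QpcrRecord, efficiency: float = 2.0) -> float:
    """ChIP enrichment as percent of input, dilution-adjusted delta-Ct.

    100 * E^((ct_input - log_E(1/f)) - ct_ip) with amplification
    efficiency E (default 2.0) and input fraction f.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must be > 1")
    adjusted_input_ct = rec.ct_input - math.log(1.0 / rec.input_fraction, efficiency)
    return 100.0 * efficiency ** (adjusted_input_ct - rec.ct_ip)


def cumulative_cell_numbers(records: Sequence[GrowthRecord]) -> list[float]:
    """Expansion-corrected counts over ordered passages.

    Raises
    ------
    ValueError
        If passage indices are not strictly increasing.
    """
    for prev, cur in zip(records, records[1:]):
        if cur.passage <= prev.passage:
            raise ValueError("passage indices must be strictly increasing")
    out: list[float] = []
    expansion = 1.0
    for i, rec in enumerate(records):
        if i > 0:
            expansion *= records[i - 1].split_ratio
        out.append(rec.count * expansion)
    return out
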
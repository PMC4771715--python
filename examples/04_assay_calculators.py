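"""ChIP-qPCR percent-of-input and cumulative cell numbers."""

from cotarget import GrowthRecord, QpcrRecord, cumulative_cell_numbers, percent_input
from cotarget.assays import MYC_CHIP_AMPLICON

# the MYC promoter amplicon used in ChIP-qPCR validations
print(f"amplicon {MYC_CHIP_AMPLICON['target']}: "
      f"F {MYC_CHIP_AMPLICON['forward']} / R {MYC_CHIP_AMPLICON['reverse']}")

# 1% of chromatin kept as input; IP comes up 5 cycles after input
rec = QpcrRecord("MYC", ct_input=25.0, ct_ip=30.0, input_fraction=0.01)
print(f"percent of input: {percent_input(rec):.4f}%")
print("(= 100 x 0.01 x 2^(25-30): five extra cycles on a 1% input)")

# a culture split 1:4 at each passage
records = [GrowthRecord(0, 1.0e6, 4.0), GrowthRecord(1, 2.0e6, 4.0),
           GrowthRecord(2, 1.5e6, 4.0)]
cumulative = cumulative_cell_numbers(records)
for r, c in zip(records, cumulative):
    print(f"passage {r.passage}: counted {r.count:.2g}, cumulative {c:.2g}")
print("each count is scaled by the product of the preceding split ratios")
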
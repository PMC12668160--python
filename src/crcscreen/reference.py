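"""Published base-case CEA results for CRC screening in the Dominican Republic.

Per-person lifetime discounted costs (2024 USD) and incremental DALYs averted
for no screening (NH), biennial FIT, biennial FOBT, 10-yearly colonoscopy
(Colo), and 5-yearly sigmoidoscopy (Sig), as printed in the published
analysis these fixtures emulate.  Used as *input data* to exercise the
decision logic (frontier, dominance, WTP choice) against known results.
"""
from __future__ import annotations

#: strategy -> (lifetime cost per person USD, cumulative DALYs averted vs NH)
#: cumulative effects reconstructed from the printed incremental column:
#: FIT 0.0129; FOBT = 0.0129 - 0.0037; Colo = 0.0129 + 0.0054; Sig = 0.0183 - 0.0041
TABLE1 = {
    "NH": (73.89, 0.0),
    "FIT": (101.39, 0.0129),
    "FOBT": (106.46, 0.0092),
    "Colo": (171.43, 0.0183),
    "Sig": (177.90, 0.0142),
}

#: printed incremental (cost, DALYs averted) pairs along the frontier and the
#: ICERs the source reports for them
PRINTED_INCREMENTS = {
    "FIT": (27.50, 0.0129, 2134.74),
    "Colo": (70.04, 0.0054, 12903.51),
}

WTP_GDP_PER_CAPITA = 11_692.0
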
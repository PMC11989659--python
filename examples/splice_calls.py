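"""Apply the splice decision rules to the packaged four-variant score table.

A variant is called a splice-site loss when its maximal SpliceAI delta
score is a loss channel at >= 0.2, or when it sits inside a functional
splice site and its MaxEntScan difference is negative.  The two
near-splice variants are losses; the two deep-intronic ones show no
predicted effect.
"""

from abca4tools import (
    call_splice_effect,
    fixture_path,
    parse_cdna,
    read_splice_table,
)

table = read_splice_table(fixture_path("table2_splice.tsv"))
for key, prediction in table.items():
    offset = parse_cdna(key).intron_offset
    in_site = 0 < abs(offset) <= 20
    call = call_splice_effect(prediction, in_functional_site=in_site)
    dme = "" if call.delta_maxent is None else f"  dMaxEnt={call.delta_maxent}"
    print(f"{key:15s} delta_max={call.delta_max:.2f} "
          f"({call.dominant_channel.value}) -> {call.effect.value}{dme}")
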
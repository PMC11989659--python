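"""Convert acuity notation to logMAR and classify phenotype severity.

Severity needs at least two hits among {late onset > 15 y, better-eye
BCVA < 0.78, type-1 imaging labels} for mild, or {onset < 10 y,
BCVA > 1.0, type-3 labels} for severe; anything else is moderate.
"""

from abca4tools import better_eye, classify_severity, to_logmar

for raw in ("0.40", "FC/40cm", "HM"):
    print(f"acuity {raw!r:10s} -> logMAR {to_logmar(raw)}")

cases = [
    ("childhood onset, poor vision", 7, "1.40", "1.30", 1),
    ("late onset, preserved vision", 55, "0.40", "0.15", 3),
    ("mid onset, intermediate vision", 12, "0.90", "0.95", 2),
]
for label, onset, od, os_, af in cases:
    better = better_eye(to_logmar(od), to_logmar(os_))
    a = classify_severity(onset, better, af=af)
    print(f"{label:32s} onset={onset:2d}y better={better:.2f} AF={af} "
          f"-> class {int(a.klass)} "
          f"(mild hits {a.mild_hits}, severe hits {a.severe_hits})")
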
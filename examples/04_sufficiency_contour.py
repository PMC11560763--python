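"""Which E2F1/STAT3 expression levels suffice to trigger IL-6 secretion.

Scans E2F1 x total STAT3 over 0.1-10 a.u. (IL-6 read at 100 h) and
extracts the iso-response contour at 50% of the dynamic range: for each
STAT3 level, the least E2F1 that still reaches high secretion.
"""

import il6loop as il

system = il.monoculture("melanoma")
scan2d = il.scan_E2F1_STAT3(system, lo=0.1, hi=10.0, n=13)
R = scan2d.response
level = R.min() + 0.5 * (R.max() - R.min())
contour = il.iso_response_contour(scan2d, level)

print(f"response range {R.min():.3g} .. {R.max():.3g} a.u.; "
      f"threshold {level:.3g} a.u.\n")
print("STAT3 [a.u.]   min E2F1 for high secretion [a.u.]")
for e2f1, s_tot in contour:
    print(f"{s_tot:12.3f}   {e2f1:10.3f}")

print("\nThe contour is a trade-off curve: high secretion is reachable with")
print("high E2F1 and little STAT3, with high STAT3 and moderate E2F1, or")
print("with moderate levels of both transcription factors (the AND-gate's")
print("two Hill inputs compensate for each other).")
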
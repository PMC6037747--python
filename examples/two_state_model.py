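"""Heterosynaptic plasticity in the two-state scaffold variant.

Instead of basal/LTP/LTD scaffold states, each scaffold is either high- or
low-affinity (basal = 40% high + 60% low, chosen to match the three-state
resting synaptic population).  LTP converts low->high, LTD high->low.
LTP at PSD1+2 still depresses the non-stimulated PSD3, showing the
compensatory effect does not depend on the three-state assumption, though
its magnitude is smaller (part of the scaffold population is already
high-affinity before induction).
"""

from spinetraffic import make_protocol, run_protocol
from spinetraffic.analysis import summarize_percent_changes
from spinetraffic.protocols import WINDOW_DT1

trajs = run_protocol(make_protocol("ts_ltp_at_12"))
print("two-state model, LTP at PSD1+2, window 10-160 s:")
print(summarize_percent_changes(trajs, WINDOW_DT1).to_string(index=False))
print("\nPSD1/2 gain ~+100%; PSD3-5 show a modest compensatory loss")
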
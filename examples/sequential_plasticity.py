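"""Prior heterosynaptic depression amplifies a later LTP.

Two spines (PSD1, PSD2) receive LTP at t=10 s, which depresses their
neighbours; a third spine (PSD3) then receives LTP at t=180 s.  The percent
change of PSD3 over the posterior window (180-330 s) is compared with a
control in which PSD3 is potentiated without any prior plasticity.  The
depressed synapse starts lower and has more free scaffolds, so its relative
potentiation is larger than the control's.
"""

import numpy as np

from spinetraffic import make_protocol, run_protocol
from spinetraffic.analysis import percent_changes
from spinetraffic.protocols import WINDOW_DT1, WINDOW_DT2

seq = run_protocol(make_protocol("seq_ltp12_ltp3", n_replicates=5))
ctrl = run_protocol(make_protocol("ctrl_post_ltp3"))

prior = percent_changes(seq, 3, WINDOW_DT1)
posterior = percent_changes(seq, 3, WINDOW_DT2)
control = percent_changes(ctrl, 3, WINDOW_DT2)

print(f"PSD3 during prior LTP at PSD1+2 (10-160 s): {prior.mean():+.1f}% "
      f"(heterosynaptic depression)")
print(f"PSD3 posterior LTP (180-330 s):            {posterior.mean():+.1f}%")
print(f"PSD3 control LTP without prior plasticity: {control.mean():+.1f}%")
print("\nthe prior depression increases the later relative potentiation "
      f"by {posterior.mean() - control.mean():+.1f} percentage points")
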
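"""Estimate SSRT with the integration method (go-omission replacement).

The stop-signal reaction time is the latent latency of the stopping
process: the go-RT distribution's quantile at P(respond | stop), minus the
mean stop-signal delay.
"""

import numpy as np

from burstpipe.behavior import compute_ssrt

# worked example: 8 go RTs + 2 omissions, half of stop trials failed
go_rts = [300, 400, 500, 600, 700, 800, 900, 1000, np.nan, np.nan]
ssrt = compute_ssrt(go_rts, p_respond_given_stop=0.5, mean_ssd=200.0)
print(f"go RTs (ms): {go_rts}")
print(f"P(respond|stop) = 0.5, mean SSD = 200 ms")
print(f"SSRT = {ssrt:.0f} ms")
# Omissions are replaced by the 2000-ms deadline before sorting; the rank
# ceil(10 * 0.5) = 5 picks the 5th RT (700 ms), and 700 - 200 = 500 ms is
# the stopping latency consistent with the race model.
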
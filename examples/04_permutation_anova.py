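"""Permutation repeated-measures ANOVA on burst rates.

Builds subject x trial-type x time-bin burst-rate matrices with a known
trial-type effect, then tests it with the label-randomization null
(significant = observed F above the null 95th percentile AND p < .05).
"""

import numpy as np

from burstpipe.stats import holm_pairwise, perm_rm_anova

rng = np.random.default_rng(0)
n_subjects, n_types, n_bins = 12, 2, 5
data = rng.normal(0.3, 0.08, (n_subjects, n_types, n_bins))
data[:, 0, 2:4] += 0.15  # successful stops burst more in mid bins

res = perm_rm_anova(data, n_perm=2000, seed=1, factor_names=("trial type", "timepoint"))
print(res[["effect", "F", "eta2_partial", "p_perm", "null_f_95", "significant"]]
      .to_string(index=False))

contrasts = [
    (f"bin{b}", data[:, 0, b], data[:, 1, b]) for b in range(n_bins)
]
pw = holm_pairwise(contrasts)
print()
print(pw.to_string(index=False))
# The trial-type main effect and interaction are flagged because the
# injected 0.15 bursts/trial difference is confined to two bins; the
# Holm-corrected pairwise tests localize it to those bins.
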
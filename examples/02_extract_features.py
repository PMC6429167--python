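"""Extract the 176-dimensional feature vector from one EEG segment.

The segment is denoised by soft-threshold db5 wavelet shrinkage, split
into five subbands (delta..gamma) by an 8-level decomposition, and
summarized by time, frequency, wavelet-coefficient and nonlinear features.
"""

import numpy as np

from moodquant import CohortConfig, extract_segment_features, generate_eeg_session, segment
from moodquant.features import CATALOG

config = CohortConfig(n_subjects=1, eeg_duration_s=10.0, coupling_strength=3.0, seed=0)
rec = generate_eeg_session(
    latent_value=8.0, config=config, rng=np.random.default_rng(0)
)
seg = segment(rec, segment_len_s=10.0)[0]
fv = extract_segment_features(seg, subject_id="demo")

print(f"features extracted: {len(fv.values)}")
from collections import Counter
print("block sizes:", dict(Counter(CATALOG[n].block for n in fv.values)))
for name in ("alpha_psd", "beta_theta_rel_ratio", "denoised_sum_CD4",
             "original_min_CD6", "wavelet_entropy", "alpha_apen"):
    print(f"  {name:22s} = {fv[name]:10.4f}")
# alpha_psd is the integrated Welch power of the alpha subband (uV^2); the
# wavelet features summarize detail-coefficient layers D3..D7 of the
# denoised signal ('original_*' names are aliases of 'denoised_*').
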
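"""Phase coherence between the periodic stimulus variable and sensors.

P-cycle trials entrain responses at 3.33 Hz to p; coherence with the
aperiodic p(1-p) of the same trials is a negative control.
"""

import numpy as np

from freqtrack import (ALTERNATION_FREQ, ForwardModel, generate_session,
                       kappa_at, phase_coherence, simulate_recording,
                       stimulus_timeseries)

session = generate_session("demo", {"formal_per_condition": 10,
                                    "catch_per_condition": 0,
                                    "n_blocks": 1}, rng_seed=4)
fwd = ForwardModel(n_locations=12, srate=300.0, seed=0)
rec = simulate_recording(session, fwd, tmin=0.0, tmax=6.0,
                         conditions=[("P", "large")],
                         rng=np.random.default_rng(1))

mags = rec.magnetometer_index()
n_samp = rec.data.shape[2]
for var in ("p", "u"):
    stim = np.stack([stimulus_timeseries(session.trials[t], var, 300.0, n_samp)
                     for t in rec.trials["session_trial"]])
    freqs, kappa = phase_coherence(stim, rec.data[:, mags, :])
    k33 = kappa_at(freqs, kappa, ALTERNATION_FREQ)
    print(f"{var}: max kappa at 3.33 Hz over magnetometers = {k33.max():.3f}")

# The periodic variable (p in P-cycles) yields strong 3.33 Hz coherence at
# channels carrying its weight map; for the aperiodic p(1-p) of the same
# trials the maximum over channels stays within the range expected by
# chance for this trial count (compare coherence_permutation_test).
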
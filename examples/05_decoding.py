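"""Time-resolved decoding of the aperiodic variable and its peak latency.

The forward model injects response kernels peaking at 327 ms (p) and
419 ms (p(1-p)); lag-wise ridge decoding on PCA components recovers the
latency from the held-out reconstruction correlation.
"""

import numpy as np

from freqtrack import (ForwardModel, cluster_permutation_time,
                       estimate_peak_latency, generate_session,
                       simulate_recording, timeresolved_decode)

session = generate_session("demo", {"formal_per_condition": 10,
                                    "catch_per_condition": 0,
                                    "n_blocks": 1}, rng_seed=5)
lags = np.arange(0.0, 901.0, 25.0)
courses = []
for subj in range(4):
    fwd = ForwardModel(n_locations=8, srate=300.0, seed=subj)
    rec = simulate_recording(session, fwd, tmin=0.0, tmax=6.0,
                             conditions=[("P", "large")],
                             rng=np.random.default_rng(10 + subj))
    course = timeresolved_decode(rec, "u", lags_ms=lags, n_pca=12)
    courses.append(course.r)
    print(f"subject {subj}: max r = {course.r.max():.3f} "
          f"at {lags[np.argmax(course.r)]:.0f} ms")

res = cluster_permutation_time(np.array(courses), lags, n_perm=200, rng_seed=0)
lat = estimate_peak_latency(lags, res["t"], res["clusters"])
print(f"group peak latency (t-weighted cluster centroid): {lat:.0f} ms "
      f"(injected 419 ms)")

# Per-subject reconstruction correlations peak near the injected kernel
# latency.  The cluster centroid pools subjects with multiple-comparison
# control, but at this high signal-to-noise ratio the significant cluster
# spans most of the 100-500 ms band, pulling the centroid toward the band
# center - prefer the course peak when decoding saturates.
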
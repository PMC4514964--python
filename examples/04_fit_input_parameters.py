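"""Recover the four input-profile parameters from phospho-ERK profiles.

Generates cytoplasmic and nuclear phospho-ERK partition profiles from the
cascade model itself (known ground truth, arbitrary affine units), then
refits the four free parameters — baseline and amplitude of the Ca2+ and
plasma-membrane CaM input profiles — by bounded multi-start least squares
with nested per-species affine scaling.
"""

import numpy as np

from epiderk import CascadeParameters, fit_inputs, synth_profiles_from_model

truth = CascadeParameters()
erkc, erkn = synth_profiles_from_model(truth, gain=2.0, offset=1.0, noise_sd=0.0)

result = fit_inputs(erkc, erkn, n_starts=8, seed=0)
names = ("b_ca", "a_ca", "b_cam", "a_cam")
print(f"{'param':6s} {'true':>8s} {'fitted':>10s}")
for name in names:
    print(f"{name:6s} {getattr(truth, name):8.3f} {getattr(result, name):10.6f}")
print(f"SSE = {result.sse:.2e}, converged = {result.converged}")
print("successful starts:",
      sum(1 for _, sse, _ in result.start_results if sse < 1e-8),
      "/", len(result.start_results))
# With noise-free data the fit returns the generating parameters to ~1e-6
# and SSE ~ 0: the four input parameters are identifiable from the shape
# of the two spatial profiles alone (the affine scaling absorbs units).
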
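"""Estimate period, phase and RAE of a synthetic luminescence trace.

Generates an hourly-sampled 5-day bioluminescence trace with known
period, damping and noise, then runs FFT-NLLS on the LL48-LL120 window
and prints the estimate next to the truth.
"""

from lwdclock import TraceSpec, fft_nlls, gen_luminescence_trace

spec = TraceSpec(period=24.7, phase=5.0, amplitude=1.0, damping=0.1,
                 baseline=12.0, slope=-0.005, noise_sd=0.1, seed=7)
trace = gen_luminescence_trace(spec)

est = fft_nlls(trace.time, trace.channel("lum"), window=(48, 120))

print(f"truth:    period {spec.period:.2f} h, phase {spec.phase:.2f} h")
print(f"estimate: period {est.period:.2f} h, phase {est.phase % est.period:.2f} h, "
      f"amplitude {est.amplitude:.3f}, RAE {est.rae:.3f} -> {est.verdict}")
print(f"components kept after culling: {est.n_components}")
print("\nRAE (relative amplitude error) is the amplitude confidence "
      "half-width over the amplitude; RAE <= 1 marks a statistically "
      "rhythmic trace, and values near 0 mean a crisp rhythm.")
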
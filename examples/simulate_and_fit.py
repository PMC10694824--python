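"""Simulate a two-species photon-count histogram and recover its parameters.

Two fluorophore species share one spectral window: 8 emitters detected with
probability 0.1 each, and 10 emitters detected with probability 0.2.  A
photon-number-resolving detector only records the summed photon count per
pulse, so an intensity measurement could never tell the species apart.  The
combination-search estimator recovers both (M, p) pairs from the histogram
alone.
"""

from pnrcount import MixtureParams, SimConfig, fit_with_search, sample_histogram

truth = MixtureParams.from_flat([8, 0.1, 10, 0.2])
hist = sample_histogram(SimConfig(theta=truth, nu=10**10, seed=1))
print(f"histogram: nu={hist.nu:.0f} experiments, largest photon number N={hist.N}")

fit = fit_with_search(hist, m=2)
for j, s in enumerate(fit.theta_hat.species, start=1):
    print(f"species {j}: M={s.M} emitters, p={s.p:.5f} detection probability")
print(f"log-likelihood {fit.loglik:.1f}; {fit.seed_provenance}")
# With 1e10 pulses the integer emitter counts lock onto the truth exactly and
# the detection probabilities are recovered to ~1e-4.
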
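"""High-order synchrony versus the shuffled independent model.

Two spontaneous 73.5-s recordings (1500 frames at 20.4 Hz) of a
30-neuron circuit: one with independent background activity only, one
where shared population events recruit about half the circuit.  Each
neuron's spike train is shuffled 1000 times (spike counts preserved) to
build the independent model; mass in the 11-to-infinity order band above
the null's 97.5th percentile indicates genuine high-order synchrony.
"""

import v1sense as v

pop = v.make_uniform_population(30, seed=1)

for name, rate in (("independent", 0.0), ("population events", 0.05)):
    cfg = v.SimConfig(T=73.5, bg_rate=0.3, sync_rate=rate, sync_recruit=0.5)
    truth = v.simulate_activity(pop, None, cfg, seed=1)
    events = v.EventTrainSet(B=truth.raster(), f=cfg.f)
    obs = v.observed_sync(events)
    null = v.shuffle_null(events, n_shuffles=1000, seed=1)
    lo, hi = v.aggregate_ranges(obs.probs)
    n_lo, n_hi = null.range_percentile(97.5)
    flag = "SYNCHRONY" if hi > n_hi else "consistent with independence"
    print(f"{name:18s}: P(1-10) = {lo:.4f}   P(11-inf) = {hi:.2e} "
          f"(null 97.5%: {n_hi:.2e})  -> {flag}")
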
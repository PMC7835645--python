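"""Simulate post-arrest ECoG and recover its burst-suppression ratio.

Builds a 10-minute, 4-channel recording whose suppression probability
decays from 0.9 to 0.2 (half-life 3 min, mimicking early recovery), runs
the full quantitative-EEG chain, and compares the estimated BSR with the
simulator's ground truth.
"""

from ca_recovery.qeeg import SuppressionParams, bsr_pipeline, channel_mean_bsr
from ca_recovery.synthetic import EcogSimConfig, simulate_ecog

cfg = EcogSimConfig(
    duration=600.0,
    supp_frac_start=0.9,
    supp_frac_end=0.2,
    recovery_halflife=180.0,
    seed=7,
)
sim = simulate_ecog(cfg)
series = channel_mean_bsr(bsr_pipeline(sim.recording))
params = SuppressionParams()

print("epoch_start_s  bsr_estimate  bsr_ground_truth")
for t, bsr in zip(series.epoch_start_times, series.values[0]):
    gt = sim.state_track.suppressed_fraction(t, t + params.window_length)
    print(f"{t:12.0f}  {bsr:12.3f}  {gt:16.3f}")

# Each row is one 60 s epoch (30 s step): the estimated fraction of the
# epoch spent suppressed (channel mean) against the simulated truth.  The
# decay from ~0.9 toward ~0.2 is the recovering cortex spending more time
# bursting; estimates should track the truth to within a few percent.
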
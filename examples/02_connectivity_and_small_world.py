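"""From one subject's ROI series to network matrices and small-worldness.

Builds the four sensorimotor networks (motor/sensory x left/right) from
beta-band lagged linear coherence, then normalizes clustering and path
length by 100 surrogate random networks.
"""

from betasw import (assemble_networks, default_coupling_spec,
                    generate_roi_timeseries, small_worldness)

# a "high-fatigue-like" subject: coupling hubs in the sensory networks
spec = default_coupling_spec("high")
roi = generate_roi_timeseries(spec, duration_s=60.0, rate_hz=250.0, seed=3)

for cm in assemble_networks(roi):
    m = small_worldness(cm.W, n_surrogates=100, seed=7)
    print(f"{cm.network:8s} {cm.hemisphere:6s} "
          f"n={cm.W.shape[0]}  epochs={cm.n_epochs_used}  "
          f"Cw={m.Cw:5.2f}  Lw={m.Lw:5.2f}  Sw={m.Sw:5.2f}")
# Sw ~ 1 marks a random-like network; the sensory networks, which carry the
# planted coupling hub, show Sw clearly above 1 (locally clustered yet
# globally integrated), while the motor networks stay near 1.
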
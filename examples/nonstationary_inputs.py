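"""Drive the synapse with time-varying presynaptic inputs.

A sinusoidal input keeps the weight and activity oscillating around the
moving equilibrium (no fixed point is reached); a transient input
5 e^{-t/5} cos t decays away, after which the state spirals into the fixed
point of the input-free system -- the origin when both set-points are zero.
The weight responds about ten times more slowly than the activity
(gamma_w = gamma_mu / 10).
"""

import numpy as np

from synbm import PhaseState, PresynapticSignal, integrate, preset

initial = PhaseState(mu=5.0, w=5.0)

# nonzero set-points keep the equilibrium moving with the input, so the
# response oscillates indefinitely instead of settling
osc = integrate(initial, PresynapticSignal.sinusoidal(5.0),
                preset("table1_solid"), t_end=30.0, dt=0.01)
late = slice(int(20 / 0.01), None)
print("sinusoidal input s(t) = 5 cos t:")
print(f"  late-time activity range: [{osc.mu[late].min():+.2f}, "
      f"{osc.mu[late].max():+.2f}]  (sustained oscillation)")
print(f"  late-time weight range:   [{osc.w[late].min():+.2f}, "
      f"{osc.w[late].max():+.2f}]")

decay = integrate(initial, PresynapticSignal.transient(5.0, decay_time=5.0),
                  preset("table1_solid").replace(mu_d=0.0, w_d=0.0),
                  t_end=60.0, dt=0.01)
print("\ntransient input s(t) = 5 e^(-t/5) cos t:")
print(f"  final state (w, mu) = ({decay.final_state.w:+.4f}, "
      f"{decay.final_state.mu:+.4f})  -> approaches the origin")
print(f"  distance to origin: "
      f"{np.hypot(decay.final_state.w, decay.final_state.mu):.2e}")
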
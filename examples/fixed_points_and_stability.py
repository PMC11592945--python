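"""Equilibria of the synaptic mechanics under a constant input.

Solves the stationarity system R Psi + I = 0 for the two shipped parameter
presets at s = 5 and prints the equilibrium (w, mu), the eigenvalues of R
and the stability of the state block.  The momenta vanish at equilibrium,
so (w_eq, mu_eq) is where the weight/activity spiral ends up.
"""

from synbm import fixed_point, preset, spectrum

for name in ("table1_solid", "table1_dotted"):
    params = preset(name)
    report = fixed_point(5.0, params)
    eigs, label = spectrum(5.0, params)
    print(f"{name} (hebbian_sign={params.hebbian_sign:+d}):")
    print(f"  equilibrium (w, mu) = ({report.state.w:.4f}, {report.state.mu:.4f})"
          f"  -> rounds to ({report.state.w:.1f}, {report.state.mu:.1f})")
    print(f"  stability: {report.stability}  (state-block eigenvalues "
          f"{eigs[0]:.3f}, {eigs[1]:.3f})")
    print(f"  trace residual of R: {report.trace_residual:.1e} (exactly 0 in theory)")

# Flipping to the Hebbian sign turns the spiral into a saddle: co-activity
# then feeds back positively and the strong input s=5 overwhelms the damping.
hebbian = preset("table1_solid").replace(hebbian_sign=1)
print(f"\nHebbian variant stability: {fixed_point(5.0, hebbian).stability}")
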
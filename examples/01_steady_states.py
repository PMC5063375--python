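"""Solve GMA steady states: the closed-form toy chain and a deficiency.

A GMA network's steady state solves N v(x, alpha) + B u = 0 with power-law
rates v_k = alpha_k * prod x_l**g_kl.  The toy chain has the analytic
solution x = ((a1/a2)^2, (a1/a3)^2), so we can see the solver hit it exactly,
then watch a 50% "deficiency" of the influx reaction shift the state.
"""

from fmdd import apply_deficiency, fold_changes, solve_steady_state, toy_network

net = toy_network()
healthy = solve_steady_state(net)
print("healthy steady state:", healthy.x, f"(residual {healthy.residual_norm:.1e})")

sick = solve_steady_state(net, apply_deficiency(net, "v1", 50.0))
xf, vf = fold_changes(sick, healthy)
print("after 50% deficiency of v1:", sick.x)
print("concentration folds vs healthy:", xf)

# both pools drop to 0.25x: halving the influx activity quarters each pool
# because the transfer and efflux rates scale with sqrt(concentration).
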
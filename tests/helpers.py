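from ssipkit.ssimple import make_phase_state, solve_speciation


def make_state(epsilons, theta, temperature=298.0, solve=True):
    """Assemble (and optionally solve) an idealised phase from raw arrays."""
    state = make_phase_state(epsilons, theta, temperature)
    if solve:
        solve_speciation(state)
    return state
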
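"""End-to-end cooperativity-ratio benchmarks on simulated patches.

These drive the whole chain — Gillespie gating simulation, trace
rendering with noise and 50 Hz filtering, half-amplitude idealization
with dead-time imposition, time-fraction level occupancies, and the
two-channel cooperativity ratio — under fixed study conditions:
600 s records sampled at 1 kHz, unitary current -1 pA (20 pS at
-50 mV), 0.15 pA noise, 4 ms event exclusion.
"""

from __future__ import annotations

from .binomial import cooperativity_ratio
from .channels import PatchSpec, simulate_patch, two_state_scheme
from .idealize import detect_events, exclude_brief_events

__all__ = ["cr_from_two_channel_simulation",
           "cr_identical_channels", "cr_unequal_channels"]

_CONDITIONS = dict(duration_s=600.0, sampling_rate_hz=1000.0,
                   noise_sd_pa=0.15, filter_cutoff_hz=50.0,
                   holding_mv=-50.0)
_CONDUCTANCE_PS = 20.0          # -1 pA unitary current at -50 mV
_EXCLUDE_MS = 4.0


def cr_from_two_channel_simulation(rates, seed: int) -> dict:
    """Simulate two independent two-state channels and measure their CR.

    ``rates`` is a pair of (k_open, k_close) tuples in 1/s.  Returns the
    measured level occupancies, the CR, and the record size.
    """
    channels = [(two_state_scheme(ko, kc, conductance_ps=_CONDUCTANCE_PS), 1)
                for ko, kc in rates]
    spec = PatchSpec(channels=channels, seed=seed, **_CONDITIONS)
    trace, truths = simulate_patch(spec)
    i_pa = channels[0][0].unitary_current_pa(spec.holding_mv)
    events = detect_events(trace.current_pa, spec.sampling_rate_hz,
                           baseline_pa=0.0, level_amplitude_pa=i_pa,
                           n_levels=2)
    events = exclude_brief_events(events, _EXCLUDE_MS)
    occ = events.level_occupancies(2)
    return {"occupancies": occ,
            "cr": cooperativity_ratio(occ[0], occ[1], occ[2], n=2),
            "true_po": [t.true_po for t in truths],
            "n_samples": trace.n_samples,
            "duration_s": spec.duration_s}


def cr_identical_channels(seed: int) -> dict:
    """CR benchmark: two identical channels, k_open 4/s, k_close 6/s."""
    return cr_from_two_channel_simulation([(4.0, 6.0), (4.0, 6.0)], seed)


def cr_unequal_channels(seed: int) -> dict:
    """CR benchmark: stationary open probabilities 0.15 and 0.50."""
    return cr_from_two_channel_simulation([(1.5, 8.5), (5.0, 5.0)], seed)
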
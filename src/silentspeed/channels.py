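"""Continuous-time Markov simulation of ligand-gated channel gating.

This module generates ground-truth single-channel activity: a kinetic
scheme (:class:`GatingScheme`) is simulated by exact stochastic jumps
(Gillespie), and one or more independent channels are rendered into a
noisy current trace the way an excised inside-out patch recording would
appear.  PKA-activated CFTR-like behaviour — bursts of openings broken by
brief flickery closures and separated by long interburst closures — is
reproduced by the default three-state linear scheme

    C_interburst  <->  O  <->  C_flicker

whose rates are configurable.  The simulated trajectory (dwell sequence,
stationary open probability, unitary current) is retained as
:class:`GroundTruth`, the oracle for every downstream recovery test.

Sign conventions follow the recording configuration: with a large
inside-high chloride gradient and the voltage clamped negative, channel
openings are downward (negative) current deflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .errors import ValidationError

__all__ = [
    "GatingScheme",
    "PatchSpec",
    "GroundTruth",
    "Trace",
    "two_state_scheme",
    "default_bursting_scheme",
    "nernst_potential_mv",
    "stationary_distribution",
    "simulate_dwells",
    "render_trace",
    "simulate_patch",
    "make_two_population_patch",
]

#: Gas constant R * T / F at 37 degC in mV (R=8.314 J/mol/K, F=96485 C/mol).
_RT_F_37C_MV = 8.314 * 310.15 / 96485.0 * 1000.0


def nernst_potential_mv(conc_out_mm: float, conc_in_mm: float, z: int = -1,
                        temperature_c: float = 37.0) -> float:
    """Nernst equilibrium potential in mV for an ion of valence ``z``.

    For the chloride gradient used in CFTR patch recordings
    (external 10 mM, internal 147 mM, 37 degC) this evaluates to about
    +71.8 mV.  The simulator treats the reversal potential as a plain
    configuration value; this helper only documents the physics.
    """
    if conc_out_mm <= 0 or conc_in_mm <= 0:
        raise ValidationError("concentrations must be positive")
    rt_f = 8.314 * (temperature_c + 273.15) / 96485.0 * 1000.0
    return rt_f / z * float(np.log(conc_out_mm / conc_in_mm))


@dataclass(frozen=True)
class GatingScheme:
    """A kinetic scheme: states, generator matrix, and unitary conductance.

    Parameters
    ----------
    state_labels
        Names of the kinetic states.
    rate_matrix
        Square generator matrix Q in 1/s.  Off-diagonals are transition
        rates (>= 0); each diagonal equals minus its row's off-diagonal
        sum.  Rows therefore sum to zero.
    conducting
        Labels of the states that carry current.  At least one state must
        conduct and at least one must not.
    conductance_ps
        Single-channel (unitary) conductance gamma, pS.
    reversal_mv
        Reversal potential of the conducted ion, mV.
    """

    state_labels: tuple
    rate_matrix: np.ndarray
    conducting: tuple
    conductance_ps: float
    reversal_mv: float = 0.0

    def __post_init__(self):
        labels = tuple(self.state_labels)
        object.__setattr__(self, "state_labels", labels)
        q = np.asarray(self.rate_matrix, dtype=float)
        object.__setattr__(self, "rate_matrix", q)
        cond = tuple(self.conducting)
        object.__setattr__(self, "conducting", cond)
        n = len(labels)
        if q.shape != (n, n):
            raise ValidationError(f"rate_matrix must be {n}x{n}, got {q.shape}")
        off = q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValidationError("off-diagonal rates must be >= 0")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-9):
            raise ValidationError("rate_matrix rows must sum to 0")
        if self.conductance_ps <= 0:
            raise ValidationError("conductance must be positive")
        unknown = set(cond) - set(labels)
        if unknown:
            raise ValidationError(f"conducting states not in scheme: {unknown}")
        if not cond or len(cond) == n:
            raise ValidationError(
                "scheme needs at least one conducting and one non-conducting state")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def conducting_mask(self) -> np.ndarray:
        return np.array([s in self.conducting for s in self.state_labels])

    def unitary_current_pa(self, holding_mv: float) -> float:
        """Open-channel current i = gamma * (V_hold - V_rev), in pA."""
        return self.conductance_ps * (holding_mv - self.reversal_mv) * 1e-3


def two_state_scheme(k_open: float, k_close: float,
                     conductance_ps: float = 20.0,
                     reversal_mv: float = 0.0) -> GatingScheme:
    """Minimal C <-> O scheme with stationary P_o = k_open/(k_open+k_close)."""
    if k_open < 0 or k_close < 0:
        raise ValidationError("rates must be non-negative")
    q = np.array([[-k_open, k_open], [k_close, -k_close]], float)
    return GatingScheme(("closed", "open"), q, ("open",),
                        conductance_ps, reversal_mv)


def default_bursting_scheme(k_ib_open: float = 1.0, k_open_ib: float = 2.0,
                            k_open_f: float = 10.0, k_f_open: float = 100.0,
                            conductance_ps: float = 20.0,
                            reversal_mv: float = 0.0) -> GatingScheme:
    """Three-state chain C_interburst <-> O <-> C_flicker.

    Defaults give ~1 s interburst closures, bursts of a few openings of
    ~80 ms each, and ~10 ms flickery closures — the bursting phenotype of
    PKA-phosphorylated CFTR.
    """
    q = np.array([
        [-k_ib_open, k_ib_open, 0.0],
        [k_open_ib, -(k_open_ib + k_open_f), k_open_f],
        [0.0, k_f_open, -k_f_open],
    ])
    return GatingScheme(("closed_interburst", "open", "closed_flicker"),
                        q, ("open",), conductance_ps, reversal_mv)


def stationary_distribution(scheme: GatingScheme) -> np.ndarray:
    """Stationary distribution pi with pi @ Q = 0, sum(pi) = 1."""
    ns = null_space(scheme.rate_matrix.T)
    if ns.shape[1] == 0:
        raise ValidationError("rate matrix has no stationary distribution")
    pi = np.abs(ns[:, 0])
    return pi / pi.sum()


@dataclass
class GroundTruth:
    """The simulated truth for one channel: dwell sequence and summaries."""

    scheme: GatingScheme
    states: np.ndarray          # state index per dwell
    durations_s: np.ndarray     # dwell durations, sum to requested duration
    truncated_last: bool        # final dwell cut at the record end
    true_current_pa: float = 0.0

    @property
    def duration_s(self) -> float:
        return float(self.durations_s.sum())

    @property
    def open_mask(self) -> np.ndarray:
        return self.scheme.conducting_mask[self.states]

    @property
    def true_po(self) -> float:
        """Realized open probability: conducting time / total time."""
        return float(self.durations_s[self.open_mask].sum() / self.duration_s)

    def open_indicator(self, times_s: np.ndarray) -> np.ndarray:
        """1 where the channel conducts at each queried time."""
        edges = np.cumsum(self.durations_s)
        idx = np.searchsorted(edges, times_s, side="right")
        idx = np.minimum(idx, len(self.states) - 1)
        return self.open_mask[idx].astype(float)


@dataclass
class PatchSpec:
    """Configuration of one simulated membrane patch.

    ``channels`` is a list of (GatingScheme, count) pairs; the total count
    must be between 1 and 5, mirroring the experimental practice of only
    analysing patches with at most five active channels.
    """

    channels: list
    holding_mv: float = -50.0
    sampling_rate_hz: float = 1000.0
    duration_s: float = 60.0
    noise_sd_pa: float = 0.15
    filter_cutoff_hz: float | None = None
    seed: int = 0

    def __post_init__(self):
        total = sum(int(c) for _, c in self.channels)
        if not (1 <= total <= 5):
            raise ValidationError(f"total channel count must be in [1, 5], got {total}")
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.noise_sd_pa < 0:
            raise ValidationError("noise SD must be non-negative")
        if (self.filter_cutoff_hz is not None
                and self.sampling_rate_hz <= 2 * self.filter_cutoff_hz):
            raise ValidationError("sampling_rate must exceed 2 x filter_cutoff")

    @property
    def n_channels(self) -> int:
        return sum(int(c) for _, c in self.channels)


@dataclass
class Trace:
    """A sampled current record with its acquisition metadata."""

    current_pa: np.ndarray
    sampling_rate_hz: float
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.current_pa)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


def simulate_dwells(scheme: GatingScheme, duration_s: float,
                    seed=None) -> GroundTruth:
    """Exact-jump (Gillespie) trajectory of one channel.

    The initial state is drawn from the stationary distribution, holding
    times are exponential with the state's exit rate, and the final dwell
    is truncated at ``duration_s`` (and flagged), so dwell durations sum
    exactly to the requested record length.  An absorbing state yields a
    single dwell spanning the remainder of the record.
    """
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(seed)
    q = scheme.rate_matrix
    exit_rates = -np.diag(q)
    jump_probs = []
    for i in range(scheme.n_states):
        if exit_rates[i] > 0:
            jump_probs.append(q[i] / exit_rates[i])
        else:
            jump_probs.append(None)   # absorbing

    pi = stationary_distribution(scheme)
    state = int(rng.choice(scheme.n_states, p=pi))
    states, durations = [], []
    t = 0.0
    truncated = False
    while t < duration_s:
        if exit_rates[state] <= 0:
            dwell = duration_s - t
        else:
            dwell = rng.exponential(1.0 / exit_rates[state])
        if t + dwell >= duration_s:
            dwell = duration_s - t
            truncated = True
            states.append(state)
            durations.append(dwell)
            break
        states.append(state)
        durations.append(dwell)
        t += dwell
        p = jump_probs[state].copy()
        p[state] = 0.0
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        state = int(rng.choice(scheme.n_states, p=p))
    return GroundTruth(scheme, np.array(states), np.array(durations), truncated)


def render_trace(spec: PatchSpec, truths: list[GroundTruth],
                 seed=None) -> Trace:
    """Render channel trajectories into one noisy current trace.

    Per sample, current = sum over open channels of the unitary current
    i = gamma * (V_hold - V_rev), plus white Gaussian noise; an optional
    zero-phase Gaussian low-pass is applied after the noise, as a
    recording filter would act on the summed signal.
    """
    for gt in truths:
        if gt.duration_s < spec.duration_s - 1e-9:
            raise ValidationError("trajectory does not cover the patch duration")
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    t = (np.arange(n) + 0.5) / spec.sampling_rate_hz
    current = np.zeros(n)
    for gt in truths:
        i_pa = gt.scheme.unitary_current_pa(spec.holding_mv)
        gt.true_current_pa = i_pa
        current += i_pa * gt.open_indicator(t)
    if spec.noise_sd_pa > 0:
        current += rng.normal(0.0, spec.noise_sd_pa, n)
    if spec.filter_cutoff_hz is not None:
        from .idealize import lowpass_filter
        current = lowpass_filter(current, spec.sampling_rate_hz,
                                 spec.filter_cutoff_hz)
    meta = {
        "sampling_rate_hz": spec.sampling_rate_hz,
        "holding_mv": spec.holding_mv,
        "noise_sd_pa": spec.noise_sd_pa,
        "filter_cutoff_hz": spec.filter_cutoff_hz,
        "n_channels": spec.n_channels,
        "seed": spec.seed,
    }
    return Trace(current, spec.sampling_rate_hz, meta)


def simulate_patch(spec: PatchSpec) -> tuple[Trace, list[GroundTruth]]:
    """Simulate every channel in the patch and render the combined trace.

    The patch seed is expanded into independent per-channel substreams so
    channels are statistically independent and the run is reproducible.
    """
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.n_channels + 1)
    truths = []
    k = 0
    for scheme, count in spec.channels:
        for _ in range(int(count)):
            truths.append(simulate_dwells(scheme, spec.duration_s,
                                          np.random.default_rng(child_seeds[k])))
            k += 1
    trace = render_trace(spec, truths, np.random.default_rng(child_seeds[-1]))
    return trace, truths


def make_two_population_patch(wtl_scheme: GatingScheme, sc_scheme: GatingScheme,
                              spec_kwargs: dict | None = None,
                              sc_conductance_fraction: float = 0.5,
                              coupled: bool = False,
                              seed: int = 0) -> tuple[Trace, list[GroundTruth], PatchSpec]:
    """One wild-type-like and one small-conductance channel in one patch.

    The sc channel's conductance is forced to ``sc_conductance_fraction``
    of the wtl conductance (default 0.5 — the sc population's conductance
    is about half the wild-type's).  By default the channels gate
    independently; with ``coupled=True`` both channels share the same
    gating trajectory (a deliberately non-independent control used to
    exercise the cooperativity analysis).
    """
    if not (0 < sc_conductance_fraction <= 1):
        raise ValidationError("sc conductance fraction must be in (0, 1]")
    sc_scheme = GatingScheme(
        sc_scheme.state_labels, sc_scheme.rate_matrix, sc_scheme.conducting,
        wtl_scheme.conductance_ps * sc_conductance_fraction,
        sc_scheme.reversal_mv)
    spec = PatchSpec(channels=[(sc_scheme, 1), (wtl_scheme, 1)], seed=seed,
                     **(spec_kwargs or {}))
    if not coupled:
        trace, truths = simulate_patch(spec)
        return trace, truths, spec
    # coupled mode: one trajectory drives both conductance levels
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(2)
    gt = simulate_dwells(wtl_scheme, spec.duration_s, np.random.default_rng(kids[0]))
    gt_sc = GroundTruth(sc_scheme, gt.states.copy(), gt.durations_s.copy(),
                        gt.truncated_last)
    trace = render_trace(spec, [gt_sc, gt], np.random.default_rng(kids[1]))
    return trace, [gt_sc, gt], spec
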
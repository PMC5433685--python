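import numpy as np
import pandas as pd
import pytest

from silentspeed.channels import (PatchSpec, default_bursting_scheme,
                                  simulate_patch, two_state_scheme)
from silentspeed.footprints import (SENSE_CODONS, FootprintSpec,
                                    generate_footprints, random_transcripts)
from silentspeed.idealize import (IdealizedEvents, detect_events,
                                  exclude_brief_events)


def make_events(levels, durations_s, **kw):
    """Hand-built event list for worked examples."""
    levels = np.asarray(levels)
    durations = np.asarray(durations_s, float)
    starts = np.concatenate(([0.0], np.cumsum(durations[:-1])))
    defaults = dict(baseline_pa=0.0, level_currents_pa=np.array([-1.0]))
    defaults.update(kw)
    return IdealizedEvents(levels, starts, durations, **defaults)


def truth_events(truth):
    """Ground-truth dwell sequence as an open/closed event list."""
    levels, durations = [], []
    for lvl, dur in zip(truth.open_mask.astype(int), truth.durations_s):
        if levels and levels[-1] == lvl:
            durations[-1] += dur
        else:
            levels.append(int(lvl))
            durations.append(float(dur))
    durs = np.array(durations)
    starts = np.concatenate(([0.0], np.cumsum(durs[:-1])))
    return IdealizedEvents(np.array(levels), starts, durs, 0.0,
                           np.array([-1.0]))


@pytest.fixture(scope="session")
def bursting_patch():
    """One simulated bursting channel: (trace, ground truth, spec)."""
    scheme = default_bursting_scheme(conductance_ps=20.0)
    spec = PatchSpec(channels=[(scheme, 1)], holding_mv=-50.0,
                     sampling_rate_hz=2000.0, duration_s=200.0,
                     noise_sd_pa=0.1, filter_cutoff_hz=100.0, seed=11)
    trace, truths = simulate_patch(spec)
    return trace, truths[0], spec


@pytest.fixture(scope="session")
def bursting_events(bursting_patch):
    trace, truth, spec = bursting_patch
    i_pa = truth.scheme.unitary_current_pa(spec.holding_mv)
    events = detect_events(trace.current_pa, spec.sampling_rate_hz,
                           baseline_pa=0.0, level_amplitude_pa=i_pa,
                           n_levels=1)
    return exclude_brief_events(events, 1.0)


@pytest.fixture(scope="session")
def two_channel_events():
    """Two identical independent two-state channels, idealized at 2 levels."""
    scheme = two_state_scheme(4.0, 6.0, conductance_ps=20.0)
    spec = PatchSpec(channels=[(scheme, 2)], holding_mv=-50.0,
                     sampling_rate_hz=1000.0, duration_s=400.0,
                     noise_sd_pa=0.15, filter_cutoff_hz=50.0, seed=21)
    trace, truths = simulate_patch(spec)
    events = detect_events(trace.current_pa, spec.sampling_rate_hz,
                           baseline_pa=0.0, level_amplitude_pa=-1.0,
                           n_levels=2)
    return exclude_brief_events(events, 4.0), truths


@pytest.fixture(scope="session")
def footprint_dataset():
    """10 genes x 300 codons, known dwell weights, 1e5 reads."""
    transcripts = random_transcripts(10, 300, seed=3)
    rng = np.random.default_rng(5)
    weights = {c: float(rng.lognormal(0.0, 0.4)) for c in SENSE_CODONS}
    spec = FootprintSpec(transcripts, weights, total_reads=100_000, seed=7)
    alignments, report = generate_footprints(spec)
    cds = pd.DataFrame(
        [(t.transcript_id, t.cds_start, t.cds_end) for t in transcripts],
        columns=["transcript_id", "cds_start", "cds_end"])
    return {"transcripts": transcripts, "weights": weights, "spec": spec,
            "alignments": alignments, "report": report, "cds": cds}
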
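"""Readers, writers, run configuration, and the umbrella pipeline.

Tabular files are TSV with '#'-prefixed header comment lines carrying
explicit units; every trace and event file has a JSON metadata sidecar
(<file>.json) recording the parameters that produced it.  Alignments
are accepted as BED-like TSV or SAM in transcript space (forward strand
only); transcripts as FASTA plus a TSV CDS table with 0-based half-open
coordinates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .channels import PatchSpec, Trace, default_bursting_scheme, simulate_patch
from .errors import ValidationError
from .footprints import Transcript
from .idealize import IdealizedEvents, detect_events, exclude_brief_events
from .kinetics import (burst_metrics, determine_tc, fit_exp_mixture,
                       segment_bursts)

__all__ = ["read_trace", "write_trace", "read_events", "write_events",
           "read_alignments", "write_alignments_bed", "write_alignments_sam",
           "read_fasta", "read_cds_table", "write_cds_table",
           "RunConfig", "read_config", "run_pipeline"]

log = logging.getLogger("silentspeed")


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_trace(path, trace: Trace) -> None:
    """Two-column TSV (time_s, current_pA) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s, "current_pA": trace.current_pa})
    with open(path, "w") as fh:
        fh.write("# time_s\tcurrent_pA\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.9g")
    _sidecar(path).write_text(json.dumps(
        {"sampling_rate_hz": trace.sampling_rate_hz, **trace.meta}, indent=1))


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["time_s", "current_pA"])
    if df.empty:
        raise ValidationError(f"{path}: empty trace file")
    meta = {}
    rate = None
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
        rate = meta.get("sampling_rate_hz")
    if rate is None:
        dt = np.diff(df["time_s"].to_numpy()[:2])
        if len(dt) == 0 or dt[0] <= 0:
            raise ValidationError(f"{path}: cannot infer sampling rate")
        rate = 1.0 / float(dt[0])
    return Trace(df["current_pA"].to_numpy(float), float(rate), meta)


def write_events(path, events: IdealizedEvents) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# level\tstart_s\tduration_s\n")
        pd.DataFrame({"level": events.levels, "start_s": events.starts_s,
                      "duration_s": events.durations_s}).to_csv(
            fh, sep="\t", header=False, index=False, float_format="%.9g")
    _sidecar(path).write_text(json.dumps({
        "baseline_pa": events.baseline_pa,
        "level_currents_pa": list(map(float, events.level_currents_pa)),
        "exclusion_ms": events.exclusion_ms, **events.meta}, indent=1))


def read_events(path) -> IdealizedEvents:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["level", "start_s", "duration_s"])
    if df.empty:
        raise ValidationError(f"{path}: empty event file")
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return IdealizedEvents(
        levels=df["level"].to_numpy(int),
        starts_s=df["start_s"].to_numpy(float),
        durations_s=df["duration_s"].to_numpy(float),
        baseline_pa=meta.get("baseline_pa", 0.0),
        level_currents_pa=np.asarray(meta.get("level_currents_pa", [1.0])),
        exclusion_ms=meta.get("exclusion_ms", 0.0), meta=meta)


_BED_COLS = ["transcript", "start", "end", "name", "length", "strand"]


def read_alignments(path) -> pd.DataFrame:
    """Footprint alignments from BED-like TSV or SAM (by extension).

    BED records are validated (end > start, start >= 0) with offending
    line numbers reported.  SAM input must carry transcript-space
    references; only forward-strand, mapped reads are taken and read
    length comes from the query sequence length.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        import pysam
        rows = []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_reverse:
                    continue
                L = rec.query_length or rec.infer_read_length()
                rows.append((rec.reference_name, rec.reference_start,
                             rec.reference_start + L, rec.query_name, L, "+"))
        return pd.DataFrame(rows, columns=_BED_COLS)
    df = pd.read_csv(path, sep="\t", comment="#", names=_BED_COLS,
                     dtype={"transcript": str, "name": str, "strand": str})
    if df[["start", "end"]].isna().any().any():
        raise ValidationError(f"{path}: missing start/end columns")
    bad = df.index[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        raise ValidationError(
            f"{path}: invalid interval at line {int(bad[0]) + 1} "
            f"(end <= start or start < 0)")
    df["length"] = df["length"].fillna(df["end"] - df["start"]).astype(int)
    return df


def write_alignments_bed(path, alignments: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# transcript\tstart\tend\tname\tlength_nt\tstrand\n")
        alignments[_BED_COLS].to_csv(fh, sep="\t", header=False, index=False)


def write_alignments_sam(path, alignments: pd.DataFrame,
                         transcripts) -> None:
    """Emit alignments as transcript-space SAM (for cross-format checks)."""
    import pysam
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": t.transcript_id, "LN": len(t.sequence)}
                     for t in transcripts]}
    seq_by_id = {t.transcript_id: t.sequence for t in transcripts}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for row in alignments.itertuples():
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.name
            a.reference_name = row.transcript
            a.reference_start = int(row.start)
            a.mapping_quality = 255
            L = int(row.length)
            a.cigarstring = f"{L}M"
            a.query_sequence = seq_by_id[row.transcript][row.start:row.start + L]
            a.flag = 0
            out.write(a)


def read_fasta(path) -> dict:
    """FASTA -> {id: sequence} (uppercased)."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValidationError(f"{path}: no FASTA records")
    return seqs


def read_cds_table(path, fasta: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["transcript_id", "cds_start", "cds_end"])
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing columns in CDS table")
    if fasta is not None:
        for row in df.itertuples():
            if row.transcript_id not in fasta:
                raise ValidationError(
                    f"CDS table names unknown transcript {row.transcript_id!r}")
            if not 0 <= row.cds_start < row.cds_end <= len(fasta[row.transcript_id]):
                raise ValidationError(
                    f"{row.transcript_id}: CDS coordinates out of bounds")
    return df


def write_cds_table(path, transcripts) -> None:
    with open(path, "w") as fh:
        fh.write("# transcript_id\tcds_start\tcds_end\n")
        for t in transcripts:
            fh.write(f"{t.transcript_id}\t{t.cds_start}\t{t.cds_end}\n")


def transcripts_from_files(fasta_path, cds_path) -> list[Transcript]:
    fasta = read_fasta(fasta_path)
    cds = read_cds_table(cds_path, fasta)
    return [Transcript(r.transcript_id, fasta[r.transcript_id],
                       int(r.cds_start), int(r.cds_end))
            for r in cds.itertuples()]


# ---------------------------------------------------------------------------
# run configuration and pipeline

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level",
    # simulate stage
    "duration_s", "sampling_rate_hz", "noise_sd_pa", "holding_mv",
    "conductance_ps", "reversal_mv", "filter_cutoff_hz",
    "k_ib_open", "k_open_ib", "k_open_f", "k_f_open",
    # idealize stage
    "exclude_ms", "n_levels",
    # kinetics stage
    "tc_ms", "dwell_censor_ms",
}


@dataclass
class RunConfig:
    """Parameters of a simulate -> idealize -> kinetics run.

    Unknown keys are rejected; every parameter is echoed into the run's
    metadata so outputs are self-describing.
    """

    seed: int = 0
    out_dir: str = "run"
    log_level: str = "INFO"
    duration_s: float = 120.0
    sampling_rate_hz: float = 2000.0
    noise_sd_pa: float = 0.1
    holding_mv: float = -50.0
    conductance_ps: float = 20.0
    reversal_mv: float = 0.0
    filter_cutoff_hz: float | None = 100.0
    k_ib_open: float = 1.0
    k_open_ib: float = 2.0
    k_open_f: float = 10.0
    k_f_open: float = 100.0
    exclude_ms: float = 1.0
    n_levels: int = 1
    tc_ms: float | None = None         # None -> determined from closed fit
    dwell_censor_ms: float = 1.0

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths and logging excluded)."""
        d = {k: v for k, v in asdict(self).items()
             if k not in ("out_dir", "log_level")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Simulate a patch, idealize it, and summarize its burst kinetics.

    Writes trace.tsv, events.tsv, metrics.json, config.json and run.log
    into the run directory; metrics carry the config hash and seed so a
    rerun with the same config is bit-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        log.info("config hash %s seed %d", config.config_hash(), config.seed)
        scheme = default_bursting_scheme(
            config.k_ib_open, config.k_open_ib, config.k_open_f,
            config.k_f_open, config.conductance_ps, config.reversal_mv)
        spec = PatchSpec(channels=[(scheme, 1)], holding_mv=config.holding_mv,
                         sampling_rate_hz=config.sampling_rate_hz,
                         duration_s=config.duration_s,
                         noise_sd_pa=config.noise_sd_pa,
                         filter_cutoff_hz=config.filter_cutoff_hz,
                         seed=config.seed)
        trace, truths = simulate_patch(spec)
        write_trace(out / "trace.tsv", trace)
        i_pa = scheme.unitary_current_pa(config.holding_mv)
        events = detect_events(trace.current_pa, trace.sampling_rate_hz,
                               baseline_pa=0.0, level_amplitude_pa=i_pa,
                               n_levels=config.n_levels)
        events = exclude_brief_events(events, config.exclude_ms)
        write_events(out / "events.tsv", events)
        log.info("idealized %d events, exclusion %.3g ms",
                 events.n_events, config.exclude_ms)
        closed_fit = fit_exp_mixture(events.dwells_ms(False), 2,
                                     censor_ms=config.dwell_censor_ms)
        tc = config.tc_ms if config.tc_ms is not None else determine_tc(closed_fit)
        bursts = segment_bursts(events, tc)
        metrics = burst_metrics(events, bursts, tc)
        log.info("t_c %.3g ms (%s), %d bursts", tc,
                 "configured" if config.tc_ms is not None else "closed-fit crossing",
                 metrics.n_bursts)
        payload = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "true_po": truths[0].true_po,
            "closed_fit": {"taus_ms": closed_fit.taus_ms.tolist(),
                           "amplitudes": closed_fit.amplitudes.tolist(),
                           "log_likelihood": closed_fit.log_likelihood},
            "tc_ms": tc,
            "tc_criterion": "equal-density crossing of closed-time components",
            "metrics": asdict(metrics),
        }
        (out / "metrics.json").write_text(json.dumps(payload, indent=1))
        (out / "config.json").write_text(json.dumps(asdict(config), indent=1))
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
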
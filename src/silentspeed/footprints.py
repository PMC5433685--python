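"""Synthetic ribosome-protected-fragment (RPF) generator.

Footprints are drawn codon-by-codon: the probability that a read's
A site sits on a given codon position is proportional to that codon's
relative dwell weight (slowly translated codons accumulate more
footprints).  Read lengths follow a configurable distribution over
27-29 nt, and the 5' end of each read is placed at

    (middle nucleotide of the A-site codon) - offset(read length)

with per-length offsets, the exact geometry the 5'-end calibration
stage must recover.  An elevated weight at the second codon (the A site
when the P site covers the start codon) emulates the initiation peak of
harringtonine-treated cells that start-codon metagene calibration
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["Transcript", "FootprintSpec", "generate_footprints",
           "random_transcripts", "SENSE_CODONS", "STOP_CODONS"]

_BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES
                     if a + b + c not in STOP_CODONS)


@dataclass(frozen=True)
class Transcript:
    """A transcript with CDS coordinates (0-based, half-open)."""

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValidationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length must be divisible by 3")

    @property
    def codons(self) -> list[str]:
        cds = self.sequence[self.cds_start:self.cds_end]
        return [cds[i:i + 3] for i in range(0, len(cds), 3)]

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3


@dataclass
class FootprintSpec:
    """Ground-truth recipe for a synthetic RPF alignment table.

    ``dwell_weights`` maps codon -> relative dwell (dimensionless; only
    ratios matter).  ``length_probs`` maps read length -> probability;
    ``offsets`` maps read length -> distance (nt) from the read 5' end
    to the middle nucleotide of the A-site codon.  ``init_peak_weight``
    multiplies the dwell weight of codon index 1 (the initiation A site)
    to produce a start-codon metagene peak; set to 1 to disable.
    """

    transcripts: list
    dwell_weights: dict
    total_reads: int
    length_probs: dict = field(default_factory=lambda: {27: 0.25, 28: 0.5, 29: 0.25})
    offsets: dict = field(default_factory=lambda: {27: 15, 28: 16, 29: 16})
    init_peak_weight: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.total_reads < 0:
            raise ValidationError("total_reads must be >= 0")
        if any(w <= 0 for w in self.dwell_weights.values()):
            raise ValidationError("dwell weights must be positive")
        for length, p in self.length_probs.items():
            if not 20 <= length <= 40:
                raise ValidationError("read lengths must lie within 20-40 nt")
            if p < 0:
                raise ValidationError("length probabilities must be >= 0")
        for length, off in self.offsets.items():
            if not 0 <= off < length:
                raise ValidationError("offsets must satisfy 0 <= offset < length")
        missing = set(self.length_probs) - set(self.offsets)
        if missing:
            raise ValidationError(f"lengths lacking an offset: {sorted(missing)}")
        for tr in self.transcripts:
            for cod in tr.codons:
                if cod not in self.dwell_weights and cod not in STOP_CODONS:
                    raise ValidationError(
                        f"{tr.transcript_id}: codon {cod} has no dwell weight")


def generate_footprints(spec: FootprintSpec) -> tuple[pd.DataFrame, dict]:
    """Sample an RPF alignment table from the spec.

    Returns a BED-like frame (transcript, start, end, name, length,
    strand) of 0-based half-open 5'-anchored intervals, plus a report
    with the number of reads discarded because the offset pushed their
    5' end below position 0.  Stop codons are never sampled.
    """
    rng = np.random.default_rng(spec.seed)
    positions = []          # (transcript index, codon index, weight)
    weights = []
    for ti, tr in enumerate(spec.transcripts):
        for ci, cod in enumerate(tr.codons):
            if cod in STOP_CODONS:
                continue
            w = spec.dwell_weights[cod]
            if ci == 1:
                w *= spec.init_peak_weight
            positions.append((ti, ci))
            weights.append(w)
    if spec.total_reads == 0 or not positions:
        empty = pd.DataFrame(columns=["transcript", "start", "end", "name",
                                      "length", "strand"])
        return empty, {"discarded_negative_start": 0, "n_reads": 0}

    weights = np.asarray(weights, float)
    probs = weights / weights.sum()
    draw = rng.multinomial(spec.total_reads, probs)

    lengths = np.array(sorted(spec.length_probs))
    lprobs = np.array([spec.length_probs[L] for L in lengths], float)
    lprobs = lprobs / lprobs.sum()

    rows = []
    discarded = 0
    read_no = 0
    for (ti, ci), count in zip(positions, draw):
        if count == 0:
            continue
        tr = spec.transcripts[ti]
        middle = tr.cds_start + 3 * ci + 1
        read_lengths = rng.choice(lengths, size=count, p=lprobs)
        for L in read_lengths:
            start = middle - spec.offsets[int(L)]
            if start < 0:
                discarded += 1
                continue
            rows.append((tr.transcript_id, int(start), int(start + L),
                         f"read{read_no}", int(L), "+"))
            read_no += 1
    df = pd.DataFrame(rows, columns=["transcript", "start", "end", "name",
                                     "length", "strand"])
    df = df.sample(frac=1.0, random_state=int(rng.integers(2 ** 31))) \
           .reset_index(drop=True)
    return df, {"discarded_negative_start": discarded, "n_reads": len(df)}


def random_transcripts(n_genes: int, n_codons: int, seed: int = 0,
                       utr5: int = 60, utr3: int = 30,
                       codons: tuple = SENSE_CODONS) -> list[Transcript]:
    """Random transcripts: ATG + random sense codons + stop, with UTRs."""
    rng = np.random.default_rng(seed)
    out = []
    for g in range(n_genes):
        mid = rng.choice(codons, size=n_codons - 1)
        cds = "ATG" + "".join(mid) + "TAA"
        seq = ("".join(rng.choice(list(_BASES), size=utr5)) + cds
               + "".join(rng.choice(list(_BASES), size=utr3)))
        out.append(Transcript(f"gene{g}", seq, utr5, utr5 + len(cds)))
    return out
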
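"""A-site offset calibration and per-codon ribosome dwelling occupancy.

Reads are calibrated from their 5' ends: for each read length, a
metagene of 5' positions around annotated start codons shows a modal
peak from initiating ribosomes.  Because the P site of an initiating
ribosome covers the start codon, its A site is the second codon, whose
middle nucleotide lies at (cds_start + 4); the distance from the modal
5' position to that nucleotide is the per-length offset.

With offsets in hand, each read contributes one count to the codon
containing the nucleotide at (5' + offset).  Counts at each position of
a gene are divided by the gene's mean count over included positions
(positions past the first 51 nt, i.e. past the first 17 codons, which
are depleted by run-off elongation during harvesting), and those ratios
are averaged across genes per codon to give the dwelling occupancy: 1
means genome-average dwell, >1 means a slowly translated codon.  Met
(ATG) codons are excluded from the occupancy table because initiation
chemistry (harringtonine) inflates their apparent dwell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ValidationError
from .footprints import STOP_CODONS

__all__ = ["OffsetTable", "CodonOccupancyTable", "calibrate_offsets",
           "assign_a_sites", "dwelling_occupancy", "occupancy_report"]

#: nt from CDS start to the middle nucleotide of the initiation A-site codon
_INIT_A_MIDDLE = 4
#: default exclusion at the CDS 5' end, nt (17 codons)
DEFAULT_EXCLUDE_NT = 51


@dataclass
class OffsetTable:
    """Read length (nt) -> offset (nt) from 5' end to A-site codon middle."""

    offsets: dict
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        for length, off in self.offsets.items():
            if not 0 <= off < length:
                raise ValidationError(
                    f"offset {off} invalid for read length {length}")

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def __contains__(self, length: int) -> bool:
        return length in self.offsets


@dataclass
class CodonOccupancyTable:
    """Per-codon mean normalized ribosome density.

    ``table`` columns: codon, occupancy (1 = genome-average dwell),
    n_positions (contributing codon positions across genes), included
    (False for ATG, which is reported but excluded from interpretation).
    """

    table: pd.DataFrame
    n_genes_used: int
    n_genes_skipped: int
    exclude_nt: int

    def occupancy(self, codon: str) -> float:
        row = self.table.loc[self.table["codon"] == codon]
        if row.empty:
            raise KeyError(codon)
        return float(row["occupancy"].iloc[0])


def _cds_lookup(cds_table: pd.DataFrame) -> dict:
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required.issubset(cds_table.columns):
        raise ValidationError(f"CDS table must have columns {sorted(required)}")
    return {r.transcript_id: (int(r.cds_start), int(r.cds_end))
            for r in cds_table.itertuples()}


def calibrate_offsets(alignments: pd.DataFrame, cds_table: pd.DataFrame,
                      lengths_retained=(27, 28, 29),
                      window_nt: int = 40,
                      min_reads: int = 100) -> OffsetTable:
    """Per-read-length A-site offsets from a start-codon metagene of 5' ends.

    For each retained length, 5' positions within ``window_nt`` upstream
    of (through just past) annotated start codons are histogrammed; the
    modal position is attributed to initiating ribosomes and converted
    to the offset.  A length whose modal bin is not at least twice the
    median bin count has no usable peak and raises.
    """
    if alignments.empty:
        raise ValidationError("empty alignment table")
    cds = _cds_lookup(cds_table)
    offsets, diag = {}, {}
    starts = alignments["start"].to_numpy()
    lengths = (alignments["end"] - alignments["start"]).to_numpy() \
        if "length" not in alignments.columns else alignments["length"].to_numpy()
    tx = alignments["transcript"].to_numpy()
    cds_start = np.array([cds[t][0] if t in cds else -1 for t in tx])
    rel = starts - cds_start          # 5' position relative to start codon
    valid = cds_start >= 0
    for L in lengths_retained:
        sel = valid & (lengths == L) & (rel >= -window_nt) & (rel <= 3)
        if sel.sum() < min_reads:
            raise ValidationError(
                f"length {L}: only {int(sel.sum())} reads near start codons "
                f"(need >= {min_reads})")
        grid = np.arange(-window_nt, 4)
        counts = np.bincount(rel[sel] + window_nt, minlength=len(grid))[:len(grid)]
        mode_idx = int(np.argmax(counts))
        background = float(np.median(counts))
        if counts[mode_idx] < 2 * max(background, 1.0):
            raise ValidationError(
                f"length {L}: no metagene peak above background "
                f"(modal bin {counts[mode_idx]}, median {background})")
        modal_rel = int(grid[mode_idx])
        offsets[int(L)] = _INIT_A_MIDDLE - modal_rel
        diag[int(L)] = {"modal_5prime_rel_start": modal_rel,
                        "peak_count": int(counts[mode_idx]),
                        "median_count": background,
                        "n_reads_window": int(sel.sum())}
    return OffsetTable(offsets, diag)


def assign_a_sites(alignments: pd.DataFrame, offsets: OffsetTable,
                   cds_table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Count reads per A-site codon position.

    Each read adds one count to the codon whose middle nucleotide is at
    (5' + offset(length)).  Reads with unknown lengths and reads whose
    A site falls outside the CDS are tallied, not silently dropped.
    Returns a frame (transcript, codon_index, count) and the tally.
    """
    cds = _cds_lookup(cds_table)
    tallies = {"assigned": 0, "outside_cds": 0, "length_not_calibrated": 0,
               "unknown_transcript": 0}
    counts: dict = {}
    lengths = (alignments["length"] if "length" in alignments.columns
               else alignments["end"] - alignments["start"])
    for t, start, L in zip(alignments["transcript"], alignments["start"],
                           lengths):
        L = int(L)
        if L not in offsets:
            tallies["length_not_calibrated"] += 1
            continue
        if t not in cds:
            tallies["unknown_transcript"] += 1
            continue
        c0, c1 = cds[t]
        middle = int(start) + offsets[L]
        if not c0 <= middle < c1:
            tallies["outside_cds"] += 1
            continue
        codon_idx = (middle - c0) // 3
        counts[(t, codon_idx)] = counts.get((t, codon_idx), 0) + 1
        tallies["assigned"] += 1
    df = pd.DataFrame(
        [(t, ci, n) for (t, ci), n in sorted(counts.items())],
        columns=["transcript", "codon_index", "count"])
    return df, tallies


def dwelling_occupancy(position_counts: pd.DataFrame,
                       transcripts,
                       exclude_nt: int = DEFAULT_EXCLUDE_NT,
                       min_mean_coverage: float = 0.5) -> CodonOccupancyTable:
    """Per-codon dwelling occupancy with normalization and exclusions.

    Per gene, the count at each included position is divided by the
    gene's mean count over included positions (so the mean ratio per
    gene is identically 1); ratios are then averaged across genes per
    codon.  Included positions are sense codons beyond the first
    ``exclude_nt`` nucleotides of the CDS.  Genes with mean coverage
    below ``min_mean_coverage`` reads/codon (or zero) are skipped and
    counted.  ATG rows are reported with ``included=False``.
    """
    if exclude_nt % 3 != 0:
        raise ValidationError("exclude_nt must be a whole number of codons")
    first_codon = exclude_nt // 3
    tx_map = {t.transcript_id: t for t in transcripts}
    by_gene = {t: g for t, g in position_counts.groupby("transcript")}
    ratios: dict = {}
    used = skipped = 0
    for tid, tr in tx_map.items():
        codons = tr.codons
        included_idx = [i for i in range(first_codon, len(codons))
                        if codons[i] not in STOP_CODONS]
        if not included_idx:
            continue
        vec = np.zeros(len(codons))
        if tid in by_gene:
            g = by_gene[tid]
            vec[g["codon_index"].to_numpy()] = g["count"].to_numpy()
        mean = vec[included_idx].mean()
        if mean <= 0 or mean < min_mean_coverage:
            skipped += 1
            continue
        used += 1
        for i in included_idx:
            ratios.setdefault(codons[i], []).append(vec[i] / mean)
    rows = []
    for codon, vals in sorted(ratios.items()):
        rows.append((codon, float(np.mean(vals)), len(vals), codon != "ATG"))
    table = pd.DataFrame(rows, columns=["codon", "occupancy", "n_positions",
                                        "included"])
    return CodonOccupancyTable(table, used, skipped, exclude_nt)


def occupancy_report(occ: CodonOccupancyTable, codon_usage: pd.DataFrame,
                     boundary_quantile: float = 0.90) -> pd.DataFrame:
    """Occupancy vs genome codon usage, with slow-codon flagging.

    ``codon_usage`` needs columns (codon, per_thousand).  Codons whose
    occupancy exceeds the ``boundary_quantile`` quantile of the
    included-codon occupancy distribution are flagged slow.  A Spearman
    rank correlation between occupancy and usage is attached as
    ``.attrs['rank_correlation']`` along with the boundary value.
    """
    if not {"codon", "per_thousand"}.issubset(codon_usage.columns):
        raise ValidationError("usage table needs columns codon, per_thousand")
    inc = occ.table[occ.table["included"]].copy()
    missing = set(inc["codon"]) - set(codon_usage["codon"])
    if missing:
        raise ValidationError(f"usage table missing codons: {sorted(missing)}")
    merged = inc.merge(codon_usage[["codon", "per_thousand"]], on="codon")
    boundary = float(merged["occupancy"].quantile(boundary_quantile))
    spread = merged["occupancy"].max() - merged["occupancy"].min()
    if spread <= 1e-12:
        merged["slow"] = False        # flat distribution: nothing stands out
    else:
        merged["slow"] = merged["occupancy"] > boundary
    if spread <= 1e-12 or merged["per_thousand"].nunique() == 1:
        rho_val = float("nan")        # correlation undefined for flat input
    else:
        rho_val = float(spearmanr(merged["occupancy"],
                                  merged["per_thousand"]).statistic)
    merged = merged.sort_values("occupancy", ascending=False,
                                ignore_index=True)
    merged.attrs["rank_correlation"] = rho_val
    merged.attrs["boundary"] = boundary
    merged.attrs["boundary_quantile"] = boundary_quantile
    return merged
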
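"""Synthetic fixtures for the assay-level quantifications.

Melt curves follow a descending Boltzmann sigmoid (fraction soluble
falls with temperature, midpoint t50); qPCR Ct tables are built so the
ddCt analysis recovers configured fold changes exactly in the
noise-free limit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["boltzmann", "generate_melt_curve", "generate_qpcr_table",
           "generate_microarray"]


def boltzmann(temps_c, t50_c: float, slope_c: float,
              top: float = 1.0, bottom: float = 0.0) -> np.ndarray:
    """Descending sigmoid: f = bottom + (top-bottom)/(1 + exp((T-t50)/slope)).

    With slope > 0 the soluble fraction decreases with temperature and
    f(t50) is exactly midway between the plateaus.
    """
    t = np.asarray(temps_c, float)
    return bottom + (top - bottom) / (1.0 + np.exp((t - t50_c) / slope_c))


def generate_melt_curve(t50_c: float, slope_c: float, temps_c,
                        noise_sd: float = 0.0, n_replicates: int = 1,
                        seed: int = 0) -> pd.DataFrame:
    """Thermal-aggregation melt curve: (temperature, replicate, soluble fraction).

    Temperatures must be strictly increasing; noise is additive Gaussian
    per replicate measurement.
    """
    temps = np.asarray(temps_c, float)
    if np.any(np.diff(temps) <= 0):
        raise ValidationError("temperatures must be strictly increasing")
    if slope_c <= 0:
        raise ValidationError("slope must be positive")
    rng = np.random.default_rng(seed)
    clean = boltzmann(temps, t50_c, slope_c)
    rows = []
    for rep in range(n_replicates):
        vals = clean + (rng.normal(0.0, noise_sd, len(temps))
                        if noise_sd > 0 else 0.0)
        for t, v in zip(temps, vals):
            rows.append((float(t), rep, float(v)))
    return pd.DataFrame(rows, columns=["temperature_c", "replicate",
                                       "soluble_fraction"])


def generate_qpcr_table(fold_changes: dict, reference_sample: str,
                        target_gene: str = "CFTR",
                        reference_gene: str = "NPT",
                        base_ct_target: float = 22.0,
                        base_ct_reference: float = 18.0,
                        ct_noise_sd: float = 0.0,
                        n_wells: int = 2, seed: int = 0) -> pd.DataFrame:
    """Ct table with ddCt-consistent structure.

    ``fold_changes`` maps sample -> true expression fold relative to the
    reference sample (assumed 100% amplification efficiency, so one fold
    of 2 lowers the target Ct by 1 cycle).  Columns: sample, gene, well,
    ct.
    """
    if reference_sample not in fold_changes:
        fold_changes = {reference_sample: 1.0, **fold_changes}
    if fold_changes[reference_sample] != 1.0:
        raise ValidationError("reference sample must have fold change 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fold in fold_changes.items():
        if fold <= 0:
            raise ValidationError("fold changes must be positive")
        ct_t = base_ct_target - np.log2(fold)
        for gene, ct in ((target_gene, ct_t),
                         (reference_gene, base_ct_reference)):
            for w in range(n_wells):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append((sample, gene, w, float(ct + noise)))
    return pd.DataFrame(rows, columns=["sample", "gene", "well", "ct"])


def generate_microarray(true_ratios: dict, spike_ins=("spike1", "spike2", "spike3"),
                        n_probes: int = 24, global_gain: float = 1.0,
                        noise_cv: float = 0.10, seed: int = 0) -> pd.DataFrame:
    """Two-channel tRNA microarray signals with spike-in standards.

    ``true_ratios`` maps tRNA id -> true Cy3/Atto647 abundance ratio
    after spike-in normalization.  ``global_gain`` multiplies the whole
    Cy3 channel (spike-ins included) to exercise normalization
    invariance.  Columns: trna, probe, cy3, atto647, is_spike_in.
    """
    rng = np.random.default_rng(seed)
    rows = []
    base = 1000.0
    entries = [(t, r, False) for t, r in true_ratios.items()]
    entries += [(s, 1.0, True) for s in spike_ins]
    for trna, ratio, is_spike in entries:
        for p in range(n_probes):
            a = base * rng.lognormal(0.0, noise_cv)
            c = base * ratio * global_gain * rng.lognormal(0.0, noise_cv)
            rows.append((trna, p, float(c), float(a), is_spike))
    return pd.DataFrame(rows, columns=["trna", "probe", "cy3", "atto647",
                                       "is_spike_in"])
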
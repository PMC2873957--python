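"""End-to-end orchestration: measurements -> consensus target peaks.

Convenience wrappers chaining the QC/normalization, peak-calling and
consensus steps with their defaults; every stage remains individually
accessible for non-standard runs.
"""

from __future__ import annotations

import pandas as pd

from . import peaks as pk
from . import qcnorm as qn

__all__ = ["peaks_from_measurements", "consensus_from_measurements"]


def peaks_from_measurements(
    measurements: pd.DataFrame,
    params: pk.PeakCallingParams = pk.PeakCallingParams(),
    qc_threshold: float | None = 0.5,
    source: str = "brute-force",
) -> tuple[list[pk.Peak], qn.QcReport | None]:
    """Normalize, QC-filter and call interval peaks per (array, replicate).

    ``qc_threshold=None`` skips correlation QC entirely (needed for
    degenerate inputs such as an exactly constant input channel, whose
    Pearson r is undefined).
    """
    report = None
    excluded = None
    if qc_threshold is not None:
        report = qn.qc_correlations(measurements, exclusion_threshold=qc_threshold)
        excluded = report.excluded
    norm = qn.normalize_measurements(measurements)
    track = qn.compute_ratio_tracks(norm, drop_arrays=excluded)
    peaks: list[pk.Peak] = []
    for _, grp in track.groupby(["array_id", "replicate_id"]):
        peaks.extend(pk.find_peaks_interval(grp, params, source=source))
    return peaks, report


def consensus_from_measurements(
    measurements: pd.DataFrame,
    tss: pd.DataFrame,
    n_replicates: int,
    params: pk.PeakCallingParams = pk.PeakCallingParams(),
    detectors: tuple[str, ...] = ("brute-force",),
    qc_threshold: float | None = 0.5,
) -> list[pk.ConsensusPeak]:
    """Full route from raw two-channel measurements to linked consensus peaks."""
    peaks, _ = peaks_from_measurements(measurements, params, qc_threshold, detectors[0])
    consensus = pk.merge_and_score(peaks, list(detectors), n_replicates, params)
    return pk.link_peaks_to_tss(consensus, tss, params)
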
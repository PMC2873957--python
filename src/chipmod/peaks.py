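"""Interval peak calling, TSS linking and consensus scoring.

The interval ("brute-force") caller works directly on the empirical
ChIP/input ratio distribution of one array: a binding event is at least
three probes where a centre probe lies in the upper q_center (default
0.01) quantile of the array's ratios and at least one upstream plus one
downstream neighbour within max_neighbor_dist (default 1000 nt) lie in
the upper q_flank (default 0.05) quantile. Peaks from several detectors
and biological replicates are merged into consensus events whose peak
score is the fraction of (detector, replicate) combinations that
detected the event — the quantity the downstream motif calibration and
target selection are conditioned on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakCallingParams",
    "Peak",
    "ConsensusPeak",
    "quantile_thresholds",
    "find_peaks_interval",
    "link_peaks_to_tss",
    "ingest_external_peaks",
    "merge_and_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakCallingParams:
    """Tunable parameters of the interval caller and consensus step.

    q_center / q_flank are upper-tail quantile fractions of the
    array-specific ratio distribution; max_neighbor_dist bounds how far
    (nt) a flanking probe may sit from the centre probe; min_probes is
    the least number of supporting probes of an emitted peak;
    tss_max_dist caps peak-to-TSS linking; merge_gap is the largest gap
    (nt) bridged when merging detections into a consensus event.
    """

    q_center: float = 0.01
    q_flank: float = 0.05
    max_neighbor_dist: int = 1000
    min_probes: int = 3
    tss_max_dist: int = 8000
    merge_gap: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.q_center <= self.q_flank < 1:
            raise ValueError("require 0 < q_center <= q_flank < 1")
        if self.min_probes < 3:
            raise ValueError("min_probes must be >= 3 (centre plus both flanks)")
        if self.max_neighbor_dist <= 0 or self.tss_max_dist <= 0:
            raise ValueError("distances must be positive")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be non-negative")


@dataclass
class Peak:
    """A called (or ingested) binding interval.

    start/end are 0-based half-open over the supporting probes
    (including probe length); for external detectors the probe fields
    are empty.
    """

    chrom: str
    start: int
    end: int
    source: str
    replicate_id: int
    probe_ids: tuple[str, ...] = ()
    center_probe: str | None = None
    max_ratio: float | None = None
    array_id: int | None = None
    linked_gene: str | None = None
    distance_to_tss: int | None = None

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ConsensusPeak:
    """A merged binding event with its detection matrix and peak score.

    peak_score = detections / (n_detectors * n_replicates), the
    fraction of declared (detector, replicate) combinations in which
    the event was found; absent combinations count as non-detections.
    """

    chrom: str
    start: int
    end: int
    detections: frozenset[tuple[str, int]]
    n_detectors: int
    n_replicates: int
    peaks: list[Peak] = field(default_factory=list)
    linked_gene: str | None = None
    distance_to_tss: int | None = None

    @property
    def peak_score(self) -> float:
        return len(self.detections) / (self.n_detectors * self.n_replicates)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def quantile_thresholds(
    ratios: np.ndarray | pd.Series, params: PeakCallingParams = PeakCallingParams()
) -> tuple[float, float]:
    """Array-specific centre/flank ratio thresholds.

    t_center is the (1 - q_center) empirical quantile of the array's
    total ChIP/input ratio distribution, t_flank the (1 - q_flank)
    quantile, both with linear interpolation.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty ratio track")
    if r.size < 100:
        warnings.warn(
            f"only {r.size} probes; upper-quantile thresholds are unstable",
            stacklevel=2,
        )
    t_center = float(np.quantile(r, 1.0 - params.q_center))
    t_flank = float(np.quantile(r, 1.0 - params.q_flank))
    return t_center, t_flank


def find_peaks_interval(
    track: pd.DataFrame,
    params: PeakCallingParams = PeakCallingParams(),
    thresholds: tuple[float, float] | None = None,
    source: str = "brute-force",
    probe_length: int = 50,
) -> list[Peak]:
    """Call peaks on one array's ratio track with the interval criterion.

    ``track`` needs columns probe_id, chrom, pos, ratio (one array_id,
    replicate_id). A probe qualifies as a peak centre if its ratio is at
    least t_center and at least one probe strictly upstream and one
    strictly downstream, each within max_neighbor_dist, has ratio at
    least t_flank. A peak's supporting probes are the centre plus every
    flank-qualifying probe within max_neighbor_dist; peaks whose
    intervals overlap are merged (union of supporting probes).

    ``thresholds`` overrides the array-derived quantile thresholds —
    used when the array-level ratio distribution is computed over more
    probes than the track at hand.
    """
    required = {"probe_id", "chrom", "pos", "ratio"}
    if not required.issubset(track.columns):
        raise ValueError(f"track needs columns {sorted(required)}")
    if "replicate_id" in track.columns and track["replicate_id"].nunique() > 1:
        raise ValueError("track mixes replicates; call per (array, replicate)")
    if thresholds is None:
        thresholds = quantile_thresholds(track["ratio"], params)
    t_center, t_flank = thresholds
    if t_center < t_flank:
        raise ValueError("t_center must be >= t_flank")

    rep = int(track["replicate_id"].iloc[0]) if "replicate_id" in track.columns else 0
    arr = int(track["array_id"].iloc[0]) if "array_id" in track.columns else None

    peaks: list[Peak] = []
    for chrom, grp in track.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        ratio = grp["ratio"].to_numpy(dtype=float)
        pid = grp["probe_id"].to_numpy()
        flank_ok = ratio >= t_flank
        cum = np.concatenate([[0], np.cumsum(flank_ok)])

        clusters: list[tuple[int, int, set[int]]] = []  # start, end, support idx
        for i in np.flatnonzero(ratio >= t_center):
            lo = int(np.searchsorted(pos, pos[i] - params.max_neighbor_dist, "left"))
            hi = int(np.searchsorted(pos, pos[i] + params.max_neighbor_dist, "right"))
            up = cum[i] - cum[lo]              # flank-qualifying probes in [lo, i)
            down = cum[hi] - cum[i + 1]        # flank-qualifying probes in (i, hi)
            if up < 1 or down < 1:
                continue
            support = set(np.flatnonzero(flank_ok[lo:hi]) + lo)
            support.add(int(i))
            span = (int(pos[min(support)]), int(pos[max(support)]) + probe_length)
            clusters.append((span[0], span[1], support))

        # merge overlapping qualifying intervals into one peak
        clusters.sort(key=lambda c: (c[0], c[1]))
        merged: list[tuple[int, int, set[int]]] = []
        for start, end, support in clusters:
            if merged and start < merged[-1][1]:
                pstart, pend, psup = merged[-1]
                merged[-1] = (pstart, max(pend, end), psup | support)
            else:
                merged.append((start, end, set(support)))

        for start, end, support in merged:
            if len(support) < params.min_probes:
                continue
            idx = sorted(support)
            centers = [j for j in idx if ratio[j] >= t_center]
            best = max(centers, key=lambda j: (ratio[j], -j)) if centers else None
            peaks.append(
                Peak(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    source=source,
                    replicate_id=rep,
                    array_id=arr,
                    probe_ids=tuple(pid[j] for j in idx),
                    center_probe=pid[best] if best is not None else None,
                    max_ratio=float(ratio[idx].max()),
                )
            )
    return peaks


def link_peaks_to_tss(
    peaks: list,
    tss: pd.DataFrame,
    params: PeakCallingParams = PeakCallingParams(),
) -> list:
    """Assign each peak the closest TSS within tss_max_dist.

    Distance is measured from the peak midpoint to the TSS and reported
    signed in gene orientation (negative upstream of the TSS).
    Equidistant TSSs are broken lexicographically by gene id; peaks with
    no TSS within range stay unlinked. Works on Peak and ConsensusPeak
    alike (mutates and returns the list).
    """
    gene_col = "gene_id" if "gene_id" in tss.columns else "promoter_id"
    ann = tss.sort_values([gene_col]).reset_index(drop=True)
    by_chrom = {c: g for c, g in ann.groupby("chrom")}
    for pk in peaks:
        grp = by_chrom.get(pk.chrom)
        if grp is None:
            pk.linked_gene = None
            pk.distance_to_tss = None
            continue
        d = pk.midpoint - grp["tss"].to_numpy(dtype=float)
        absd = np.abs(d)
        best = np.lexsort((grp[gene_col].to_numpy(), absd))[0]
        if absd[best] > params.tss_max_dist:
            pk.linked_gene = None
            pk.distance_to_tss = None
            continue
        strand = grp["strand"].iloc[best]
        signed = d[best] if strand == "+" else -d[best]
        pk.linked_gene = str(grp[gene_col].iloc[best])
        pk.distance_to_tss = int(round(signed))
    return peaks


def ingest_external_peaks(
    path: str,
    source_label: str,
    replicate_id: int,
    one_based: bool = False,
) -> list[Peak]:
    """Load a BED-like peak list from an external detector.

    Expects BED3+ (0-based half-open); ``one_based=True`` accepts the
    1-based inclusive dialect and shifts starts by -1. Lines whose
    interval is empty (end <= start) are rejected with a logged warning
    naming the line; unparseable coordinates raise with the line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: unparseable coordinates") from exc
            if one_based:
                start -= 1
            if end <= start:
                logger.warning("%s:%d: empty interval (end <= start), skipped", path, ln)
                continue
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    source=source_label,
                    replicate_id=replicate_id,
                )
            )
    return peaks


def merge_and_score(
    peaks: list[Peak],
    detectors: list[str],
    n_replicates: int,
    params: PeakCallingParams = PeakCallingParams(),
) -> list[ConsensusPeak]:
    """Merge detections across detectors and replicates; score events.

    Intervals separated by a gap of at most merge_gap nt (overlap
    included) are fused into one consensus event. The peak score of an
    event is the number of distinct (detector, replicate) combinations
    contributing at least one interval divided by
    len(detectors) * n_replicates; it is a fraction in (0, 1].
    """
    if not detectors or n_replicates < 1:
        raise ValueError("declare at least one detector and one replicate")
    declared = set(detectors)
    for pk in peaks:
        if pk.source not in declared:
            raise ValueError(f"peak source {pk.source!r} not among declared detectors")

    consensus: list[ConsensusPeak] = []
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    cluster: list[Peak] = []

    def flush() -> None:
        if not cluster:
            return
        consensus.append(
            ConsensusPeak(
                chrom=cluster[0].chrom,
                start=min(p.start for p in cluster),
                end=max(p.end for p in cluster),
                detections=frozenset((p.source, p.replicate_id) for p in cluster),
                n_detectors=len(detectors),
                n_replicates=n_replicates,
                peaks=list(cluster),
            )
        )

    cur_end = None
    for pk in ordered:
        if cluster and pk.chrom == cluster[-1].chrom and pk.start - cur_end <= params.merge_gap:
            cluster.append(pk)
            cur_end = max(cur_end, pk.end)
        else:
            flush()
            cluster = [pk]
            cur_end = pk.end
    flush()
    return consensus
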
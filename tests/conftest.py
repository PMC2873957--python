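"""Shared fixtures and independent oracles.

The peak-caller oracle below is a literal, quadratic transcription of
the interval definition (centre probe in the upper q_center quantile,
at least one upstream and one downstream neighbour within the distance
cap in the upper q_flank quantile); it is deliberately naive and kept
independent of the production implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from chipmod.peaks import PeakCallingParams


def make_random_track(
    rng: np.random.Generator,
    n: int = 150,
    spacing: int = 100,
    spike_prob: float = 0.05,
    spike_scale: float = 4.0,
    irregular: bool = False,
) -> pd.DataFrame:
    """A single-array ratio track with log-normal baseline and spikes."""
    if irregular:
        gaps = rng.integers(1, 4, size=n) * spacing
        pos = np.cumsum(gaps)
    else:
        pos = np.arange(n) * spacing
    ratio = np.exp(rng.normal(0.0, 0.25, n))
    spikes = rng.random(n) < spike_prob
    ratio[spikes] *= spike_scale * rng.random(spikes.sum()) + 1.0
    return pd.DataFrame(
        {
            "probe_id": [f"pr{i:04d}" for i in range(n)],
            "chrom": "chrS",
            "pos": pos,
            "ratio": ratio,
        }
    )


def oracle_find_peaks(
    track: pd.DataFrame,
    params: PeakCallingParams,
    thresholds: tuple[float, float],
    probe_length: int = 50,
) -> set[tuple]:
    """Exhaustive per-probe peak caller, straight from the definition.

    Tests every probe as a candidate centre, gathers its qualifying
    flanks by brute-force distance checks, merges overlapping
    qualifying intervals, and returns canonical peak tuples
    (chrom, start, end, frozenset of supporting probe ids).
    """
    t_center, t_flank = thresholds
    result: set[tuple] = set()
    for chrom in sorted(track["chrom"].unique()):
        grp = track[track["chrom"] == chrom].sort_values("pos")
        pos = grp["pos"].tolist()
        ratio = grp["ratio"].tolist()
        pid = grp["probe_id"].tolist()
        n = len(pos)
        clusters = []
        for i in range(n):
            if ratio[i] < t_center:
                continue
            up = [
                j
                for j in range(n)
                if 0 < pos[i] - pos[j] <= params.max_neighbor_dist
                and ratio[j] >= t_flank
            ]
            down = [
                j
                for j in range(n)
                if 0 < pos[j] - pos[i] <= params.max_neighbor_dist
                and ratio[j] >= t_flank
            ]
            if not up or not down:
                continue
            support = {i}
            for j in range(n):
                if abs(pos[j] - pos[i]) <= params.max_neighbor_dist and ratio[j] >= t_flank:
                    support.add(j)
            start = pos[min(support)]
            end = pos[max(support)] + probe_length
            clusters.append((start, end, support))
        clusters.sort(key=lambda c: (c[0], c[1]))
        merged: list[list] = []
        for start, end, support in clusters:
            if merged and start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] |= support
            else:
                merged.append([start, end, set(support)])
        for start, end, support in merged:
            if len(support) >= params.min_probes:
                result.add((chrom, start, end, frozenset(pid[j] for j in support)))
    return result


def canonical_peaks(peaks) -> set[tuple]:
    """Production peaks in the oracle's canonical form."""
    return {(p.chrom, p.start, p.end, frozenset(p.probe_ids)) for p in peaks}


def module_fixture_plan() -> dict[str, list[tuple[str, int, str]]]:
    """16 promoters enumerating every OCT4 x SOX2 x PORE x MORE combination.

    Plantings sit at well-separated offsets on the '+' strand; the
    all-absent combination gets an empty plan.
    """
    plan: dict[str, list[tuple[str, int, str]]] = {}
    combos = list(itertools.product([False, True], repeat=4))
    offsets = {"OCT4": 200, "SOX2": 600, "PORE": 1000, "MORE": 1400}
    for i, (oct4, sox2, pore, more) in enumerate(combos):
        plantings = []
        for name, present in zip(("OCT4", "SOX2", "PORE", "MORE"), (oct4, sox2, pore, more)):
            if present:
                plantings.append((name, offsets[name], "+"))
        plan[f"P{i + 1:04d}"] = plantings
    return plan


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20090427)
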
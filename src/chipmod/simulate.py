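"""Synthetic promoter tiling-array data.

Emulates a NimbleGen-style two-channel promoter design: probes tile a
window around each TSS (default -3500..+750) at ~100 bp median spacing,
promoters are distributed round-robin over a small set of physical
arrays, and ChIP enrichment of a planted binding event is smeared over
neighbouring probes by sonication of ~550 bp chromatin fragments.

Every generator is deterministic under an explicit integer seed and
returns plain pandas/str containers so the downstream QC, peak-calling
and motif modules can be exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "ProbeLayout",
    "PlantedEvent",
    "TruthSet",
    "MOTIF_WORDS",
    "make_probe_layout",
    "plant_events",
    "simulate_two_channel_arrays",
    "simulate_promoter_sequences",
    "simulate_knockdown_expression",
    "reverse_complement",
]


class ParameterError(ValueError):
    """A generator was configured with an invalid parameter."""


#: Fixed motif literals used throughout: the OCT4 octamer, the PORE
#: (Palindromic Oct factor Recognition Element), the MORE ("More PORE",
#: a self-reverse-complement dual-OCT4 site) and a SOX2 consensus 7-mer
#: shipped for testing only.
MOTIF_WORDS = {
    "OCT4": "ATGCAAAT",
    "PORE": "ATTTGAAATGCAAAT",
    "MORE": "ATGCATATGCAT",
    "SOX2": "CATTGTT",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PlantedEvent:
    """A planted binding event inside one promoter window."""

    promoter_id: str
    center: int              # genomic coordinate of the event
    strength: float          # multiplicative enrichment at the center, >= 1
    fragment_size: int = 550  # sonication fragment size (kernel half-width), nt

    def __post_init__(self) -> None:
        if self.strength < 1:
            raise ParameterError(f"event strength must be >= 1, got {self.strength}")
        if self.fragment_size <= 0:
            raise ParameterError("fragment_size must be positive")


@dataclass
class TruthSet:
    """Ground truth of a simulation run, for recovery tests and reports."""

    events: list[PlantedEvent] = field(default_factory=list)
    #: promoter_id -> list of (motif name or literal word, offset, strand)
    motif_positions: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    #: gene_id -> true knockdown/control fold change
    expression_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class ProbeLayout:
    """Probe and TSS geometry of a simulated promoter array set.

    Attributes
    ----------
    probes : DataFrame with columns probe_id, chrom, pos, length,
        promoter_id, array_id; within each promoter probes are strictly
        ordered by pos at the configured spacing, and a promoter's
        probes all sit on one physical array.
    tss : DataFrame with columns promoter_id, chrom, tss, strand,
        window_start, window_end (0-based half-open promoter window).
    """

    probes: pd.DataFrame
    tss: pd.DataFrame
    spacing: int
    window_up: int
    window_down: int
    arrays: int
    probe_length: int = 50

    @property
    def window_span(self) -> int:
        """Length in nt of each promoter window (= sequence length)."""
        return self.window_up + self.window_down

    def promoter_window(self, promoter_id: str) -> tuple[str, int, int]:
        row = self.tss.set_index("promoter_id").loc[promoter_id]
        return str(row["chrom"]), int(row["window_start"]), int(row["window_end"])


def make_probe_layout(
    n_promoters: int,
    spacing: int = 100,
    window_up: int = 3500,
    window_down: int = 750,
    arrays: int = 2,
    seed: int = 0,
    probe_length: int = 50,
) -> ProbeLayout:
    """Lay out tiling probes around ``n_promoters`` synthetic TSSs.

    Each promoter window spans ``window_up`` nt upstream to
    ``window_down`` nt downstream of its TSS (oriented by gene strand)
    and carries ``floor((window_up+window_down)/spacing) + 1`` probes.
    Promoters are assigned to physical arrays round-robin and separated
    by >15 kb of unprobed sequence so peaks can never bridge promoters.
    """
    if n_promoters < 1:
        raise ParameterError("n_promoters must be >= 1")
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    if arrays < 1:
        raise ParameterError("arrays must be >= 1")

    rng = np.random.default_rng(seed)
    span = window_up + window_down
    n_probes = span // spacing + 1
    gap = span + 20_000

    probe_rows = []
    tss_rows = []
    for i in range(n_promoters):
        pid = f"P{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss = 10_000 + window_up + i * gap
        if strand == "+":
            win_start = tss - window_up
        else:
            win_start = tss - window_down
        win_end = win_start + span
        array_id = i % arrays + 1
        for k in range(n_probes):
            pos = win_start + k * spacing
            probe_rows.append(
                (f"{pid}_{k + 1:03d}", "chrS", pos, probe_length, pid, array_id)
            )
        tss_rows.append((pid, "chrS", tss, strand, win_start, win_end))

    probes = pd.DataFrame(
        probe_rows,
        columns=["probe_id", "chrom", "pos", "length", "promoter_id", "array_id"],
    )
    tss_df = pd.DataFrame(
        tss_rows,
        columns=["promoter_id", "chrom", "tss", "strand", "window_start", "window_end"],
    )
    return ProbeLayout(
        probes=probes,
        tss=tss_df,
        spacing=spacing,
        window_up=window_up,
        window_down=window_down,
        arrays=arrays,
        probe_length=probe_length,
    )


def plant_events(
    layout: ProbeLayout,
    promoter_ids: list[str],
    strength: float = 4.0,
    fragment_size: int = 550,
) -> list[PlantedEvent]:
    """Plant one binding event per listed promoter.

    The event center snaps to the tiled probe position nearest the
    middle of the promoter window, so a probe sits exactly on the
    enrichment-kernel peak.
    """
    known = set(layout.tss["promoter_id"])
    events = []
    for pid in promoter_ids:
        if pid not in known:
            raise ParameterError(f"unknown promoter {pid!r}")
        _, win_start, win_end = layout.promoter_window(pid)
        mid = (win_start + win_end) // 2
        pos = layout.probes.loc[layout.probes["promoter_id"] == pid, "pos"]
        center = int(pos.iloc[(pos - mid).abs().to_numpy().argmin()])
        events.append(
            PlantedEvent(
                promoter_id=pid,
                center=center,
                strength=strength,
                fragment_size=fragment_size,
            )
        )
    return events


def _triangular_kernel(dist: np.ndarray, half_width: int) -> np.ndarray:
    """Fragment-smearing kernel: 1 at the event center, 0 beyond half_width."""
    return np.clip(1.0 - np.abs(dist) / half_width, 0.0, None)


def expected_ratio(layout: ProbeLayout, events: list[PlantedEvent]) -> np.ndarray:
    """Noise-free expected ChIP/input ratio per probe (layout order).

    ratio = 1 + sum over events of (strength - 1) * k(d) with k the
    triangular kernel of half-width fragment_size and d the probe-to-
    center distance; excess enrichments of distinct events add.
    """
    pos = layout.probes["pos"].to_numpy()
    chrom = layout.probes["chrom"].to_numpy()
    ratio = np.ones(len(pos))
    tss_chrom = dict(zip(layout.tss["promoter_id"], layout.tss["chrom"]))
    for ev in events:
        mask = chrom == tss_chrom[ev.promoter_id]
        k = _triangular_kernel(pos[mask] - ev.center, ev.fragment_size)
        ratio[mask] += (ev.strength - 1.0) * k
    return ratio


def simulate_two_channel_arrays(
    layout: ProbeLayout,
    truth: TruthSet,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    dye_bias: tuple[float, float] = (1.0, 1.0),
    base_intensity: float = 1000.0,
    probe_effect_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ChIP (Cy5-like) and input (Cy3-like) probe intensities.

    The input channel is event-independent; the ChIP channel carries the
    planted enrichment. Each probe has a brightness factor shared by
    both channels and all replicates (log-normal, log-sd
    ``probe_effect_sd``) — the source of the high chip-vs-input
    correlations a well-behaved two-channel hybridization shows; it
    cancels exactly in the ChIP/input ratio. On top, both channels get
    independent log-normal multiplicative noise with log-scale standard
    deviation ``noise_sd``, and per-channel dye scale factors
    ``dye_bias = (chip, input)``.

    Returns the probe-measurement table (one row per probe, replicate):
    probe_id, chrom, pos, array_id, replicate_id, chip_intensity,
    input_intensity.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if noise_sd < 0 or probe_effect_sd < 0:
        raise ParameterError("noise_sd and probe_effect_sd must be non-negative")

    rng = np.random.default_rng(seed)
    ratio = expected_ratio(layout, truth.events)
    n = len(layout.probes)
    brightness = (
        np.exp(rng.normal(0.0, probe_effect_sd, n)) if probe_effect_sd > 0 else 1.0
    )
    frames = []
    for rep in range(1, n_replicates + 1):
        noise_chip = np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd > 0 else 1.0
        noise_input = np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd > 0 else 1.0
        df = layout.probes[["probe_id", "chrom", "pos", "array_id"]].copy()
        df["replicate_id"] = rep
        df["chip_intensity"] = base_intensity * brightness * ratio * dye_bias[0] * noise_chip
        df["input_intensity"] = base_intensity * brightness * dye_bias[1] * noise_input
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_promoter_sequences(
    layout: ProbeLayout,
    motif_plan: dict[str, list[tuple[str, int, str]]] | None = None,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, list[tuple[str, int, str]]]]:
    """Draw i.i.d. background promoter sequences and plant motif words.

    ``motif_plan`` maps promoter_id to a list of (motif, offset, strand)
    plantings, where motif is either a name from :data:`MOTIF_WORDS` or
    a literal ACGT word, offset is 0-based from the genomic left end of
    the promoter window, and strand '-' inserts the reverse complement.
    Background base probabilities are (gc/2) for G and C, ((1-gc)/2)
    for A and T.

    Returns (sequences keyed by promoter_id, motif-position truth).
    Overlapping plantings within a promoter raise an error naming the
    collision.
    """
    if not 0.0 <= gc <= 1.0:
        raise ParameterError("gc must be in [0, 1]")
    motif_plan = motif_plan or {}
    known = set(layout.tss["promoter_id"])
    for pid in motif_plan:
        if pid not in known:
            raise ParameterError(f"motif_plan references unknown promoter {pid!r}")

    rng = np.random.default_rng(seed)
    span = layout.window_span
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))

    sequences: dict[str, str] = {}
    truth: dict[str, list[tuple[str, int, str]]] = {}
    for pid in layout.tss["promoter_id"]:
        seq = rng.choice(bases, size=span, p=probs)
        occupied: list[tuple[int, int, str]] = []
        for motif, offset, strand in motif_plan.get(pid, []):
            word = MOTIF_WORDS.get(motif, motif).upper()
            if set(word) - set("ACGT"):
                raise ParameterError(f"motif {motif!r} is not an ACGT word")
            if strand not in "+-":
                raise ParameterError(f"strand must be '+' or '-', got {strand!r}")
            if offset < 0 or offset + len(word) > span:
                raise ParameterError(
                    f"planting {motif!r} at {offset} does not fit the "
                    f"{span} nt window of {pid}"
                )
            for o_start, o_end, o_name in occupied:
                if offset < o_end and offset + len(word) > o_start:
                    raise ParameterError(
                        f"planting collision in {pid}: {motif!r} at {offset} "
                        f"overlaps {o_name!r} at {o_start}"
                    )
            inserted = word if strand == "+" else reverse_complement(word)
            seq[offset : offset + len(word)] = list(inserted)
            occupied.append((offset, offset + len(word), motif))
            truth.setdefault(pid, []).append((motif, offset, strand))
        sequences[pid] = "".join(seq)
    return sequences, truth


def simulate_knockdown_expression(
    genes: list[str],
    effects: dict[str, float],
    base_level: float = 200.0,
    floor: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate control/knockdown expression intensities with a floor.

    The knockdown intensity of a gene is base_level * effect * noise;
    the control is base_level * noise. Any simulated value below the
    detection floor (the vendor-style threshold S, default 20) is
    emitted as exactly the floor.

    Returns a long table (gene_id, condition, intensity) with
    conditions 'control' and 'knockdown'.
    """
    if floor <= 0:
        raise ParameterError("floor must be positive")
    if base_level <= floor:
        raise ParameterError("base_level must exceed the detection floor")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        effect = effects.get(gene, 1.0)
        for cond, level in (
            ("control", base_level),
            ("knockdown", base_level * effect),
        ):
            noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            value = level * noise
            rows.append((gene, cond, max(value, floor)))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "intensity"])
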
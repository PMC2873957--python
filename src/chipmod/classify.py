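"""Six-module classification of transcription-factor target genes.

Target promoters are screened (default window -3500..+750 around the
TSS) for four motif signals: an OCT4 PWM hit at or above its calibrated
threshold, a SOX2 PWM hit likewise, and exact presence of the fixed
dual-OCT4 elements PORE and MORE. The primary modules partition every
classified gene:

    module 1  OCT4 and SOX2 motifs present
    module 2  OCT4 motif present, SOX2 absent
    module 3  SOX2 motif present, OCT4 absent
    module 4  neither OCT4 nor SOX2 motif

Modules 5 (PORE) and 6 (MORE) are overlays on top of the primary
module, since one gene can carry both a SOX2 motif and a MORE element.
Knockdown expression fold changes label each target up-, down- or
un-regulated at a 2-fold boundary (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import motifs as mo
from .peaks import ConsensusPeak

logger = logging.getLogger(__name__)

__all__ = [
    "MotifFlags",
    "TargetGene",
    "RegulationCall",
    "scan_target_regions",
    "assign_module",
    "integrate_regulation",
    "compare_target_lists",
    "summarize_modules",
    "classify_targets",
]


@dataclass(frozen=True)
class MotifFlags:
    """Per-gene motif content of the scanned promoter region."""

    oct4: bool = False
    sox2: bool = False
    pore: bool = False
    more: bool = False
    best_oct4_score: float = float("-inf")
    best_sox2_score: float = float("-inf")
    best_oct4_offset: int | None = None
    best_sox2_offset: int | None = None


@dataclass(frozen=True)
class RegulationCall:
    """Knockdown regulation of one gene at a fold-change boundary."""

    gene_id: str
    fold_change: float
    direction: str  # up | down | unchanged | unmeasured
    threshold: float = 2.0


@dataclass
class TargetGene:
    """A classified target: peaks, motif content, module, regulation."""

    gene_id: str
    flags: MotifFlags
    primary_module: int
    overlay_modules: frozenset[int]
    peaks: list[ConsensusPeak] = field(default_factory=list)
    best_peak_score: float | None = None
    regulation: RegulationCall | None = None


def scan_target_regions(
    sequences: dict[str, str],
    oct4_pwm: mo.Pwm,
    oct4_threshold: float,
    sox2_pwm: mo.Pwm,
    sox2_threshold: float,
) -> tuple[dict[str, MotifFlags], list[str]]:
    """Motif flags per gene from its promoter-region sequence.

    OCT4/SOX2 flags come from the best PWM hit on either strand
    compared against the calibrated thresholds; PORE and MORE are exact
    literal matches. Genes whose sequence is missing (None/empty) are
    reported unscanned and excluded from module tables.

    Returns (gene -> flags, list of unscanned genes).
    """
    flags: dict[str, MotifFlags] = {}
    unscanned: list[str] = []
    for gene, seq in sequences.items():
        if not seq or len(seq) < max(oct4_pwm.length, sox2_pwm.length):
            logger.warning("gene %s has no scannable sequence; skipped", gene)
            unscanned.append(gene)
            continue
        o = mo.best_hit(seq, oct4_pwm, sequence_id=gene)
        s = mo.best_hit(seq, sox2_pwm, sequence_id=gene)
        flags[gene] = MotifFlags(
            oct4=o.score >= oct4_threshold,
            sox2=s.score >= sox2_threshold,
            pore=bool(mo.match_fixed_motif(seq, "PORE", sequence_id=gene)),
            more=bool(mo.match_fixed_motif(seq, "MORE", sequence_id=gene)),
            best_oct4_score=o.score,
            best_sox2_score=s.score,
            best_oct4_offset=o.offset,
            best_sox2_offset=s.offset,
        )
    return flags, unscanned


def assign_module(
    flags: MotifFlags, module1_max_spacing: int | None = None
) -> tuple[int, frozenset[int]]:
    """Deterministic module assignment from motif flags.

    Returns (primary module in 1..4, overlay set among {5, 6}); the
    overlays are independent of the primary assignment. By default
    module 1 only requires co-occurrence of OCT4 and SOX2 motifs
    anywhere in the scanned region; ``module1_max_spacing`` optionally
    demands the best hits lie within that many nt of each other
    (otherwise the gene falls back to module 2, OCT4-driven).
    """
    if flags.oct4 and flags.sox2:
        primary = 1
        if (
            module1_max_spacing is not None
            and flags.best_oct4_offset is not None
            and flags.best_sox2_offset is not None
            and abs(flags.best_oct4_offset - flags.best_sox2_offset) > module1_max_spacing
        ):
            primary = 2
    elif flags.oct4:
        primary = 2
    elif flags.sox2:
        primary = 3
    else:
        primary = 4
    overlays = set()
    if flags.pore:
        overlays.add(5)
    if flags.more:
        overlays.add(6)
    return primary, frozenset(overlays)


def integrate_regulation(
    gene_id: str,
    fold_change: float | None,
    threshold: float = 2.0,
) -> RegulationCall:
    """Regulation label from a knockdown/control fold change.

    fold >= threshold is up, fold <= 1/threshold is down (both
    boundaries inclusive), anything between is unchanged; a missing
    fold change yields 'unmeasured'.
    """
    if fold_change is None or (isinstance(fold_change, float) and np.isnan(fold_change)):
        return RegulationCall(gene_id, float("nan"), "unmeasured", threshold)
    if fold_change >= threshold:
        direction = "up"
    elif fold_change <= 1.0 / threshold:
        direction = "down"
    else:
        direction = "unchanged"
    return RegulationCall(gene_id, float(fold_change), direction, threshold)


def normalize_gene_id(gene_id: str) -> str:
    """Uppercase and strip a trailing transcript-version suffix (.N)."""
    g = gene_id.strip().upper()
    head, dot, tail = g.rpartition(".")
    if dot and tail.isdigit():
        return head
    return g


def compare_target_lists(lists: dict[str, set[str] | list[str]]) -> pd.DataFrame:
    """Pairwise and full intersection counts of named gene lists.

    Gene ids are normalized (case, version suffixes) before set
    algebra. Returns a long table with one row per list (its size), per
    pair (intersection size) and one row for the intersection of all
    lists — the numbers a Venn diagram would display.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists to compare")
    norm = {}
    for name, genes in lists.items():
        genes = {normalize_gene_id(g) for g in genes}
        if not genes:
            logger.warning("gene list %r is empty", name)
        norm[name] = genes
    names = list(norm)
    rows = [(n, "size", len(norm[n])) for n in names]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append((f"{a} & {b}", "pairwise", len(norm[a] & norm[b])))
    common = set.intersection(*norm.values())
    rows.append((" & ".join(names), "all", len(common)))
    return pd.DataFrame(rows, columns=["sets", "kind", "count"])


def classify_targets(
    sequences: dict[str, str],
    oct4_pwm: mo.Pwm,
    oct4_threshold: float,
    sox2_pwm: mo.Pwm,
    sox2_threshold: float,
    consensus_peaks: list[ConsensusPeak] | None = None,
    fold_changes: pd.DataFrame | None = None,
    regulation_threshold: float = 2.0,
) -> list[TargetGene]:
    """Full classification: motif scan + module + regulation per gene.

    ``fold_changes`` is the (gene_id, fold_change, ...) table produced
    by the expression helpers; genes absent from it are 'unmeasured'.
    Consensus peaks linked to a gene are attached with the best peak
    score across them.
    """
    flags, _ = scan_target_regions(
        sequences, oct4_pwm, oct4_threshold, sox2_pwm, sox2_threshold
    )
    peaks_by_gene: dict[str, list[ConsensusPeak]] = {}
    for cp in consensus_peaks or []:
        if cp.linked_gene is not None:
            peaks_by_gene.setdefault(cp.linked_gene, []).append(cp)
    folds = {}
    if fold_changes is not None:
        folds = dict(zip(fold_changes["gene_id"], fold_changes["fold_change"]))

    targets = []
    for gene, fl in flags.items():
        primary, overlays = assign_module(fl)
        gene_peaks = peaks_by_gene.get(gene, [])
        targets.append(
            TargetGene(
                gene_id=gene,
                flags=fl,
                primary_module=primary,
                overlay_modules=overlays,
                peaks=gene_peaks,
                best_peak_score=max((p.peak_score for p in gene_peaks), default=None),
                regulation=integrate_regulation(
                    gene, folds.get(gene), regulation_threshold
                ),
            )
        )
    return targets


def summarize_modules(targets: list[TargetGene]) -> dict:
    """Per-module counts and regulated-gene lists.

    Primary-module counts partition the classified genes; overlay
    counts (5, 6) are reported separately; regulated subsets are listed
    by direction within each primary module.
    """
    primary_counts = {m: 0 for m in (1, 2, 3, 4)}
    overlay_counts = {m: 0 for m in (5, 6)}
    regulated: dict[int, dict[str, list[str]]] = {
        m: {"up": [], "down": []} for m in (1, 2, 3, 4)
    }
    for t in targets:
        primary_counts[t.primary_module] += 1
        for m in t.overlay_modules:
            overlay_counts[m] += 1
        if t.regulation and t.regulation.direction in ("up", "down"):
            regulated[t.primary_module][t.regulation.direction].append(t.gene_id)
    return {
        "primary_counts": primary_counts,
        "overlay_counts": overlay_counts,
        "regulated": regulated,
        "n_classified": len(targets),
    }


def targets_to_frame(targets: list[TargetGene]) -> pd.DataFrame:
    """Flatten TargetGene records into the per-gene report table."""
    rows = []
    for t in targets:
        rows.append(
            {
                "gene_id": t.gene_id,
                "peak_score": t.best_peak_score,
                "best_oct4_score": t.flags.best_oct4_score,
                "best_sox2_score": t.flags.best_sox2_score,
                "pore": t.flags.pore,
                "more": t.flags.more,
                "primary_module": t.primary_module,
                "overlays": ",".join(str(m) for m in sorted(t.overlay_modules)),
                "regulation": t.regulation.direction if t.regulation else "unmeasured",
                "fold_change": t.regulation.fold_change if t.regulation else float("nan"),
            }
        )
    return pd.DataFrame(rows)
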
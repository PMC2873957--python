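"""Readers and writers for the pipeline's plain-text interchange formats.

Probe tables and expression tables are tab-delimited with headers; peak
and truth intervals are BED (0-based half-open); ratio tracks are
bedGraph; promoter sequences are FASTA (via Biopython); PWMs use the
JASPAR plain-text matrix format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import BASES, Pwm
from .peaks import ConsensusPeak
from .qcnorm import validate_measurements

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_fasta",
    "write_fasta",
    "read_expression",
    "write_expression",
    "write_bedgraph",
    "write_truth_bed",
    "write_consensus_bed",
    "read_jaspar",
    "write_jaspar",
    "write_qc_report",
]


def read_probe_table(path: str) -> pd.DataFrame:
    """Read and validate a probe-measurement TSV."""
    df = pd.read_csv(path, sep="\t")
    return validate_measurements(df)


def write_probe_table(df: pd.DataFrame, path: str) -> None:
    validate_measurements(df)
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str) -> dict[str, str]:
    """FASTA records as id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_expression(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "condition", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df


def write_expression(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bedgraph(track: pd.DataFrame, path: str, probe_length: int = 50) -> None:
    """Ratio track as bedGraph (0-based half-open probe intervals)."""
    with open(path, "w") as fh:
        for _, row in track.sort_values(["chrom", "pos"]).iterrows():
            start = int(row["pos"])
            fh.write(f"{row['chrom']}\t{start}\t{start + probe_length}\t{row['ratio']:.6g}\n")


def write_truth_bed(events, layout, path: str) -> None:
    """Planted events as BED6 (score = strength, strand '.')."""
    chrom = dict(zip(layout.tss["promoter_id"], layout.tss["chrom"]))
    with open(path, "w") as fh:
        for ev in events:
            start = ev.center - ev.fragment_size
            end = ev.center + ev.fragment_size
            fh.write(
                f"{chrom[ev.promoter_id]}\t{start}\t{end}\t{ev.promoter_id}"
                f"\t{ev.strength:g}\t.\n"
            )


def write_consensus_bed(consensus: list[ConsensusPeak], path: str) -> None:
    """Consensus peaks as BED6+ with score = peak_score x 1000.

    Extra columns: detection count, denominator, linked gene and signed
    TSS distance.
    """
    with open(path, "w") as fh:
        for cp in sorted(consensus, key=lambda c: (c.chrom, c.start)):
            name = cp.linked_gene or "."
            fh.write(
                f"{cp.chrom}\t{cp.start}\t{cp.end}\t{name}\t"
                f"{round(cp.peak_score * 1000)}\t.\t{len(cp.detections)}\t"
                f"{cp.n_detectors * cp.n_replicates}\t"
                f"{cp.distance_to_tss if cp.distance_to_tss is not None else '.'}\n"
            )


def write_motif_hits(hits, path: str) -> None:
    """Motif hits as TSV (sequence_id, offset, strand, motif, score)."""
    with open(path, "w") as fh:
        fh.write("sequence_id\toffset\tstrand\tmotif\tscore\n")
        for h in hits:
            score = "" if h.score is None else f"{h.score:.4f}"
            fh.write(f"{h.sequence_id}\t{h.offset}\t{h.strand}\t{h.motif}\t{score}\n")


def read_consensus_bed(path: str) -> list[ConsensusPeak]:
    """Round-trip reader for the BED6+ written by write_consensus_bed."""
    out: list[ConsensusPeak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{ln}: expected 9 BED6+ columns")
            chrom, start, end, name, _score, _strand, ndet, denom, dist = fields[:9]
            n_det = int(ndet)
            out.append(
                ConsensusPeak(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    # detector labels are not stored in BED; synthesize
                    # distinct placeholders so the score round-trips
                    detections=frozenset(("det", i) for i in range(n_det)),
                    n_detectors=1,
                    n_replicates=int(denom),
                    linked_gene=None if name == "." else name,
                    distance_to_tss=None if dist == "." else int(dist),
                )
            )
    return out


def write_jaspar(pwm: Pwm, path: str, counts_scale: int = 100) -> None:
    """PWM in JASPAR plain-text format (probabilities x counts_scale)."""
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, base in enumerate(BASES):
            vals = "  ".join(f"{v * counts_scale:8.3f}" for v in pwm.probs[i])
            fh.write(f"{base}  [ {vals} ]\n")


def read_jaspar(path: str) -> Pwm:
    """Read a JASPAR-style count/probability matrix; columns renormalized."""
    name = "motif"
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            base = line[0].upper()
            inner = line[line.index("[") + 1 : line.rindex("]")]
            rows[base] = [float(v) for v in inner.split()]
    if set(rows) != set(BASES):
        raise ValueError(f"JASPAR matrix must have rows {BASES}, got {sorted(rows)}")
    mat = np.array([rows[b] for b in BASES], dtype=float)
    return Pwm(mat / mat.sum(axis=0), name=name)


def write_qc_report(report, path: str) -> None:
    """QC report (per-array correlations + exclusions) as TSV."""
    report.per_array.to_csv(path, sep="\t", index=False)
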
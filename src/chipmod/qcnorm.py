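"""Array QC, quantile normalization, ratio tracks and fold-change helpers.

Two-channel promoter arrays are normalized array-wise: the ChIP and
input channels of one physical hybridization are quantile-normalized
together, so both channels share the identical multiset of values (the
across-channel mean order statistics) while within-channel ranks are
preserved. Pearson correlation between the two channels is the QC
statistic: well-behaved hybridizations sit at high r, and an array whose
raw channel correlation falls below the exclusion threshold is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "quantile_normalize",
    "normalize_measurements",
    "qc_correlations",
    "compute_ratio_tracks",
    "qpcr_fold_enrichment",
    "expression_fold_changes",
]

REQUIRED_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "array_id",
    "replicate_id",
    "chip_intensity",
    "input_intensity",
)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Check the probe-measurement table contract.

    Intensities must be finite and strictly positive and
    (probe_id, array_id, replicate_id) must be unique; offending rows
    are reported by index in the raised error.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table is missing columns: {missing}")
    intens = df[["chip_intensity", "input_intensity"]].to_numpy(dtype=float)
    bad = ~np.isfinite(intens) | (intens <= 0)
    if bad.any():
        rows = df.index[bad.any(axis=1)].tolist()
        raise ValueError(
            f"non-positive or non-finite intensities in rows {rows[:10]}"
            + ("..." if len(rows) > 10 else "")
        )
    dup = df.duplicated(subset=["probe_id", "array_id", "replicate_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (probe_id, array_id, replicate_id) rows: "
            f"{df.index[dup].tolist()[:10]}"
        )
    return df


def quantile_normalize(columns: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Quantile-normalize an (n probes x m columns) intensity matrix.

    Each column's sorted values are replaced by the across-column mean
    of sorted values, so afterwards every column carries the identical
    multiset (the mean order statistics) and within-column ranks are
    preserved. Ties receive the mean of the target order statistics over
    the tied ranks, which makes the transform idempotent.
    """
    as_frame = isinstance(columns, pd.DataFrame)
    x = np.asarray(columns, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix of intensity columns")
    if not np.isfinite(x).all():
        raise ValueError("intensity matrix contains NaN or infinite values")
    if (x <= 0).any():
        raise ValueError("intensities must be strictly positive")

    target = np.sort(x, axis=0).mean(axis=1)  # mean order statistics
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        # average ranks (1-based); fractional ranks from ties interpolate
        # linearly between the neighbouring target order statistics
        ranks = stats.rankdata(x[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        out[:, j] = target[lo] * (1 - frac) + target[hi] * frac
    if as_frame:
        return pd.DataFrame(out, index=columns.index, columns=columns.columns)
    return out


def normalize_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Array-wise two-channel quantile normalization of a probe table.

    The chip and input columns of each physical array (one array_id,
    replicate_id pair) are normalized together; arrays remain
    independent of each other.
    """
    validate_measurements(df)
    out = df.copy()
    for _, idx in df.groupby(["array_id", "replicate_id"]).groups.items():
        block = df.loc[idx, ["chip_intensity", "input_intensity"]]
        out.loc[idx, ["chip_intensity", "input_intensity"]] = quantile_normalize(
            block.to_numpy()
        )
    return out


@dataclass
class QcReport:
    """Per-array channel correlations and exclusion decisions."""

    per_array: pd.DataFrame  # array_id, replicate_id, r_raw, r_norm, excluded
    replicate_pairs: pd.DataFrame  # array_id, channel, rep_a, rep_b, r
    excluded: list[tuple[int, int]] = field(default_factory=list)
    threshold: float = 0.5


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def qc_correlations(df: pd.DataFrame, exclusion_threshold: float = 0.5) -> QcReport:
    """Pearson QC of every physical array, raw and quantile-normalized.

    For each (array_id, replicate_id) the chip-vs-input Pearson r is
    computed on raw and on normalized intensities; arrays whose raw r
    falls below ``exclusion_threshold`` (or is undefined through a
    zero-variance channel) are flagged excluded. Replicate-pair
    correlations per channel are reported for reproducibility review.
    """
    validate_measurements(df)
    norm = normalize_measurements(df)

    rows = []
    excluded: list[tuple[int, int]] = []
    for (arr, rep), idx in df.groupby(["array_id", "replicate_id"]).groups.items():
        if len(idx) < 3:
            raise ValueError(f"array ({arr}, {rep}) has fewer than 3 probes")
        r_raw = _safe_pearson(
            df.loc[idx, "chip_intensity"].to_numpy(),
            df.loc[idx, "input_intensity"].to_numpy(),
        )
        r_norm = _safe_pearson(
            norm.loc[idx, "chip_intensity"].to_numpy(),
            norm.loc[idx, "input_intensity"].to_numpy(),
        )
        drop = np.isnan(r_raw) or r_raw < exclusion_threshold
        if drop:
            excluded.append((arr, rep))
            logger.warning(
                "array (%s, rep %s) excluded: raw chip-vs-input r = %s",
                arr, rep, f"{r_raw:.3f}" if np.isfinite(r_raw) else "undefined",
            )
        rows.append((arr, rep, r_raw, r_norm, drop))
    per_array = pd.DataFrame(
        rows, columns=["array_id", "replicate_id", "r_raw", "r_norm", "excluded"]
    )

    pair_rows = []
    for channel in ("chip_intensity", "input_intensity"):
        wide = df.pivot_table(
            index=["probe_id", "array_id"], columns="replicate_id", values=channel
        )
        for arr, block in wide.groupby(level="array_id"):
            reps = [c for c in block.columns if block[c].notna().all()]
            for i, ra in enumerate(reps):
                for rb in reps[i + 1 :]:
                    r = _safe_pearson(block[ra].to_numpy(), block[rb].to_numpy())
                    pair_rows.append((arr, channel.split("_")[0], ra, rb, r))
    replicate_pairs = pd.DataFrame(
        pair_rows, columns=["array_id", "channel", "rep_a", "rep_b", "r"]
    )
    return QcReport(
        per_array=per_array,
        replicate_pairs=replicate_pairs,
        excluded=excluded,
        threshold=exclusion_threshold,
    )


def compute_ratio_tracks(df: pd.DataFrame, drop_arrays: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Per-probe ChIP/input fold enrichment from normalized measurements.

    Returns the probe table with a ``ratio`` column, keyed by
    (array_id, replicate_id); arrays listed in ``drop_arrays`` (e.g. QC
    failures) are removed.
    """
    validate_measurements(df)
    out = df.copy()
    if drop_arrays:
        mask = out.apply(
            lambda r: (r["array_id"], r["replicate_id"]) in set(drop_arrays), axis=1
        )
        out = out.loc[~mask].reset_index(drop=True)
    out["ratio"] = out["chip_intensity"] / out["input_intensity"]
    return out.drop(columns=["chip_intensity", "input_intensity"])


def qpcr_fold_enrichment(ct_input: float, ct_chip: float) -> float:
    """ChIP real-time-PCR fold enrichment, 2**(Ct(input) - Ct(ChIP))."""
    if not (np.isfinite(ct_input) and np.isfinite(ct_chip)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_input - ct_chip))


def expression_fold_changes(
    expr: pd.DataFrame,
    floor: float = 20.0,
    control: str = "control",
    condition: str = "knockdown",
) -> pd.DataFrame:
    """Per-gene knockdown/control fold change with a detection floor.

    Intensities below the floor (detection threshold S, default 20) are
    raised to it before forming the ratio, avoiding nonsense ratios from
    background-level signals. Genes missing either condition get a NaN
    fold change and are reported missing rather than raising.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    wide = expr.pivot_table(index="gene_id", columns="condition", values="intensity")
    rows = []
    for gene, row in wide.iterrows():
        ctrl = row.get(control, np.nan)
        cond = row.get(condition, np.nan)
        if np.isnan(ctrl) or np.isnan(cond):
            rows.append((gene, np.nan, True))
            logger.warning("gene %s missing a condition; fold change unavailable", gene)
            continue
        fold = max(cond, floor) / max(ctrl, floor)
        rows.append((gene, fold, False))
    return pd.DataFrame(rows, columns=["gene_id", "fold_change", "missing"])
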
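"""Seed-dependent off-target expression analysis.

Implements the downstream statistics applied to microarray or RNA-seq
expression tables after an siRNA transfection: QC flag filtering, low-TPM
exclusion, quantile normalization, per-transcript log2 fold changes against a
mock control (MA coordinates), empirical cumulative distributions, and a
Wilcoxon rank-sum comparison of seed-matched (SM) versus non-seed-matched
transcripts.  Also provides the two companion assay quantifications:
relative luciferase activity and the ddCt qPCR fold change.

The Wilcoxon rank-sum test is implemented in-repo (exact null enumeration for
small tie-free samples, otherwise a normal approximation with tie and
continuity corrections); the scipy implementation is used only as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from seedscreen.seed_match import SeedClassification

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "QcCriteria",
    "GroupComparison",
    "EcdfCurve",
    "OfftargetResult",
    "DEFAULT_FLAG_CRITERIA",
    "apply_flag_filter",
    "filter_low_tpm",
    "quantile_normalize",
    "compute_fold_changes",
    "wilcoxon_rank_sum",
    "ecdf",
    "offtarget_report",
    "relative_luc_activity",
    "ddct_fold_change",
]

#: Agilent-style feature-quality flags and the value each must take for a
#: probe to enter the analysis.
DEFAULT_FLAG_CRITERIA: dict[str, int] = {
    "ControlType": 0,
    "gIsPosAndSignif": 1,
    "gIsFeatNonUnifOL": 0,
    "gIsWellAboveBG": 1,
    "gIsSaturated": 0,
    "gIsFeatPopnOL": 0,
}


@dataclass(frozen=True)
class ExpressionTable:
    """Transcripts x samples expression values plus QC metadata.

    ``data`` holds one row per transcript with a ``transcript_id`` column,
    the named flag columns (microarray only), an optional annotation column
    of systematic names, and the named sample columns (non-negative, finite).
    """

    data: pd.DataFrame
    sample_columns: tuple[str, ...]
    flag_columns: tuple[str, ...] = ()
    platform: Literal["microarray", "rnaseq"] = "microarray"
    annotation_column: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_columns", tuple(self.sample_columns))
        object.__setattr__(self, "flag_columns", tuple(self.flag_columns))
        if "transcript_id" not in self.data.columns:
            raise ValueError("expression table needs a transcript_id column")
        for col in self.sample_columns + self.flag_columns:
            if col not in self.data.columns:
                raise ValueError(f"missing column {col!r}")
        vals = self.data[list(self.sample_columns)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite expression values")
        if np.any(vals < 0):
            raise ValueError("negative expression values")
        if self.platform not in ("microarray", "rnaseq"):
            raise ValueError(f"unknown platform {self.platform!r}")

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: transcript_id, flag columns, then sample columns."""
        cols = ["transcript_id"]
        if self.annotation_column:
            cols.append(self.annotation_column)
        cols += list(self.flag_columns) + list(self.sample_columns)
        self.data[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        platform: Literal["microarray", "rnaseq"] = "microarray",
        annotation_column: str | None = None,
    ) -> "ExpressionTable":
        """Read a TSV written by :meth:`to_tsv` (flag columns recognized by name)."""
        df = pd.read_csv(path, sep="\t")
        flags = tuple(c for c in df.columns if c in DEFAULT_FLAG_CRITERIA)
        meta = {"transcript_id", annotation_column, *flags} - {None}
        samples = tuple(c for c in df.columns if c not in meta)
        return cls(
            data=df,
            sample_columns=samples,
            flag_columns=flags,
            platform=platform,
            annotation_column=annotation_column,
        )


@dataclass(frozen=True)
class QcCriteria:
    """Microarray feature-QC requirements: flag column -> required value."""

    flags: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FLAG_CRITERIA)
    )
    systematic_name_prefix: str | None = "NM_"


@dataclass(frozen=True)
class GroupComparison:
    """SM vs non-SM fold-change comparison by the Wilcoxon rank-sum test."""

    n_sm: int
    n_other: int
    rank_sum_w: float
    u_sm: float
    u_other: float
    z_value: float | None
    p_two_sided: float
    method: Literal["exact", "normal_approx"]
    mean_log2fc_sm: float
    mean_log2fc_other: float


@dataclass(frozen=True)
class EcdfCurve:
    """Right-continuous empirical CDF: cumulative fraction at each sorted value."""

    values: np.ndarray
    fractions: np.ndarray

    def __call__(self, x: float) -> float:
        idx = np.searchsorted(self.values, x, side="right")
        return 0.0 if idx == 0 else float(self.fractions[idx - 1])


@dataclass(frozen=True)
class OfftargetResult:
    """Joined MA table, per-group ECDFs and the rank-sum comparison."""

    ma_table: pd.DataFrame
    comparison: GroupComparison | None
    ecdf_sm: EcdfCurve | None
    ecdf_other: EcdfCurve | None
    warnings: tuple[str, ...] = ()


def apply_flag_filter(
    table: ExpressionTable, criteria: QcCriteria | None = None
) -> ExpressionTable:
    """Keep only rows whose QC flags all take their required values.

    When the table carries an annotation column, rows whose systematic name
    does not start with ``criteria.systematic_name_prefix`` (curated mRNA
    accessions, ``NM_``) are also removed.  Per-criterion removal counts are
    logged at INFO level.
    """
    if criteria is None:
        criteria = QcCriteria()
    df = table.data
    keep = pd.Series(True, index=df.index)
    for col, required in criteria.flags.items():
        if col not in df.columns:
            raise ValueError(f"flag column {col!r} missing from table")
        fails = df[col] != required
        logger.info("flag filter %s != %d removed %d rows", col, required, int((keep & fails).sum()))
        keep &= ~fails
    if criteria.systematic_name_prefix and table.annotation_column:
        named = df[table.annotation_column].astype(str).str.startswith(
            criteria.systematic_name_prefix
        )
        logger.info(
            "systematic-name prefix %r removed %d rows",
            criteria.systematic_name_prefix,
            int((keep & ~named).sum()),
        )
        keep &= named
    return replace(table, data=df[keep].reset_index(drop=True))


def filter_low_tpm(
    table: ExpressionTable,
    threshold: float = 10.0,
    reference_sample: str | None = None,
) -> ExpressionTable:
    """Exclude transcripts whose TPM in the reference sample is below threshold.

    ``reference_sample`` defaults to the first sample column (conventionally
    the mock control).  A transcript with TPM exactly at the threshold is
    kept ("below" is strict).
    """
    if table.platform != "rnaseq":
        raise ValueError("TPM filtering applies to rnaseq tables only")
    if reference_sample is None:
        reference_sample = table.sample_columns[0]
    if reference_sample not in table.sample_columns:
        raise ValueError(f"unknown reference sample {reference_sample!r}")
    keep = table.data[reference_sample] >= threshold
    return replace(table, data=table.data[keep].reset_index(drop=True))


def _quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a numeric frame (ties -> rank-mean values)."""
    arr = values.to_numpy(dtype=float)
    n, _ = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        # fractional (tied) ranks interpolate between reference quantiles
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(table: ExpressionTable | pd.DataFrame):
    """Force all sample columns to share the same value distribution by rank.

    Each column's sorted values are replaced by the across-column mean of the
    values at the same rank; tied values receive the average of the tied
    ranks' reference values, preserving within-column rank order.  Accepts an
    :class:`ExpressionTable` (returns the same type) or a plain numeric
    DataFrame.
    """
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 2:
            raise ValueError("quantile normalization needs >= 2 sample columns")
        return _quantile_normalize_frame(table)
    if len(table.sample_columns) < 2:
        raise ValueError("quantile normalization needs >= 2 sample columns")
    df = table.data.copy()
    df[list(table.sample_columns)] = _quantile_normalize_frame(
        df[list(table.sample_columns)]
    )
    return replace(table, data=df)


def compute_fold_changes(
    table: ExpressionTable,
    treated: str,
    mock: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-transcript MA coordinates for a treated vs mock comparison.

    Returns a frame with ``transcript_id``, ``log2fc`` =
    log2((treated + eps) / (mock + eps)) and ``avg_log_intensity`` = the mean
    of log10(value + eps) over the two samples.  ``pseudocount`` (eps) may be
    zero only when every value is strictly positive.
    """
    for col in (treated, mock):
        if col not in table.sample_columns:
            raise ValueError(f"unknown sample column {col!r}")
    t = table.data[treated].to_numpy(dtype=float)
    m = table.data[mock].to_numpy(dtype=float)
    if np.any(t < 0) or np.any(m < 0):
        raise ValueError("negative expression values")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (np.any(t == 0) or np.any(m == 0)):
        raise ValueError("zero values require a positive pseudocount")
    log2fc = np.log2(t + pseudocount) - np.log2(m + pseudocount)
    avg = 0.5 * (np.log10(t + pseudocount) + np.log10(m + pseudocount))
    return pd.DataFrame(
        {
            "transcript_id": table.data["transcript_id"].to_numpy(),
            "log2fc": log2fc,
            "avg_log_intensity": avg,
        }
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test (in-repo implementation)
# ---------------------------------------------------------------------------


def _exact_u_sf_cdf(n1: int, n2: int, u: float) -> tuple[float, float]:
    """P(U <= u) and P(U >= u) under the exact tie-free null distribution.

    Dynamic program over the generating function of the Mann-Whitney U
    statistic: counts[k] after including m of the n2 'other' items satisfy the
    standard recurrence for the number of (n1, n2) rank arrangements with a
    given U.
    """
    total = n1 * n2
    # f(m, n, u): arrangements of m group-a and n group-b ranks with U = u.
    # Conditioning on whether the top pooled rank is an a or a b item gives
    # f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u).
    table = np.zeros((n1 + 1, total + 1), dtype=float)  # f(m, 0, u)
    table[:, 0] = 1.0
    for n in range(1, n2 + 1):
        new = np.zeros_like(table)
        new[0, 0] = 1.0
        for m in range(1, n1 + 1):
            new[m] = table[m]
            new[m, n:] += new[m - 1, : total + 1 - n]
        table = new
    counts = table[n1]
    counts /= counts.sum()
    ks = np.arange(total + 1)
    return float(counts[ks <= u].sum()), float(counts[ks >= u].sum())


def wilcoxon_rank_sum(
    values_a: Sequence[float],
    values_b: Sequence[float],
    mode: Literal["auto", "exact", "normal_approx"] = "auto",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    ``auto`` uses exact enumeration of the null distribution when
    ``min(n_a, n_b) <= 10`` and the pooled values are tie-free, otherwise the
    normal approximation with tie correction and a 0.5 continuity correction.
    Group *a* plays the seed-matched role in the returned
    :class:`GroupComparison`; ``u_sm + u_other == n_sm * n_other`` always.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    u_a = w - n1 * (n1 + 1) / 2.0
    u_b = n1 * n2 - u_a
    has_ties = np.unique(pooled).size < pooled.size

    if mode == "auto":
        mode = "exact" if (min(n1, n2) <= 10 and not has_ties) else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        cdf, sf = _exact_u_sf_cdf(n1, n2, u_a)
        p = min(1.0, 2.0 * min(cdf, sf))
        z: float | None = None
        method: Literal["exact", "normal_approx"] = "exact"
    elif mode == "normal_approx":
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            # all pooled values identical: the samples cannot differ
            z, p = 0.0, 1.0
        else:
            diff = u_a - mu
            cc = 0.5 * math.copysign(1.0, diff) if diff != 0 else 0.0
            z = (diff - cc) / math.sqrt(var)
            p = min(1.0, float(2.0 * stats.norm.sf(abs(z))))
        method = "normal_approx"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return GroupComparison(
        n_sm=n1,
        n_other=n2,
        rank_sum_w=w,
        u_sm=u_a,
        u_other=u_b,
        z_value=z,
        p_two_sided=p,
        method=method,
        mean_log2fc_sm=float(a.mean()),
        mean_log2fc_other=float(b.mean()),
    )


def ecdf(values: Sequence[float]) -> EcdfCurve:
    """Empirical CDF of a sample: fractions at the sorted unique values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ecdf of an empty sample")
    uniq, counts = np.unique(arr, return_counts=True)
    return EcdfCurve(values=uniq, fractions=np.cumsum(counts) / arr.size)


def offtarget_report(
    table: ExpressionTable,
    classification: Sequence[SeedClassification],
    treated: str,
    mock: str,
    on_target_ids: Sequence[str] = (),
    pseudocount: float = 1.0,
    out_dir: str | Path | None = None,
) -> OfftargetResult:
    """Full SM vs non-SM off-target comparison for one treated/mock pair.

    Joins per-transcript log2 fold changes to seed-match labels, excludes any
    supplied on-target transcript(s) from both groups, and computes the
    Wilcoxon rank-sum comparison plus per-group ECDFs.  When ``out_dir`` is
    given, writes ``ma.tsv`` (transcript_id, log2fc, avg_log_intensity,
    is_sm), ``ecdf_sm.tsv``, ``ecdf_other.tsv`` and ``summary.json``.

    Transcripts absent from the classification are dropped with a warning; a
    table with no SM transcripts yields a result whose comparison is ``None``.
    """
    sm_by_id = {c.transcript_id: c.is_sm for c in classification}
    ma = compute_fold_changes(table, treated, mock, pseudocount=pseudocount)
    warnings: list[str] = []

    known = ma["transcript_id"].isin(sm_by_id)
    if not known.all():
        warnings.append(
            f"{int((~known).sum())} transcripts missing from classification; dropped"
        )
        ma = ma[known].reset_index(drop=True)
    if ma.empty:
        raise ValueError("classification covers no transcript in the table")
    ma["is_sm"] = ma["transcript_id"].map(sm_by_id).astype(bool)

    analysis = ma[~ma["transcript_id"].isin(set(on_target_ids))]
    sm_vals = analysis.loc[analysis["is_sm"], "log2fc"].to_numpy()
    other_vals = analysis.loc[~analysis["is_sm"], "log2fc"].to_numpy()

    comparison = ecdf_sm = ecdf_other = None
    if sm_vals.size == 0 or other_vals.size == 0:
        warnings.append("one comparison group is empty; p-value undefined")
    else:
        comparison = wilcoxon_rank_sum(sm_vals, other_vals)
        ecdf_sm = ecdf(sm_vals)
        ecdf_other = ecdf(other_vals)

    result = OfftargetResult(
        ma_table=ma,
        comparison=comparison,
        ecdf_sm=ecdf_sm,
        ecdf_other=ecdf_other,
        warnings=tuple(warnings),
    )
    if out_dir is not None:
        _write_offtarget_outputs(result, Path(out_dir))
    return result


def _write_offtarget_outputs(result: OfftargetResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.ma_table.to_csv(out_dir / "ma.tsv", sep="\t", index=False)
    for name, curve in (("ecdf_sm", result.ecdf_sm), ("ecdf_other", result.ecdf_other)):
        if curve is not None:
            pd.DataFrame(
                {"log2fc": curve.values, "cumulative_fraction": curve.fractions}
            ).to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    c = result.comparison
    summary = {
        "n_transcripts": int(len(result.ma_table)),
        "warnings": list(result.warnings),
        "comparison": None
        if c is None
        else {
            "n_sm": c.n_sm,
            "n_other": c.n_other,
            "rank_sum_w": c.rank_sum_w,
            "u_sm": c.u_sm,
            "u_other": c.u_other,
            "z_value": c.z_value,
            "p_two_sided": c.p_two_sided,
            "method": c.method,
            "mean_log2fc_sm": c.mean_log2fc_sm,
            "mean_log2fc_other": c.mean_log2fc_other,
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))


def relative_luc_activity(renilla, firefly, control_ratio):
    """Relative luciferase activity in percent of the control siRNA.

    The readout is the Renilla/firefly ratio (Renilla carries the target
    site; firefly is the transfection control), expressed as a percentage of
    ``control_ratio`` — the same ratio measured with a neutral control siRNA.
    Accepts scalars or arrays.
    """
    renilla = np.asarray(renilla, dtype=float)
    firefly = np.asarray(firefly, dtype=float)
    if np.any(firefly <= 0):
        raise ValueError("firefly activity must be positive")
    if not np.all(np.asarray(control_ratio) > 0):
        raise ValueError("control ratio must be positive")
    out = 100.0 * (renilla / firefly) / control_ratio
    return float(out) if out.ndim == 0 else out


def ddct_fold_change(
    ct_target_sample,
    ct_ref_sample,
    ct_target_mock,
    ct_ref_mock,
):
    """Relative expression by the ddCt method: 2**(-ddCt).

    ddCt = (Ct_target - Ct_reference) in the treated sample minus the same
    difference in the mock control; the reference gene (e.g. GAPDH) cancels
    loading differences.  Accepts scalars or arrays; values must be finite.
    """
    arrs = [np.asarray(x, dtype=float) for x in (
        ct_target_sample, ct_ref_sample, ct_target_mock, ct_ref_mock)]
    if not all(np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("Ct values must be finite")
    ddct = (arrs[0] - arrs[1]) - (arrs[2] - arrs[3])
    out = np.exp2(-ddct)
    return float(out) if out.ndim == 0 else out
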
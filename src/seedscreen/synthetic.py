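"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study's three measurement layers with known truth
labels so that each analysis stage can be validated end to end:

* UV melting curves from the two-state duplex model with linear hypochromic
  baselines and Gaussian absorbance noise, over a concentration series;
* 3'UTR sequence sets with a controlled fraction of transcripts carrying a
  planted seed-complement motif, against motif-free rejection-sampled
  background sequence;
* mock/treated expression tables with a strong log-scale knockdown applied to
  the on-target transcript and a smaller shift applied to seed-matched
  transcripts (microarray tables carry Agilent-style QC flag columns);
* luciferase plate and qPCR Ct tables with known fold changes.

All randomness flows from a single integer seed per spec; child streams are
derived deterministically per curve/transcript, so identical specs produce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from seedscreen.duplex_thermo import MeltingCurve, two_state_fraction
from seedscreen.expression import DEFAULT_FLAG_CRITERIA, ExpressionTable
from seedscreen.seed_match import _normalize_rna, scan_sequence

__all__ = [
    "MeltSimSpec",
    "TranscriptomeSimSpec",
    "ExpressionSimSpec",
    "TruthTable",
    "gen_melting_curves",
    "gen_utr_set",
    "gen_expression_table",
    "gen_assay_tables",
]

# Study-condition defaults: 3, 6, 9 and 12 uM per strand -> total single-strand
# concentrations of 6, 12, 18 and 24 uM; 15-90 C at 0.5 C steps.
DEFAULT_CONC_SERIES_M = (6e-6, 12e-6, 18e-6, 24e-6)
DEFAULT_TEMP_GRID_C = tuple(np.arange(15.0, 90.0 + 0.25, 0.5))


@dataclass(frozen=True)
class MeltSimSpec:
    """Parameters for simulating a concentration series of UV melting curves.

    ``dH_kcal_per_mol`` / ``dS_cal_per_mol_K`` are association-signed (both
    negative for a melting duplex).  Baselines are (slope, intercept) lines in
    arbitrary absorbance units vs degrees C; the single-strand line must lie
    above the duplex line over the whole grid (hyperchromicity: A260 rises on
    melting).
    """

    dH_kcal_per_mol: float
    dS_cal_per_mol_K: float
    conc_series_M: tuple[float, ...] = DEFAULT_CONC_SERIES_M
    temp_grid_C: tuple[float, ...] = DEFAULT_TEMP_GRID_C
    baseline_ds: tuple[float, float] = (0.0002, 0.80)
    baseline_ss: tuple[float, float] = (0.0004, 1.00)
    noise_sd_au: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.dH_kcal_per_mol, self.dS_cal_per_mol_K, self.noise_sd_au,
                *self.baseline_ds, *self.baseline_ss]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite melting simulation parameters")
        t = np.asarray(self.temp_grid_C, dtype=float)
        if t.size < 10 or not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing, >= 10 points")
        if any(c <= 0 or not math.isfinite(c) for c in self.conc_series_M):
            raise ValueError("concentrations must be positive")
        if self.noise_sd_au < 0:
            raise ValueError("noise sd must be >= 0")
        ds = self.baseline_ds[0] * t + self.baseline_ds[1]
        ss = self.baseline_ss[0] * t + self.baseline_ss[1]
        if not np.all(ss > ds):
            raise ValueError("single-strand baseline must lie above duplex baseline")


@dataclass(frozen=True)
class TranscriptomeSimSpec:
    """Parameters for a synthetic 3'UTR set with planted seed matches."""

    n_transcripts: int
    motif: str
    planted_fraction: float = 0.15
    utr_length_range: tuple[int, int] = (200, 1500)
    gc_fraction: float = 0.5
    on_target_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("need at least one transcript")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        motif = _normalize_rna(self.motif)
        if set(motif) - set("ACGU"):
            raise ValueError("motif alphabet must be within {A,C,G,U/T}")
        if len(motif) not in (7, 8):
            raise ValueError("motif length must be 7 or 8")
        object.__setattr__(self, "motif", motif)
        lo, hi = self.utr_length_range
        if lo < len(motif) or hi < lo:
            raise ValueError("UTR length range invalid or shorter than the motif")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters for a mock/treated expression table over a truth table."""

    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    on_target_log2fc: float = -2.0
    sm_log2fc: float = -0.5
    noise_log2_sd: float = 0.3
    platform: str = "microarray"
    fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_log2_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.baseline_log2_sd < 0:
            raise ValueError("baseline sd must be >= 0")
        if self.platform not in ("microarray", "rnaseq"):
            raise ValueError("platform must be 'microarray' or 'rnaseq'")
        if not 0.0 <= self.fail_fraction < 1.0:
            raise ValueError("fail_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for a synthetic transcriptome.

    One row per transcript: ``transcript_id``, ``is_sm``,
    ``n_planted_motifs`` (actual motif occurrences in the emitted UTR),
    ``is_on_target`` and ``true_log2fc`` (the applied expression effect,
    zero until an expression table is generated).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"transcript_id", "is_sm", "n_planted_motifs", "is_on_target",
                    "true_log2fc"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"truth table missing columns {sorted(missing)}")
        if not (self.df["is_sm"] == (self.df["n_planted_motifs"] >= 1)).all():
            raise ValueError("is_sm inconsistent with n_planted_motifs")

    @property
    def n_sm(self) -> int:
        return int(self.df["is_sm"].sum())

    @property
    def on_target_ids(self) -> tuple[str, ...]:
        return tuple(self.df.loc[self.df["is_on_target"], "transcript_id"])


def gen_melting_curves(spec: MeltSimSpec) -> list[MeltingCurve]:
    """Simulate one melting curve per concentration in the series.

    The noiseless signal is ``alpha(T)*ds(T) + (1 - alpha(T))*ss(T)`` with
    ``alpha`` the two-state duplex fraction at that concentration; Gaussian
    noise of sd ``noise_sd_au`` is added on top.  Curve labels record the
    generating parameters.
    """
    t_C = np.asarray(spec.temp_grid_C, dtype=float)
    t_K = t_C + 273.15
    ds = spec.baseline_ds[0] * t_C + spec.baseline_ds[1]
    ss = spec.baseline_ss[0] * t_C + spec.baseline_ss[1]
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.conc_series_M))
    curves = []
    for ct, ss_seed in zip(spec.conc_series_M, streams):
        alpha = two_state_fraction(
            spec.dH_kcal_per_mol, spec.dS_cal_per_mol_K, ct, t_K
        )
        signal = alpha * ds + (1.0 - alpha) * ss
        if spec.noise_sd_au > 0:
            signal = signal + np.random.default_rng(ss_seed).normal(
                0.0, spec.noise_sd_au, size=signal.size
            )
        curves.append(
            MeltingCurve(
                temperature_C=t_C,
                absorbance_au=signal,
                total_strand_conc_M=ct,
                label=(
                    f"sim dH={spec.dH_kcal_per_mol} kcal/mol "
                    f"dS={spec.dS_cal_per_mol_K} cal/(mol*K) Ct={ct} M "
                    f"noise={spec.noise_sd_au} seed={spec.seed}"
                ),
            )
        )
    return curves


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.array(list("ACGU"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))


def gen_utr_set(spec: TranscriptomeSimSpec) -> tuple[list[SeqRecord], TruthTable]:
    """Generate a 3'UTR FASTA set with a controlled planted-motif fraction.

    Exactly ``round(n * planted_fraction)`` transcripts carry the motif,
    overwritten at a uniform random offset into an i.i.d. background at the
    given GC fraction; every other transcript is rejection-sampled until it
    is motif-free.  ``n_planted_motifs`` in the truth table counts actual
    occurrences in the emitted sequence (chance overlaps included), so a
    naive substring scan over the FASTA reproduces ``is_sm`` exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_transcripts
    motif = spec.motif
    n_planted = round(n * spec.planted_fraction)
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=n_planted, replace=False)] = True

    width = max(6, len(str(n)))
    ids = [f"TX{str(i + 1).zfill(width)}" for i in range(n)]
    if spec.on_target_id is not None and spec.on_target_id not in ids:
        raise ValueError(f"on_target_id {spec.on_target_id!r} not among generated ids")

    records: list[SeqRecord] = []
    rows = []
    for i, rec_id in enumerate(ids):
        length = int(rng.integers(spec.utr_length_range[0], spec.utr_length_range[1] + 1))
        if planted[i]:
            seq = _random_seq(rng, length, spec.gc_fraction)
            offset = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:offset] + motif + seq[offset + len(motif):]
        else:
            while True:
                seq = _random_seq(rng, length, spec.gc_fraction)
                if motif not in seq:
                    break
        n_occ = len(scan_sequence(seq, motif))
        records.append(SeqRecord(Seq(seq), id=rec_id, description=""))
        rows.append((rec_id, bool(planted[i]), n_occ, rec_id == spec.on_target_id, 0.0))

    truth = TruthTable(
        pd.DataFrame(
            rows,
            columns=["transcript_id", "is_sm", "n_planted_motifs", "is_on_target",
                     "true_log2fc"],
        )
    )
    return records, truth


def gen_expression_table(
    truth: TruthTable, spec: ExpressionSimSpec
) -> tuple[ExpressionTable, TruthTable]:
    """Simulate mock and treated expression columns over a truth table.

    Mock expression is lognormal (``2**Normal(baseline_log2_mean,
    baseline_log2_sd)``); the treated column applies ``on_target_log2fc`` to
    the on-target transcript and ``sm_log2fc`` to every other seed-matched
    transcript, plus Gaussian log2 noise.  Microarray tables carry the six
    QC flag columns (all passing, except a ``fail_fraction`` of rows with one
    randomly failed flag) and an ``NM_``-prefixed systematic-name column.
    Returns the table and a truth copy with ``true_log2fc`` filled in.
    """
    if truth.df.empty:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    df = truth.df.copy()
    n = len(df)

    effect = np.where(
        df["is_on_target"], spec.on_target_log2fc,
        np.where(df["is_sm"], spec.sm_log2fc, 0.0),
    )
    df["true_log2fc"] = effect

    mock_log2 = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=n)
    noise = (
        rng.normal(0.0, spec.noise_log2_sd, size=n)
        if spec.noise_log2_sd > 0
        else np.zeros(n)
    )
    mock = np.exp2(mock_log2)
    treated = np.exp2(mock_log2 + effect + noise)

    out = pd.DataFrame({"transcript_id": df["transcript_id"].to_numpy()})
    flag_cols: tuple[str, ...] = ()
    annotation = None
    if spec.platform == "microarray":
        annotation = "SystematicName"
        out[annotation] = ["NM_" + tid for tid in out["transcript_id"]]
        for col, passing in DEFAULT_FLAG_CRITERIA.items():
            out[col] = passing
        flag_cols = tuple(DEFAULT_FLAG_CRITERIA)
        if spec.fail_fraction > 0:
            n_fail = round(n * spec.fail_fraction)
            fail_rows = rng.choice(n, size=n_fail, replace=False)
            which = rng.integers(0, len(flag_cols), size=n_fail)
            for row, col_idx in zip(fail_rows, which):
                col = flag_cols[col_idx]
                out.loc[row, col] = 1 - DEFAULT_FLAG_CRITERIA[col]
    out["mock"] = mock
    out["treated"] = treated

    table = ExpressionTable(
        data=out,
        sample_columns=("mock", "treated"),
        flag_columns=flag_cols,
        platform=spec.platform,
        annotation_column=annotation,
    )
    return table, TruthTable(df)


def gen_assay_tables(
    n_conditions: int = 4,
    effects: Sequence[float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate luciferase plate readings and qPCR Ct tables.

    ``effects`` are true log2 fold changes of the target readout per
    condition (default all zero).  The luciferase table has one row per
    condition with Renilla/firefly readings whose ratio is ``2**effect``
    times the control ratio; the Ct table has a leading ``mock`` row and one
    row per condition with target and GAPDH Ct values such that the ddCt
    fold change equals ``2**effect``.  ``noise`` is the sd of multiplicative
    log2 noise on luminescence and of additive noise on Ct values.
    """
    if n_conditions < 1:
        raise ValueError("need at least one condition")
    if effects is None:
        effects = np.zeros(n_conditions)
    effects = np.asarray(effects, dtype=float)
    if effects.size != n_conditions:
        raise ValueError("effects length must equal n_conditions")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    firefly_base, ratio_base = 1000.0, 1.0
    conditions = [f"cond_{i + 1:02d}" for i in range(n_conditions)]
    firefly = firefly_base * np.exp2(rng.normal(0, noise, n_conditions)) \
        if noise > 0 else np.full(n_conditions, firefly_base)
    ren_noise = rng.normal(0, noise, n_conditions) if noise > 0 else np.zeros(n_conditions)
    renilla = firefly * ratio_base * np.exp2(effects + ren_noise)
    luc = pd.DataFrame(
        {
            "condition": conditions,
            "renilla": renilla,
            "firefly": firefly,
            "true_log2fc": effects,
        }
    )

    ct_target_mock, ct_ref_mock = 20.0, 15.0
    rows = [("mock", ct_target_mock, ct_ref_mock, 0.0)]
    ct_noise = rng.normal(0, noise, (n_conditions, 2)) if noise > 0 else np.zeros((n_conditions, 2))
    for i, cond in enumerate(conditions):
        rows.append(
            (
                cond,
                ct_target_mock - effects[i] + ct_noise[i, 0],
                ct_ref_mock + ct_noise[i, 1],
                effects[i],
            )
        )
    ct = pd.DataFrame(rows, columns=["condition", "ct_target", "ct_gapdh", "true_log2fc"])
    return luc, ct
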
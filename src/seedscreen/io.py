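"""File-format helpers: melting-curve CSV (+ JSON sidecar), UTR FASTA, reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from seedscreen.duplex_thermo import MeltingCurve

__all__ = [
    "write_melting_curves_csv",
    "read_melting_curves_csv",
    "write_utr_fasta",
]


def write_melting_curves_csv(curves: Sequence[MeltingCurve], path: str | Path) -> Path:
    """Write curves as long-format CSV with a JSON sidecar of per-curve Ct.

    Columns: ``temperature_C, absorbance, curve_id``.  The sidecar
    ``<path>.meta.json`` maps each curve id to its total single-strand
    concentration (mol/L) and label.
    """
    path = Path(path)
    frames = []
    meta = {}
    for i, curve in enumerate(curves):
        cid = f"curve_{i + 1:02d}"
        frames.append(
            pd.DataFrame(
                {
                    "temperature_C": curve.temperature_C,
                    "absorbance": curve.absorbance_au,
                    "curve_id": cid,
                }
            )
        )
        meta[cid] = {
            "total_strand_conc_M": curve.total_strand_conc_M,
            "label": curve.label,
        }
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_melting_curves_csv(path: str | Path) -> list[MeltingCurve]:
    """Read melting curves written by :func:`write_melting_curves_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing concentration sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    curves = []
    for cid, group in df.groupby("curve_id", sort=False):
        if cid not in meta:
            raise ValueError(f"curve {cid!r} absent from sidecar {sidecar}")
        curves.append(
            MeltingCurve(
                temperature_C=group["temperature_C"].to_numpy(),
                absorbance_au=group["absorbance"].to_numpy(),
                total_strand_conc_M=float(meta[cid]["total_strand_conc_M"]),
                label=str(meta[cid].get("label", cid)),
            )
        )
    return curves


def write_utr_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    """Write UTR records as 60-column-wrapped FASTA."""
    SeqIO.write(records, str(path), "fasta")
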
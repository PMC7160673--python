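"""Plain-text table I/O for plates, profiles, titrations and abundances.

Plate tables are long-format TSV with one row per replicate well:
``reader_id, methyl_order, fixed_position, fixed_residue, pool, replicate,
signal, gst_signal``.  Pool rows set ``pool`` true and leave the set fields
empty.  Profiles are written as two TSV matrices (raw and normalized, rows =
flank offsets, columns = residues) plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fp import TitrationSeries
from .library import KmeSetID
from .signal import PlateMeasurement, ReaderProfile

__all__ = [
    "write_plate_table",
    "read_plate_table",
    "write_profile",
    "read_profile",
    "write_titrations",
    "read_titrations",
    "read_abundance",
]

PLATE_COLUMNS = [
    "reader_id",
    "methyl_order",
    "fixed_position",
    "fixed_residue",
    "pool",
    "replicate",
    "signal",
    "gst_signal",
]


def write_plate_table(measurements: Iterable[PlateMeasurement], path: str | Path) -> None:
    rows = []
    for m in measurements:
        for rep, sig in enumerate(m.replicate_signals, start=1):
            gst = m.gst_signals[rep - 1] if rep <= len(m.gst_signals) else np.nan
            rows.append(
                {
                    "reader_id": m.reader_id,
                    "methyl_order": m.methyl_order,
                    "fixed_position": "" if m.set_id is None else m.set_id.fixed_position,
                    "fixed_residue": "" if m.set_id is None else m.set_id.fixed_residue,
                    "pool": m.set_id is None,
                    "replicate": rep,
                    "signal": sig,
                    "gst_signal": gst,
                }
            )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_plate_table(path: str | Path) -> list[PlateMeasurement]:
    """Group replicate rows back into :class:`PlateMeasurement` objects."""
    df = pd.read_csv(path, sep="\t")
    out = []
    keys = ["reader_id", "methyl_order", "pool", "fixed_position", "fixed_residue"]
    for (reader, order, pool, pos, res), grp in df.groupby(keys, dropna=False, sort=False):
        grp = grp.sort_values("replicate")
        gst = grp["gst_signal"].dropna()
        common = dict(
            reader_id=str(reader),
            replicate_signals=tuple(grp["signal"].astype(float)),
            gst_signals=tuple(gst.astype(float)),
        )
        if bool(pool):
            out.append(PlateMeasurement(pool_order=int(order), **common))
        else:
            out.append(
                PlateMeasurement(
                    set_id=KmeSetID(int(order), int(float(pos)), str(res)), **common
                )
            )
    return out


def write_profile(profile: ReaderProfile, directory: str | Path, stem: str) -> dict[str, Path]:
    """Write raw/normalized matrices as TSV plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw": directory / f"{stem}.raw.tsv",
        "norm": directory / f"{stem}.norm.tsv",
        "meta": directory / f"{stem}.json",
    }

    def _fmt(mat: pd.DataFrame, path: Path) -> None:
        out = mat.copy()
        out.index = [f"P{p:+d}" for p in out.index]
        out.index.name = "position"
        out.to_csv(path, sep="\t")

    _fmt(profile.raw, paths["raw"])
    _fmt(profile.norm, paths["norm"])
    counts = profile.replicate_counts
    meta = {
        "reader_id": profile.reader_id,
        "methyl_order": profile.methyl_order,
        "background_mode": profile.background_mode,
        "no_binding": profile.no_binding,
        "replicate_counts": None if counts is None else counts.to_numpy().tolist(),
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_profile(directory: str | Path, stem: str) -> ReaderProfile:
    directory = Path(directory)

    def _load(path: Path) -> pd.DataFrame:
        mat = pd.read_csv(path, sep="\t", index_col=0)
        mat.index = [int(p.removeprefix("P")) for p in mat.index]
        return mat

    raw = _load(directory / f"{stem}.raw.tsv")
    norm = _load(directory / f"{stem}.norm.tsv")
    meta = json.loads((directory / f"{stem}.json").read_text())
    counts = meta.get("replicate_counts")
    return ReaderProfile(
        meta["reader_id"],
        int(meta["methyl_order"]),
        raw,
        norm,
        replicate_counts=None
        if counts is None
        else pd.DataFrame(counts, index=raw.index, columns=raw.columns),
        background_mode=meta.get("background_mode", "matched"),
    )


def write_titrations(series: Iterable[TitrationSeries], path: str | Path) -> None:
    rows = [
        {"peptide_id": s.peptide_id, "concentration_uM": c, "mP": p}
        for s in series
        for c, p in zip(s.concentrations_um, s.mp)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_titrations(path: str | Path, ligand_nm: float = 10.0) -> list[TitrationSeries]:
    df = pd.read_csv(path, sep="\t")
    return [
        TitrationSeries(
            str(pid),
            tuple(grp["concentration_uM"].astype(float)),
            tuple(grp["mP"].astype(float)),
            ligand_nm,
        )
        for pid, grp in df.groupby("peptide_id", sort=False)
    ]


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Copy-number table: protein_id, copy_number (particles/cell), sd."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "copy_number"}
    if not required.issubset(df.columns):
        raise ValueError(f"abundance table needs columns {sorted(required)}")
    return df
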
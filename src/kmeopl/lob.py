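"""Proteome-wide Lowest-Bin (LoB) motif scoring.

Every lysine-centered seven-mer in a proteome is scored against a reader
profile by the LoB rule: the score is the *minimum* of the six profile values
at the motif's (flank position, residue) lookups.  A single disfavored
residue therefore vetoes the motif, which keeps false positives down.  Scores
are normalized to the scan maximum and ranked; motifs the library cannot
measure (cysteine in the window, ambiguous residues, or a lysine within three
residues of a terminus) are reported as excluded rather than silently
dropped, so motif totals reconcile.  Protein copy numbers can be joined on to
weigh a hit's detectability against abundant competitors such as histones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library import FLANK_OFFSETS, STANDARD_RESIDUES, KCenteredMotif
from .signal import ReaderProfile

__all__ = [
    "ProteomeRecord",
    "read_proteome",
    "extract_motifs",
    "lob_score",
    "score_proteome",
    "predict_optimal_sequence",
    "predict_worst_sequence",
    "count_at_or_above",
    "annotate_with_abundance",
    "SequencePrediction",
]

RESULT_COLUMNS = [
    "protein_id",
    "k_position",
    "window",
    "lob_score",
    "norm_score",
    "rank",
    "excluded",
    "reason",
]


@dataclass(frozen=True)
class ProteomeRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


def read_proteome(path: str | Path) -> list[ProteomeRecord]:
    """Load a proteome from FASTA."""
    from Bio import SeqIO

    return [
        ProteomeRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def exclusion_reason(window: str | None, near_terminus: bool) -> str | None:
    if near_terminus:
        return "near_terminus"
    assert window is not None
    if "C" in window:
        return "contains_C"
    if any(ch not in STANDARD_RESIDUES for ch in window):
        return "ambiguous_residue"
    return None


def extract_motifs(
    proteome: Iterable[ProteomeRecord],
) -> list[tuple[KCenteredMotif | None, str, int, str | None]]:
    """Enumerate lysine-centered seven-mers with exclusion flags.

    Returns one entry per K in the proteome as a tuple
    ``(motif, protein_id, k_position, reason)``; ``reason`` is ``None`` for
    scoreable motifs.  K's with fewer than three residues on either side have
    no complete window (``motif`` is None, reason ``near_terminus``); windows
    containing cysteine or non-standard codes carry their reason but keep the
    window for reporting.
    """
    records = list(proteome)
    if not records:
        warnings.warn("empty proteome: no motifs extracted")
        return []
    out: list[tuple[KCenteredMotif | None, str, int, str | None]] = []
    for rec in records:
        seq = rec.sequence
        for i, ch in enumerate(seq):  # i is 0-based; k_position is 1-based
            if ch != "K":
                continue
            kpos = i + 1
            if i < 3 or i + 3 >= len(seq):
                out.append((None, rec.id, kpos, "near_terminus"))
                continue
            window = seq[i - 3 : i + 4]
            motif = KCenteredMotif(
                window, source_protein=rec.id, k_position=kpos
            )
            out.append((motif, rec.id, kpos, exclusion_reason(window, False)))
    return out


def lob_score(profile: ReaderProfile, motif: KCenteredMotif) -> float:
    """Lowest-Bin score: min over the six flank lookups of the raw profile."""
    reason = exclusion_reason(motif.window, False)
    if reason is not None:
        raise ValueError(f"motif {motif.window} cannot be scored: {reason}")
    return min(profile.value(p, motif.residue_at(p)) for p in FLANK_OFFSETS)


def score_proteome(
    profile: ReaderProfile, proteome: Iterable[ProteomeRecord]
) -> pd.DataFrame:
    """Score and rank every lysine-centered seven-mer in a proteome.

    Non-excluded motifs get ``lob_score``, ``norm_score`` (score divided by
    the scan maximum) and a 1-based ``rank`` (1 = highest; ties share the
    minimum rank).  Rows are ordered by rank, then protein id, then K
    position, so output is deterministic regardless of input record order.
    If the profile carries no signal at all, scores are all zero and ranking
    is refused (rank left empty) with a warning.
    """
    # Precompute (offset -> residue -> value) maps; .at lookups are too slow
    # for proteome-scale scans.
    col_of = {r: j for j, r in enumerate(profile.raw.columns)}
    row_of = {p: i for i, p in enumerate(profile.raw.index)}
    mat = profile.raw.to_numpy()

    rows = []
    for motif, pid, kpos, reason in extract_motifs(proteome):
        window = motif.window if motif is not None else None
        if reason is not None:
            rows.append((pid, kpos, window, np.nan, np.nan, reason))
            continue
        score = min(
            mat[row_of[p], col_of[motif.window[3 + p]]] for p in FLANK_OFFSETS
        )
        rows.append((pid, kpos, window, float(score), np.nan, None))
    df = pd.DataFrame(
        rows,
        columns=["protein_id", "k_position", "window", "lob_score", "norm_score", "reason"],
    )
    df["excluded"] = df["reason"].notna()

    scored = ~df["excluded"]
    peak = df.loc[scored, "lob_score"].max() if scored.any() else np.nan
    if scored.any() and peak > 0:
        df.loc[scored, "norm_score"] = df.loc[scored, "lob_score"] / peak
        df["rank"] = df.loc[scored, "lob_score"].rank(method="min", ascending=False)
    else:
        if scored.any():
            df.loc[scored, "norm_score"] = 0.0
            warnings.warn("no binding signal: all LoB scores are zero, ranking refused")
        df["rank"] = np.nan
    df = df.sort_values(
        ["excluded", "rank", "protein_id", "k_position"],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return df[RESULT_COLUMNS]


@dataclass(frozen=True)
class SequencePrediction:
    """An extremal seven-mer read off a profile, with per-position ties."""

    sequence: str
    ties: dict[int, tuple[str, ...]]
    unconstrained: tuple[int, ...]


def _extremal_sequence(profile: ReaderProfile, best: bool) -> SequencePrediction:
    chars: dict[int, str] = {0: "K"}
    ties: dict[int, tuple[str, ...]] = {}
    unconstrained: list[int] = []
    residues = list(profile.raw.columns)
    for p in profile.raw.index:
        col = profile.raw.loc[p]
        target = col.max() if best else col.min()
        tied = tuple(sorted(r for r in residues if col[r] == target))
        ties[int(p)] = tied
        if len(tied) == len(residues):
            unconstrained.append(int(p))
        chars[int(p)] = tied[0]  # lexicographically smallest among ties
    seq = "".join(chars[p] for p in (-3, -2, -1, 0, 1, 2, 3))
    return SequencePrediction(seq, ties, tuple(unconstrained))


def predict_optimal_sequence(profile: ReaderProfile) -> SequencePrediction:
    """Best-binding seven-mer: the argmax residue at each flank position.

    Ties are reported exhaustively; the primary sequence takes the
    lexicographically smallest residue.  A position where every residue is
    equal (e.g. an all-zero column) is reported as unconstrained.
    """
    return _extremal_sequence(profile, best=True)


def predict_worst_sequence(profile: ReaderProfile) -> SequencePrediction:
    """Poorest-binding seven-mer: the argmin residue at each flank position."""
    return _extremal_sequence(profile, best=False)


def _reference_row(
    results: pd.DataFrame, reference: KCenteredMotif | tuple[str, int]
) -> pd.Series:
    if isinstance(reference, KCenteredMotif):
        pid, kpos = reference.source_protein, reference.k_position
    else:
        pid, kpos = reference
    hit = results[(results["protein_id"] == pid) & (results["k_position"] == kpos)]
    if hit.empty:
        raise KeyError(f"reference motif {pid}:{kpos} not found in scan")
    row = hit.iloc[0]
    if row["excluded"]:
        raise ValueError(f"reference motif {pid}:{kpos} was excluded ({row['reason']})")
    return row


def count_at_or_above(
    results: pd.DataFrame, reference: KCenteredMotif | tuple[str, int]
) -> int:
    """Number of scored motifs with LoB score >= the reference motif's,
    excluding the reference itself."""
    ref = _reference_row(results, reference)
    scored = results[~results["excluded"]]
    at_or_above = scored["lob_score"] >= ref["lob_score"]
    self_row = (scored["protein_id"] == ref["protein_id"]) & (
        scored["k_position"] == ref["k_position"]
    )
    return int((at_or_above & ~self_row).sum())


def annotate_with_abundance(
    results: pd.DataFrame,
    abundance: pd.DataFrame,
    reference_protein: str,
) -> pd.DataFrame:
    """Join protein copy numbers and express abundance relative to a reference.

    ``abundance`` needs columns ``protein_id`` and ``copy_number``
    (particles/cell, > 0).  ``fold_abundance`` is copy_number(reference) /
    copy_number(protein): how many times more abundant the reference (e.g.
    histone H3.1) is than each motif's protein.  Motifs without an abundance
    entry are flagged rather than dropped.
    """
    ab = abundance.set_index("protein_id")
    if (ab["copy_number"] <= 0).any():
        raise ValueError("copy numbers must be > 0")
    if reference_protein not in ab.index:
        raise KeyError(f"reference protein {reference_protein!r} not in abundance table")
    ref_copies = float(ab.at[reference_protein, "copy_number"])
    out = results.merge(
        ab[["copy_number"]], left_on="protein_id", right_index=True, how="left"
    )
    out["fold_abundance"] = ref_copies / out["copy_number"]
    out["abundance_missing"] = out["copy_number"].isna()
    return out
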
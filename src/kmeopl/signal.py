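"""From raw plate fluorescence to reader binding profiles.

The assay reads out reader binding to each Kme-OPL set or pool as a
fluorescence intensity (RFU).  Because the anti-GST detection antibody alone
gives appreciable signal, every reader well is paired with a GST-only control
well whose mean is subtracted; where a matched control was not run, a
background level is inferred from the unmethylated (Kme0) pool.  Subtracted
per-set means form a 6 position x 19 residue matrix (the reader profile),
which is also scaled to [0, 1] for heatmap display and cross-reader
comparison.  A histogram of the 114 normalized set signals distinguishes
sequence-specific readers (few high sets) from promiscuous ones (most sets
high).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library import (
    FLANK_OFFSETS,
    METHYL_ORDERS,
    N_SETS_PER_ORDER,
    RESIDUES,
    KmeSetID,
    enumerate_sets,
)

__all__ = [
    "PlateMeasurement",
    "ReaderProfile",
    "MethylOrderCall",
    "SpecificityHistogram",
    "IncompleteProfileError",
    "subtract_background",
    "infer_background",
    "build_profile",
    "summarize_pools",
    "call_methyl_order",
    "specificity_histogram",
]

#: Specificity-index thresholds for the qualitative label.
SPECIFIC_INDEX_MAX = 0.15
PROMISCUOUS_INDEX_MIN = 0.5


class IncompleteProfileError(ValueError):
    """Raised when a profile is built without all 114 sets present."""

    def __init__(self, missing: Sequence[KmeSetID]):
        self.missing = tuple(missing)
        labels = ", ".join(s.label for s in self.missing[:8])
        more = "" if len(self.missing) <= 8 else f" (+{len(self.missing) - 8} more)"
        super().__init__(f"profile incomplete; missing sets: {labels}{more}")


def _as_signal_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
        raise ValueError(f"invalid signal: {name} must be finite and >= 0")
    return arr


@dataclass(frozen=True)
class PlateMeasurement:
    """Replicate fluorescence readings for one library entity and one reader.

    Exactly one of ``set_id`` / ``pool_order`` is set: per-set wells carry a
    :class:`KmeSetID`, pool wells carry just the methyl order.  ``gst_signals``
    holds the matched GST-only control wells and may be empty when no
    simultaneous control was run.
    """

    reader_id: str
    replicate_signals: tuple[float, ...]
    gst_signals: tuple[float, ...] = ()
    set_id: KmeSetID | None = None
    pool_order: int | None = None

    def __post_init__(self) -> None:
        if (self.set_id is None) == (self.pool_order is None):
            raise ValueError("exactly one of set_id or pool_order must be given")
        sig = _as_signal_array(self.replicate_signals, "replicate_signals")
        if sig.size < 1:
            raise ValueError("at least one replicate signal is required")
        _as_signal_array(self.gst_signals, "gst_signals")
        object.__setattr__(self, "replicate_signals", tuple(float(x) for x in sig))
        object.__setattr__(
            self, "gst_signals", tuple(float(x) for x in self.gst_signals)
        )

    @property
    def methyl_order(self) -> int:
        return self.set_id.methyl_order if self.set_id is not None else self.pool_order

    @property
    def reader_mean(self) -> float:
        return float(np.mean(self.replicate_signals))

    @property
    def gst_mean(self) -> float | None:
        return float(np.mean(self.gst_signals)) if self.gst_signals else None


def subtract_background(reader_mean: float, gst_mean: float) -> float:
    """GST-subtracted signal, clamped at zero.

    Negative differences are floored at 0 RFU: a reader cannot bind less than
    not at all, and downstream Lowest-Bin scores are defined on a 0-based
    RFU scale.
    """
    if not np.isfinite(reader_mean) or not np.isfinite(gst_mean):
        raise ValueError("invalid signal: inputs must be finite")
    if reader_mean < 0 or gst_mean < 0:
        raise ValueError("invalid signal: fluorescence intensities must be >= 0")
    return max(float(reader_mean) - float(gst_mean), 0.0)


def infer_background(
    kme0_pool_signal: float, low_ref: float, high_ref: float
) -> float:
    """Choose the background to subtract when no matched GST control exists.

    The unmethylated (Kme0) pool carries no methyl mark for a reader to engage,
    so its signal tracks the assay background.  The returned value is whichever
    user-supplied reference (low or high) is nearer to the Kme0 pool signal;
    ties go to the high reference, which is the conservative choice (it can
    only suppress, never inflate, apparent binding).
    """
    if low_ref > high_ref:
        raise ValueError("low_ref must be <= high_ref")
    if abs(kme0_pool_signal - high_ref) < abs(kme0_pool_signal - low_ref):
        return float(high_ref)
    if abs(kme0_pool_signal - high_ref) == abs(kme0_pool_signal - low_ref):
        return float(high_ref)
    return float(low_ref)


@dataclass
class ReaderProfile:
    """GST-subtracted binding matrix for one reader at one methyl order.

    ``raw`` holds per-set mean RFU after background subtraction (rows =
    flank offsets P-3..P+3, columns = residues); ``norm`` is the same matrix
    scaled so its maximum is 1 (all zeros if there is no binding at all).
    """

    reader_id: str
    methyl_order: int
    raw: pd.DataFrame
    norm: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    replicate_counts: pd.DataFrame | None = None
    background_mode: str = "matched"

    def __post_init__(self) -> None:
        raw = self.raw.astype(float)
        if (raw.to_numpy() < 0).any():
            raise ValueError("raw profile entries must be >= 0")
        self.raw = raw
        if self.norm is None:
            self.norm = normalize_matrix(raw)

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(self.raw.columns)

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(self.raw.index)

    @property
    def no_binding(self) -> bool:
        return float(self.raw.to_numpy().max(initial=0.0)) == 0.0

    def value(self, offset: int, residue: str) -> float:
        """Raw (RFU-scale) profile value for one (position, residue) set."""
        return float(self.raw.at[offset, residue])

    def normalized(self) -> "ReaderProfile":
        """Profile whose raw matrix is the 0-1 normalized one (for
        cross-reader comparisons)."""
        return ReaderProfile(
            self.reader_id,
            self.methyl_order,
            self.norm.copy(),
            replicate_counts=self.replicate_counts,
            background_mode=self.background_mode,
        )


def normalize_matrix(raw: pd.DataFrame) -> pd.DataFrame:
    peak = float(raw.to_numpy().max(initial=0.0))
    if peak <= 0:
        return raw * 0.0
    return raw / peak


def build_profile(
    measurements: Iterable[PlateMeasurement],
    background: float | None = None,
) -> ReaderProfile:
    """Aggregate per-set plate measurements into a :class:`ReaderProfile`.

    All measurements must belong to one reader and one methyl order and cover
    every one of the 114 sets at least once.  Per cell the replicate reader
    signals are averaged, the matched GST mean (or the supplied inferred
    ``background`` when a well has no GST control) is subtracted, and the
    result is clamped at 0.  A profile whose matrix is entirely zero is flagged
    (``no_binding``) but still returned.
    """
    ms = [m for m in measurements if m.set_id is not None]
    if not ms:
        raise ValueError("no per-set measurements supplied")
    readers = {m.reader_id for m in ms}
    orders = {m.set_id.methyl_order for m in ms}
    if len(readers) != 1 or len(orders) != 1:
        raise ValueError("measurements must come from one reader and one methyl order")
    reader_id, order = readers.pop(), orders.pop()

    by_set: dict[KmeSetID, list[PlateMeasurement]] = {}
    for m in ms:
        by_set.setdefault(m.set_id, []).append(m)

    expected = enumerate_sets(order)
    missing = [s for s in expected if s not in by_set]
    if missing:
        raise IncompleteProfileError(missing)

    raw = pd.DataFrame(0.0, index=list(FLANK_OFFSETS), columns=list(RESIDUES))
    counts = pd.DataFrame(0, index=list(FLANK_OFFSETS), columns=list(RESIDUES))
    used_inferred = False
    for s in expected:
        reader_reps: list[float] = []
        gst_reps: list[float] = []
        for m in by_set[s]:
            reader_reps.extend(m.replicate_signals)
            gst_reps.extend(m.gst_signals)
        if gst_reps:
            gst_mean = float(np.mean(gst_reps))
        elif background is not None:
            gst_mean = float(background)
            used_inferred = True
        else:
            raise ValueError(
                f"set {s.label} has no GST control and no inferred background was given"
            )
        raw.at[s.fixed_position, s.fixed_residue] = subtract_background(
            float(np.mean(reader_reps)), gst_mean
        )
        counts.at[s.fixed_position, s.fixed_residue] = len(reader_reps)

    if used_inferred:
        mode = "inferred" if all(not m.gst_signals for m in ms) else "mixed"
    else:
        mode = "matched"
    profile = ReaderProfile(
        reader_id, order, raw, replicate_counts=counts, background_mode=mode
    )
    if profile.no_binding:
        warnings.warn(f"profile for {reader_id} (Kme{order}) shows no binding")
    return profile


def summarize_pools(measurements: Iterable[PlateMeasurement]) -> pd.DataFrame:
    """Per-methyl-order pool summary: reader mean, GST mean, subtracted signal
    (clamped >= 0), replicate count, SD of the reader replicates."""
    rows = {}
    for m in measurements:
        if m.pool_order is None:
            continue
        sig = np.asarray(m.replicate_signals)
        gst = m.gst_mean or 0.0
        rows[m.pool_order] = {
            "reader_mean": float(sig.mean()),
            "gst_mean": float(gst),
            "subtracted": subtract_background(float(sig.mean()), float(gst)),
            "n": int(sig.size),
            "sd": float(sig.std(ddof=1)) if sig.size > 1 else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "methyl_order"
    return out


@dataclass(frozen=True)
class MethylOrderCall:
    """Preferred methyl order(s) from pool screening."""

    orders: tuple[int, ...]
    detected: bool

    def __contains__(self, order: int) -> bool:
        return order in self.orders


def call_methyl_order(
    pool_signals: Mapping[int, float] | pd.DataFrame, rel_tol: float = 0.10
) -> MethylOrderCall:
    """Call the preferred methyl order(s) from GST-subtracted pool signals.

    The argmax order is preferred; any order within ``rel_tol`` (default 10%)
    of the maximum is co-reported, which captures dual me2/me3 readers.  If
    all four subtracted signals are zero no preference is detectable.
    """
    if isinstance(pool_signals, pd.DataFrame):
        sig = {int(k): float(v) for k, v in pool_signals["subtracted"].items()}
    else:
        sig = {int(k): float(v) for k, v in pool_signals.items()}
    if set(sig) != set(METHYL_ORDERS):
        raise ValueError("all four methyl orders must be measured")
    peak = max(sig.values())
    if peak <= 0:
        return MethylOrderCall((), detected=False)
    called = tuple(sorted(m for m, v in sig.items() if v >= (1 - rel_tol) * peak))
    return MethylOrderCall(called, detected=True)


@dataclass(frozen=True)
class SpecificityHistogram:
    """Distribution of the 114 normalized set signals for one profile.

    ``specificity_index`` is the fraction of sets at or above 0.5 of the peak
    signal: low for sequence-specific readers (few tolerated sequences), high
    for promiscuous ones.
    """

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    specificity_index: float
    label: str

    @property
    def n_sets(self) -> int:
        return int(sum(self.counts))


def specificity_histogram(
    profile: ReaderProfile, n_bins: int = 10
) -> SpecificityHistogram:
    """Histogram the normalized per-set signals and classify specificity.

    Bins span [0, 1]; counts sum to the number of sets (114 for the full
    library).  The label is ``specific`` when the specificity index is at most
    0.15, ``promiscuous`` at 0.5 or above, otherwise ``intermediate``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = profile.norm.to_numpy().ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    index = float(np.mean(values >= 0.5))
    if index <= SPECIFIC_INDEX_MAX:
        label = "specific"
    elif index >= PROMISCUOUS_INDEX_MIN:
        label = "promiscuous"
    else:
        label = "intermediate"
    return SpecificityHistogram(
        tuple(float(e) for e in edges),
        tuple(int(c) for c in counts),
        index,
        label,
    )
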
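"""Combinatorial model of the methyllysine-oriented peptide library (Kme-OPL).

The library consists of degenerate seven-mer peptides oriented around a
central lysine carrying one of four methyl orders (Kme0-Kme3).  Each *set*
fixes a single amino acid at one of the six flanking positions (P-3..P+3,
excluding the central K); the five remaining flanks are an equimolar mix of
the 19 standard residues (cysteine is excluded from the synthesis).  A *pool*
combines all sets of one methyl order.  With 6 positions x 19 residues the
library has 114 sets per methyl order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RESIDUES",
    "STANDARD_RESIDUES",
    "FLANK_OFFSETS",
    "METHYL_ORDERS",
    "N_SETS_PER_ORDER",
    "KmeSetID",
    "KCenteredMotif",
    "enumerate_sets",
    "set_membership",
    "degenerate_composition",
    "library_table",
]

#: Canonical 19-residue alphabet: the 20 standard amino acids minus cysteine,
#: sorted by one-letter code so matrix layouts are reproducible.
RESIDUES: tuple[str, ...] = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY") - {"C"}))

#: All 20 standard one-letter codes (proteome sequences may contain C).
STANDARD_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Flanking positions relative to the central lysine (offset 0 is the fixed K).
FLANK_OFFSETS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)

METHYL_ORDERS: tuple[int, ...] = (0, 1, 2, 3)

N_SETS_PER_ORDER: int = len(FLANK_OFFSETS) * len(RESIDUES)  # 114


def _check_order(order: int) -> int:
    if order not in METHYL_ORDERS:
        raise ValueError(f"methyl order must be one of {METHYL_ORDERS}, got {order!r}")
    return int(order)


def _check_offset(offset: int) -> int:
    if offset not in FLANK_OFFSETS:
        raise ValueError(
            f"flank position must be one of {FLANK_OFFSETS}, got {offset!r}"
        )
    return int(offset)


@dataclass(frozen=True, order=True)
class KmeSetID:
    """Identity of one Kme-OPL set: (methyl order, fixed position, fixed residue)."""

    methyl_order: int
    fixed_position: int
    fixed_residue: str

    def __post_init__(self) -> None:
        _check_order(self.methyl_order)
        _check_offset(self.fixed_position)
        if self.fixed_residue == "C":
            raise ValueError("cysteine is excluded from the Kme-OPL alphabet")
        if self.fixed_residue not in STANDARD_RESIDUES:
            raise ValueError(f"invalid fixed residue {self.fixed_residue!r}")

    @property
    def label(self) -> str:
        """Stable serialization, e.g. ``Kme3_P-2_A``."""
        return f"Kme{self.methyl_order}_P{self.fixed_position:+d}_{self.fixed_residue}"

    @classmethod
    def from_label(cls, label: str) -> "KmeSetID":
        order_s, pos_s, res = label.split("_")
        return cls(int(order_s.removeprefix("Kme")), int(pos_s.removeprefix("P")), res)


@dataclass(frozen=True)
class KCenteredMotif:
    """A lysine-centered seven-mer with optional provenance.

    ``window`` is the 7-residue string; its middle character (index 3) must be
    'K'.  ``methyl_order`` tags library peptides; proteome motifs are
    unmodified (``None``).  ``k_position`` is the 1-based index of the central
    K in the source protein sequence.
    """

    window: str
    methyl_order: int | None = None
    source_protein: str | None = None
    k_position: int | None = None

    def __post_init__(self) -> None:
        if len(self.window) != 7:
            raise ValueError(f"motif window must have length 7, got {self.window!r}")
        if self.window[3] != "K":
            raise ValueError(f"central residue must be 'K', got {self.window!r}")
        if self.methyl_order is not None:
            _check_order(self.methyl_order)

    def residue_at(self, offset: int) -> str:
        """Residue at a flank offset (P-3..P+3) relative to the central K."""
        _check_offset(offset)
        return self.window[3 + offset]

    @property
    def flanks(self) -> str:
        return self.window[:3] + self.window[4:]


def enumerate_sets(
    methyl_order: int,
    alphabet: Sequence[str] = RESIDUES,
    positions: Sequence[int] = FLANK_OFFSETS,
) -> list[KmeSetID]:
    """Enumerate all sets of one methyl order, position-major then by residue.

    Returns ``len(positions) * len(alphabet)`` distinct sets (114 for the full
    library).
    """
    if not alphabet or not positions:
        raise ValueError("alphabet and positions must be non-empty")
    if "C" in alphabet:
        raise ValueError("invalid alphabet: cysteine cannot appear in the Kme-OPL")
    order = _check_order(methyl_order)
    return [
        KmeSetID(order, _check_offset(p), r) for p in positions for r in alphabet
    ]


def set_membership(set_id: KmeSetID, motif: KCenteredMotif) -> bool:
    """Whether a concrete seven-mer belongs to a Kme-OPL set.

    Membership requires matching methyl order, the set's fixed residue at its
    fixed position, and no cysteine anywhere in the flanks (the library never
    synthesizes C).
    """
    if motif.methyl_order != set_id.methyl_order:
        return False
    if "C" in motif.flanks:
        return False
    return motif.residue_at(set_id.fixed_position) == set_id.fixed_residue


def degenerate_composition(
    set_id: KmeSetID, alphabet: Sequence[str] = RESIDUES
) -> dict[int, dict[str, float]]:
    """Per-position residue fractions of the equimolar degenerate mixture.

    The fixed position carries its residue at fraction 1; every other flank is
    an equimolar mix over the alphabet; offset 0 is the central methylated
    lysine (keyed ``"Kme{m}"``).  Fractions at each position sum to 1.
    """
    if "C" in alphabet:
        raise ValueError("invalid alphabet: cysteine cannot appear in the Kme-OPL")
    frac = 1.0 / len(alphabet)
    comp: dict[int, dict[str, float]] = {}
    for p in FLANK_OFFSETS:
        if p == set_id.fixed_position:
            comp[p] = {set_id.fixed_residue: 1.0}
        else:
            comp[p] = {r: frac for r in alphabet}
    comp[0] = {f"Kme{set_id.methyl_order}": 1.0}
    return dict(sorted(comp.items()))


def library_table(orders: Iterable[int] = METHYL_ORDERS):
    """Library definition as a DataFrame (set_id, methyl_order, fixed_position,
    fixed_residue), suitable for TSV export."""
    import pandas as pd

    rows = [
        {
            "set_id": s.label,
            "methyl_order": s.methyl_order,
            "fixed_position": s.fixed_position,
            "fixed_residue": s.fixed_residue,
        }
        for m in orders
        for s in enumerate_sets(m)
    ]
    return pd.DataFrame(rows)
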
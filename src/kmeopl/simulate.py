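"""Synthetic data generators for every stage of the Kme-OPL pipeline.

The wet-lab assay is emulated with a latent reader model in which binding is
independent and multiplicative across flank positions: each (position,
residue) pair carries a relative occupancy weight in (0, 1], each methyl
order a multiplier (1 for the preferred order), and a set's expected signal
is the model evaluated over the equimolar degenerate mixture:

    E[set (p, a)] = S0 * order_weight * w(p, a) * prod_{q != p} mean_r w(q, r)
    E[pool]       = S0 * order_weight * prod_q mean_r w(q, r)

Averaging over the mixture is what makes sequence-specific readers dim:
a one-hot reader multiplies five mixture means of ~1/19 into its best set,
so its pool and set signals sit far below those of a promiscuous reader.
Plate wells add a GST/antibody background and truncated Gaussian noise.
Generators for proteomes with planted motifs and for FP titrations complete
the toolkit; everything is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fp import TitrationSeries, anisotropy_to_polarization, hill_model
from .library import (
    FLANK_OFFSETS,
    METHYL_ORDERS,
    RESIDUES,
    KmeSetID,
    enumerate_sets,
)
from .lob import ProteomeRecord
from .signal import PlateMeasurement

__all__ = [
    "LatentReaderModel",
    "SyntheticPlate",
    "uniform_model",
    "one_hot_model",
    "expected_set_signal",
    "expected_pool_signal",
    "simulate_plate",
    "generate_proteome",
    "simulate_fp_titration",
    "model_from_yaml",
]

_POS_INDEX = {p: i for i, p in enumerate(FLANK_OFFSETS)}
_RES_INDEX = {r: j for j, r in enumerate(RESIDUES)}

#: Default plate magnitudes: peak signal scale, antibody background, and
#: replicate noise, all in RFU, with 4 replicate wells per measurement.
DEFAULT_S0 = 2000.0
DEFAULT_GST_BACKGROUND = 150.0
DEFAULT_NOISE_SD = 50.0
DEFAULT_N_REPLICATES = 4


@dataclass(frozen=True)
class LatentReaderModel:
    """Generative model of one reader's binding behavior.

    ``position_weights`` is a 6 x 19 matrix (rows = P-3..P+3, columns = the
    19-residue alphabet) of relative occupancy factors in (0, 1];
    ``order_weights`` has one multiplier per methyl order with the preferred
    order at 1.
    """

    preferred_order: int
    order_weights: tuple[float, float, float, float]
    position_weights: np.ndarray
    s0: float = DEFAULT_S0
    gst_background: float = DEFAULT_GST_BACKGROUND
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.position_weights, dtype=float)
        if w.shape != (len(FLANK_OFFSETS), len(RESIDUES)):
            raise ValueError(
                f"position_weights must be {len(FLANK_OFFSETS)}x{len(RESIDUES)}"
            )
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("position weights must lie in (0, 1]")
        ow = tuple(float(v) for v in self.order_weights)
        if len(ow) != 4 or any(v < 0 or v > 1 for v in ow):
            raise ValueError("order_weights must be four values in [0, 1]")
        if ow[self.preferred_order] != 1.0:
            raise ValueError("preferred order must carry weight 1")
        if self.s0 <= 0 or self.noise_sd < 0 or self.gst_background < 0:
            raise ValueError("s0 > 0, noise_sd >= 0, gst_background >= 0 required")
        object.__setattr__(self, "position_weights", w)
        object.__setattr__(self, "order_weights", ow)
        w.setflags(write=False)

    @property
    def mixture_means(self) -> np.ndarray:
        """Per-position mean weight over the equimolar 19-residue mixture."""
        return self.position_weights.mean(axis=1)

    def optimal_flanks(self) -> str:
        """Argmax residue at each flank (ties -> smallest one-letter code)."""
        return "".join(
            RESIDUES[int(np.argmax(self.position_weights[i]))]
            for i in range(len(FLANK_OFFSETS))
        )

    def optimal_window(self) -> str:
        f = self.optimal_flanks()
        return f[:3] + "K" + f[3:]


def _default_order_weights(preferred_order: int, off_order: float) -> tuple:
    return tuple(1.0 if m == preferred_order else off_order for m in METHYL_ORDERS)


def uniform_model(
    preferred_order: int = 3,
    off_order_weight: float = 0.05,
    **kwargs,
) -> LatentReaderModel:
    """Fully promiscuous reader: every residue tolerated at every position."""
    w = np.ones((len(FLANK_OFFSETS), len(RESIDUES)))
    return LatentReaderModel(
        preferred_order,
        _default_order_weights(preferred_order, off_order_weight),
        w,
        **kwargs,
    )


def one_hot_model(
    window: str,
    epsilon: float = 0.05,
    preferred_order: int = 3,
    off_order_weight: float = 0.05,
    peak_set_signal: float | None = None,
    **kwargs,
) -> LatentReaderModel:
    """Sequence-specific reader preferring one seven-mer.

    ``window`` is a 7-mer with central K (or just the 6 flank residues); the
    preferred residue at each position gets weight 1, all others ``epsilon``.
    When ``peak_set_signal`` is given, S0 is calibrated so that the brightest
    set's *expected* signal (after mixture dilution) equals it, which keeps
    synthetic plates on the RFU scale real specific readers show.
    """
    if len(window) == 7:
        if window[3] != "K":
            raise ValueError("7-mer window must have central K")
        flanks = window[:3] + window[4:]
    elif len(window) == 6:
        flanks = window
    else:
        raise ValueError("window must be a 7-mer (central K) or 6 flank residues")
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must be in (0, 1]")
    w = np.full((len(FLANK_OFFSETS), len(RESIDUES)), epsilon)
    for i, r in enumerate(flanks):
        w[i, _RES_INDEX[r]] = 1.0
    if peak_set_signal is not None:
        mean = (1.0 + (len(RESIDUES) - 1) * epsilon) / len(RESIDUES)
        kwargs["s0"] = peak_set_signal / mean ** (len(FLANK_OFFSETS) - 1)
    return LatentReaderModel(
        preferred_order,
        _default_order_weights(preferred_order, off_order_weight),
        w,
        **kwargs,
    )


def expected_set_signal(model: LatentReaderModel, set_id: KmeSetID) -> float:
    """Closed-form expected fluorescence of one set over the equimolar mix."""
    i = _POS_INDEX[set_id.fixed_position]
    j = _RES_INDEX[set_id.fixed_residue]
    means = model.mixture_means
    free = np.prod(np.delete(means, i))
    return float(
        model.s0
        * model.order_weights[set_id.methyl_order]
        * model.position_weights[i, j]
        * free
    )


def expected_pool_signal(model: LatentReaderModel, methyl_order: int) -> float:
    """Closed-form expected fluorescence of the combined 114-set pool."""
    return float(
        model.s0 * model.order_weights[methyl_order] * np.prod(model.mixture_means)
    )


@dataclass(frozen=True)
class SyntheticPlate:
    """Complete simulated experiment: 114 sets x 4 orders plus 4 pools."""

    sets: tuple[PlateMeasurement, ...]
    pools: tuple[PlateMeasurement, ...]
    n_replicates: int
    seed: int

    def set_measurements(self, methyl_order: int) -> list[PlateMeasurement]:
        return [m for m in self.sets if m.set_id.methyl_order == methyl_order]

    def pool_measurement(self, methyl_order: int) -> PlateMeasurement:
        return next(m for m in self.pools if m.pool_order == methyl_order)


def _noisy_wells(rng, mean: float, sd: float, n: int) -> tuple[float, ...]:
    return tuple(float(v) for v in np.clip(mean + rng.normal(0.0, sd, n), 0.0, None))


def simulate_plate(
    model: LatentReaderModel,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
    reader_id: str = "reader",
) -> SyntheticPlate:
    """Simulate reader and GST-control wells for the whole library.

    Each reader well draws expectation + GST background + Gaussian noise
    (truncated at 0); each matched GST well draws background + noise.  The
    plate is fully reproducible from (model, n_replicates, seed).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    sets = []
    for order in METHYL_ORDERS:
        for sid in enumerate_sets(order):
            mu = expected_set_signal(model, sid)
            sets.append(
                PlateMeasurement(
                    reader_id=reader_id,
                    set_id=sid,
                    replicate_signals=_noisy_wells(
                        rng, mu + model.gst_background, model.noise_sd, n_replicates
                    ),
                    gst_signals=_noisy_wells(
                        rng, model.gst_background, model.noise_sd, n_replicates
                    ),
                )
            )
    pools = []
    for order in METHYL_ORDERS:
        mu = expected_pool_signal(model, order)
        pools.append(
            PlateMeasurement(
                reader_id=reader_id,
                pool_order=order,
                replicate_signals=_noisy_wells(
                    rng, mu + model.gst_background, model.noise_sd, n_replicates
                ),
                gst_signals=_noisy_wells(
                    rng, model.gst_background, model.noise_sd, n_replicates
                ),
            )
        )
    return SyntheticPlate(
        tuple(sets), tuple(pools), n_replicates, model.seed if seed is None else seed
    )


def generate_proteome(
    n_proteins: int = 100,
    length_range: tuple[int, int] = (200, 400),
    residue_frequencies: Mapping[str, float] | None = None,
    planted_motifs: Sequence[str | tuple[str, int]] = (),
    seed: int = 0,
) -> tuple[list[ProteomeRecord], pd.DataFrame]:
    """Random protein sequences with optional planted seven-mers.

    Background residues are drawn i.i.d. from ``residue_frequencies`` (uniform
    over the 20 standard residues by default, so cysteine does occur, as in a
    real proteome).  Each planted motif -- a 7-mer with central K, optionally
    paired with a target protein index -- overwrites a window at least three
    residues from either terminus; collisions between plants trigger
    re-placement.  Returns the records and a ground-truth manifest
    (protein_id, k_position, window).
    """
    rng = np.random.default_rng(seed)
    if residue_frequencies is None:
        letters = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))
        probs = np.full(letters.size, 1.0 / letters.size)
    else:
        letters = np.array(sorted(residue_frequencies))
        probs = np.array([residue_frequencies[l] for l in letters], dtype=float)
        probs = probs / probs.sum()
    lo, hi = length_range
    if lo < 7:
        raise ValueError("minimum protein length must be >= 7")

    seqs = []
    for i in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seqs.append(list(rng.choice(letters, size=n, p=probs)))

    manifest_rows = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for item in planted_motifs:
        if isinstance(item, tuple):
            window, target = item
        else:
            window, target = item, int(rng.integers(0, n_proteins))
        if len(window) != 7 or window[3] != "K":
            raise ValueError(f"planted motif must be a K-centered 7-mer: {window!r}")
        seq = seqs[target]
        for _ in range(1000):
            start = int(rng.integers(3, len(seq) - 9))  # K at start+3, >=3 from ends
            span = (start, start + 7)
            if all(
                span[1] <= s or span[0] >= e for s, e in occupied.get(target, [])
            ):
                break
        else:  # pragma: no cover - would need a pathologically full protein
            raise RuntimeError("could not place planted motif without collision")
        seq[start : start + 7] = list(window)
        occupied.setdefault(target, []).append(span)
        manifest_rows.append(
            {
                "protein_id": f"synprot{target:04d}",
                "k_position": start + 4,
                "window": window,
            }
        )

    records = [
        ProteomeRecord(f"synprot{i:04d}", "".join(s)) for i, s in enumerate(seqs)
    ]
    manifest = pd.DataFrame(manifest_rows, columns=["protein_id", "k_position", "window"])
    return records, manifest


def simulate_fp_titration(
    kd: float,
    hill: float,
    amax: float,
    baseline: float = 0.0,
    concentrations_um: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    peptide_id: str = "synthetic",
    ligand_nm: float = 10.0,
) -> TitrationSeries:
    """FP titration from known Hill parameters, reported in mP.

    Anisotropy follows the Hill model plus seeded Gaussian noise and is
    converted back to polarization via P = 3A / (2 + A).  The default design
    is a 12-point serial dilution from 0.01 to 100 uM with 10 nM ligand.
    """
    if kd <= 0 or hill <= 0 or amax <= 0:
        raise ValueError("kd, hill and amax must be > 0")
    if concentrations_um is None:
        concentrations_um = np.logspace(-2, 2, 12)
    x = np.asarray(concentrations_um, dtype=float)
    rng = np.random.default_rng(seed)
    a = hill_model(x, kd, hill, amax, baseline) + rng.normal(0.0, noise_sd, x.size)
    mp = anisotropy_to_polarization(a) * 1000.0
    return TitrationSeries(
        peptide_id, tuple(float(v) for v in x), tuple(float(v) for v in mp), ligand_nm
    )


def model_from_yaml(path: str | Path) -> LatentReaderModel:
    """Build a latent model from a YAML config.

    The ``position_weights`` entry is either the string ``uniform``, a mapping
    ``{one_hot: {window: ..., epsilon: ...}}``, or an explicit 6 x 19 nested
    list (rows P-3..P+3, columns in alphabet order).
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    scalars = {
        k: cfg[k]
        for k in ("s0", "gst_background", "noise_sd", "seed")
        if k in cfg
    }
    order = int(cfg.get("preferred_order", 3))
    off = float(cfg.get("off_order_weight", 0.05))
    pw = cfg.get("position_weights", "uniform")
    if pw == "uniform":
        return uniform_model(order, off, **scalars)
    if isinstance(pw, Mapping) and "one_hot" in pw:
        oh = pw["one_hot"]
        return one_hot_model(
            oh["window"],
            epsilon=float(oh.get("epsilon", 0.05)),
            preferred_order=order,
            off_order_weight=off,
            peak_set_signal=oh.get("peak_set_signal"),
            **scalars,
        )
    return LatentReaderModel(
        order,
        tuple(cfg.get("order_weights", _default_order_weights(order, off))),
        np.asarray(pw, dtype=float),
        **scalars,
    )
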
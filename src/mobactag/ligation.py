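"""Simulation of semi-random barcode assembly by blunt-end ligation.

A barcode tag is an ordered, oriented concatemer of 38-nt units drawn from
an equimolar pool.  Blunt-end ligation is orientation-agnostic, so each
incorporated unit enters forward or reverse-complemented with (by default)
equal probability.  Ligation products are then size-selected to a
200-300 bp window; with the default flanking-adapter length of 100 nt this
retains concatemers of 3-5 units, with four-unit arrays (152 nt) modal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .oligo import OligoUnit, reverse_complement

ORIENTATIONS = ("F", "R")


def default_k_distribution(
    mode: int = 4, decay: float = 0.7, k_min: int = 1, k_max: int = 8
) -> dict[int, float]:
    """Unit-count distribution before size selection.

    A peaked form ``P(k) proportional to decay**|k - mode|`` truncated to
    ``[k_min, k_max]``.  The peak absorbs both ligation kinetics and the
    soft transmission profile of the size-selection instrument, which a
    hard retention window alone cannot reproduce.
    """
    ks = range(k_min, k_max + 1)
    weights = {k: decay ** abs(k - mode) for k in ks}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


@dataclass
class LigationConfig:
    """Parameters of one simulated assembly batch.

    ``flank_length`` is the non-array sequence (adapters/vector ends)
    carried through size selection together with the concatemer;
    ``size_window`` is the retained fragment-length window in bp.  A seed
    is mandatory: identical seed implies an identical product list.
    """

    n_products: int = 10_000
    k_distribution: Mapping[int, float] | None = None
    orientation_prob_forward: float | Mapping[str, float] = 0.5
    oligo_weights: Mapping[str, float] | None = None
    flank_length: int = 100
    size_window: tuple[int, int] = (200, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_window
        if not lo < hi:
            raise ValueError(f"size_window must satisfy min < max, got {self.size_window}")
        probs = (
            self.orientation_prob_forward.values()
            if isinstance(self.orientation_prob_forward, Mapping)
            else [self.orientation_prob_forward]
        )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"orientation probability {p} outside [0, 1]")
        if self.k_distribution is not None:
            if any(p < 0 for p in self.k_distribution.values()):
                raise ValueError("negative probability in k_distribution")

    def resolved_k_distribution(self) -> dict[int, float]:
        dist = dict(self.k_distribution) if self.k_distribution else default_k_distribution()
        total = sum(dist.values())
        return {k: v / total for k, v in dist.items()}


@dataclass(frozen=True)
class BarcodeArray:
    """An ordered, oriented concatemer of oligo units.

    ``units`` is a tuple of ``(label, orientation)`` pairs with orientation
    ``'F'`` or ``'R'``; ``sequence`` is the concatenation of the oriented
    unit sequences, so ``len(sequence) == 38 * k`` always holds.
    """

    units: tuple[tuple[str, str], ...]
    sequence: str

    @property
    def k(self) -> int:
        return len(self.units)

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_units(
        cls, units: Sequence[tuple[str, str]], oligo_map: Mapping[str, OligoUnit]
    ) -> "BarcodeArray":
        seq = "".join(oligo_map[label].oriented(orient) for label, orient in units)
        return cls(units=tuple(units), sequence=seq)


def _orientation_probs(config: LigationConfig, labels: Sequence[str]) -> np.ndarray:
    p = config.orientation_prob_forward
    if isinstance(p, Mapping):
        return np.array([p[label] for label in labels])
    return np.full(len(labels), float(p))


def simulate_ligation(oligos: Sequence[OligoUnit], config: LigationConfig) -> list[BarcodeArray]:
    """Draw ``n_products`` concatemers from the equimolar ligation model.

    Each product first draws its unit count ``k`` from the configured
    distribution, then fills each of the ``k`` positions independently with
    a unit from the pool (uniformly unless per-unit weights are given) and
    an orientation (forward with ``orientation_prob_forward``).
    """
    if len(oligos) < 2:
        raise ValueError("need at least two oligo units for ligation")
    if config.n_products <= 0:
        raise ValueError(f"n_products must be positive, got {config.n_products}")
    rng = np.random.default_rng(config.seed)
    labels = [o.label for o in oligos]
    oligo_map = {o.label: o for o in oligos}
    kdist = config.resolved_k_distribution()
    ks = rng.choice(list(kdist), size=config.n_products, p=list(kdist.values()))
    if config.oligo_weights is None:
        unit_p = np.full(len(labels), 1.0 / len(labels))
    else:
        w = np.array([config.oligo_weights[label] for label in labels], dtype=float)
        unit_p = w / w.sum()
    fwd_p = _orientation_probs(config, labels)
    products: list[BarcodeArray] = []
    for k in ks:
        idx = rng.choice(len(labels), size=int(k), p=unit_p)
        fwd = rng.random(int(k)) < fwd_p[idx]
        units = tuple(
            (labels[i], "F" if f else "R") for i, f in zip(idx, fwd)
        )
        products.append(BarcodeArray.from_units(units, oligo_map))
    return products


def size_select(arrays: Iterable[BarcodeArray], config: LigationConfig) -> list[BarcodeArray]:
    """Keep arrays whose fragment length ``38*k + flank`` falls in the window."""
    lo, hi = config.size_window
    return [a for a in arrays if lo <= len(a) + config.flank_length <= hi]


def positional_frequencies(
    arrays: Sequence[BarcodeArray], max_positions: int = 5
) -> tuple[pd.DataFrame, pd.Series]:
    """Oriented-unit frequency per array position, plus the unit-count histogram.

    Returns a matrix with one row per ``(label, orientation)`` observed in
    the input and one column per position ``p1..p{max_positions}``.  Column
    ``pj`` is normalized over the arrays with ``k >= j``; positions with no
    supporting array are NaN and reported with a warning.
    """
    arrays = list(arrays)
    if not arrays:
        raise ValueError("positional_frequencies requires a non-empty array list")
    labels = sorted({label for a in arrays for label, _ in a.units})
    index = pd.MultiIndex.from_product(
        [labels, ORIENTATIONS], names=["oligo", "orientation"]
    )
    columns = [f"p{j}" for j in range(1, max_positions + 1)]
    counts = pd.DataFrame(0.0, index=index, columns=columns)
    support = np.zeros(max_positions, dtype=int)
    for a in arrays:
        for j, unit in enumerate(a.units[:max_positions]):
            counts.loc[unit, columns[j]] += 1
        support[: min(a.k, max_positions)] += 1
    freqs = counts.copy()
    for j, col in enumerate(columns):
        if support[j] == 0:
            freqs[col] = np.nan
        else:
            freqs[col] /= support[j]
    empty = [columns[j] for j in range(max_positions) if support[j] == 0]
    if empty:
        warnings.warn(
            f"no arrays reach position(s) {', '.join(empty)}; columns left undefined",
            stacklevel=2,
        )
    k_hist = pd.Series([a.k for a in arrays]).value_counts().sort_index()
    k_hist.index.name = "k"
    return freqs, k_hist


def enumerate_products(
    oligos: Sequence[OligoUnit],
    k: int,
    *,
    orientation_prob_forward: float = 0.5,
    oligo_weights: Mapping[str, float] | None = None,
) -> dict[tuple[tuple[str, str], ...], float]:
    """Exhaustive product distribution for fixed ``k`` (small pools only).

    Distinct ``(label, orientation)`` tuples are distinct outcomes even if
    their sequences collide; a warning is emitted when a sequence collision
    exists among the enumerated products.
    """
    labels = [o.label for o in oligos]
    oligo_map = {o.label: o for o in oligos}
    if oligo_weights is None:
        unit_p = {label: 1.0 / len(labels) for label in labels}
    else:
        total = sum(oligo_weights[label] for label in labels)
        unit_p = {label: oligo_weights[label] / total for label in labels}
    orient_p = {"F": orientation_prob_forward, "R": 1.0 - orientation_prob_forward}
    out: dict[tuple[tuple[str, str], ...], float] = {}
    for combo in itertools.product(labels, ORIENTATIONS, repeat=k):
        units = tuple(zip(combo[::2], combo[1::2]))
        prob = 1.0
        for label, orient in units:
            prob *= unit_p[label] * orient_p[orient]
        if prob > 0:
            out[units] = prob
    seqs: dict[str, tuple] = {}
    for units in out:
        seq = BarcodeArray.from_units(units, oligo_map).sequence
        if seq in seqs and seqs[seq] != units:
            warnings.warn(
                f"sequence collision between products {seqs[seq]} and {units}",
                stacklevel=2,
            )
        seqs.setdefault(seq, units)
    return out


def write_array_fasta(arrays: Iterable[BarcodeArray], path) -> None:
    """Arrays as FASTA; unit composition is kept in the description line."""
    with open(path, "w") as handle:
        for i, a in enumerate(arrays):
            units = ",".join(f"{label}{orient}" for label, orient in a.units)
            handle.write(f">array{i} units={units}\n{a.sequence}\n")


def read_array_fasta(path, oligo_map: Mapping[str, OligoUnit] | None = None) -> list[BarcodeArray]:
    from Bio import SeqIO

    arrays = []
    for record in SeqIO.parse(str(path), "fasta"):
        units: tuple[tuple[str, str], ...] = ()
        for token in record.description.split():
            if token.startswith("units="):
                units = tuple(
                    (u[:-1], u[-1]) for u in token.split("=", 1)[1].split(",") if u
                )
        arrays.append(BarcodeArray(units=units, sequence=str(record.seq).upper()))
    return arrays
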
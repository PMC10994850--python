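"""Synthetic communities, reads, calibration sets and dilution series.

The generative model mirrors the structure the quantification assumes: a
sample's reads fall on features with propensities

* ``abundance * copy_number`` for a strain's endogenous 16S amplicon
  (near-isogenic strains may share one 16S feature),
* ``abundance * tag_bias`` for a strain's barcode tag, where ``tag_bias``
  is the tag-specific amplification ratio relative to 16S,
* fixed propensities for the spike tags and the plant ITS amplicon,

and counts are drawn multinomially at fixed depth, so everything is
conditioned on library size.  Reads are reference sequences with
independent per-base substitutions at a configurable error rate on a
random strand.  All outputs are deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .counts import CountTable
from .quantify import SpikeDesign
from .references import ReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class StrainSpec:
    """One community member: identity, abundance and marker bookkeeping."""

    strain_id: str
    abundance: float
    copy_number: int = 1
    tag_id: str | None = None
    tag_bias: float = 1.0
    shared_16s_feature: str | None = None  # set for near-isogenic groups

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise SimulationError(f"{self.strain_id}: 16S copy number must be >= 1")
        if self.tag_bias <= 0:
            raise SimulationError(f"{self.strain_id}: tag bias must be > 0")

    @property
    def sixteen_s_feature(self) -> str:
        return self.shared_16s_feature or f"{self.strain_id}_16S"


@dataclass(frozen=True)
class CommunitySpec:
    """Ground-truth description of a synthetic sample.

    Propensities of the spike and plant features are on the same relative
    scale as the strain abundances (whose sum is 1).  ``overdispersion``
    optionally gamma-perturbs the propensity vector per sample with that
    coefficient of variation, emulating replicate-to-replicate spread;
    the default is pure multinomial noise.
    """

    strains: tuple[StrainSpec, ...]
    spike: SpikeDesign
    spike_read_propensity: float = 0.05
    plant_read_propensity: float = 0.3
    plant_spike_read_propensity: float = 0.05
    reference_mass_ng: float = 0.15  # mass at which the dilution spike matches spike 1
    depth: int = 100_000
    error_rate: float = 0.0
    read_length: int = 250
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(s.abundance for s in self.strains)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"strain abundances sum to {total!r}, expected 1")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise SimulationError("error_rate must lie in [0, 0.1]")

    # -- feature bookkeeping --------------------------------------------
    def propensities(self, secondary_spike_mass_ng: float | None = None) -> pd.Series:
        """Expected (unnormalized) read propensity per feature."""
        values: dict[str, float] = {}
        for strain in self.strains:
            feat = strain.sixteen_s_feature
            values[feat] = values.get(feat, 0.0) + strain.abundance * strain.copy_number
            if strain.tag_id is not None:
                values[strain.tag_id] = strain.abundance * strain.tag_bias
        values[self.spike.spike_16s_feature] = self.spike_read_propensity
        values["plant_ITS"] = self.plant_read_propensity
        if self.spike.spike_plant_feature:
            values[self.spike.spike_plant_feature] = self.plant_spike_read_propensity
        if self.spike.secondary_spike_feature and secondary_spike_mass_ng is not None:
            values[self.spike.secondary_spike_feature] = (
                self.spike_read_propensity * secondary_spike_mass_ng / self.reference_mass_ng
            )
        return pd.Series(values)

    def feature_classes(self) -> pd.Series:
        classes: dict[str, str] = {}
        for strain in self.strains:
            classes[strain.sixteen_s_feature] = "endogenous_16S"
            if strain.tag_id is not None:
                classes[strain.tag_id] = "barcode_tag"
        classes[self.spike.spike_16s_feature] = "spike_tag"
        classes["plant_ITS"] = "plant_ITS"
        if self.spike.spike_plant_feature:
            classes[self.spike.spike_plant_feature] = "spike_tag"
        if self.spike.secondary_spike_feature:
            classes[self.spike.secondary_spike_feature] = "spike_tag"
        return pd.Series(classes)


def generate_community_counts(
    spec: CommunitySpec, n_samples: int = 1
) -> tuple[CountTable, pd.DataFrame]:
    """Multinomial count table plus the ground-truth table behind it."""
    rng = np.random.default_rng(spec.seed)
    prop = spec.propensities()
    classes = spec.feature_classes().reindex(prop.index)
    p = prop.to_numpy() / prop.sum()
    rows = []
    for _ in range(n_samples):
        p_i = p
        if spec.overdispersion:
            cv = spec.overdispersion
            shape = 1.0 / cv**2
            jitter = rng.gamma(shape, 1.0 / shape, size=p.size)
            p_i = p * jitter
            p_i = p_i / p_i.sum()
        rows.append(rng.multinomial(spec.depth, p_i))
    counts = pd.DataFrame(
        rows, index=[f"sample{i}" for i in range(n_samples)], columns=prop.index
    )
    table = CountTable(counts=counts, feature_classes=classes)
    truth_rows = []
    for feature in prop.index:
        strain = next(
            (
                s.strain_id
                for s in spec.strains
                if feature in (s.sixteen_s_feature, s.tag_id)
            ),
            None,
        )
        truth_rows.append(
            {
                "feature_id": feature,
                "feature_class": classes[feature],
                "strain_id": strain,
                "propensity": prop[feature],
                "expected_count": spec.depth * prop[feature] / prop.sum(),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return table, truth


def _mutate_reads(seqs: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitutions on a (n, L) uint8 base matrix."""
    if error_rate == 0.0:
        return seqs
    mask = rng.random(seqs.shape) < error_rate
    if mask.any():
        # Substitute with one of the three other bases, uniformly.
        offsets = rng.integers(1, 4, size=int(mask.sum()))
        idx = np.searchsorted(_BASES, seqs[mask])
        seqs = seqs.copy()
        seqs[mask] = _BASES[(idx + offsets) % 4]
    return seqs


def generate_reads(
    spec: CommunitySpec,
    refs: ReferenceSet,
    counts_row: pd.Series | None = None,
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Reads with truth labels for one sample.

    Draws a count vector from the community model (or uses ``counts_row``),
    then emits each feature's reads as its reference sequence with per-base
    substitution errors at ``spec.error_rate``, on a random strand.
    Returns ``(reads, truth)`` where ``truth`` maps read id to the feature
    the read was generated from.
    """
    rng = np.random.default_rng(spec.seed)
    if counts_row is None:
        prop = spec.propensities()
        p = prop.to_numpy() / prop.sum()
        counts_row = pd.Series(rng.multinomial(spec.depth, p), index=prop.index)
    ref_map = {f.feature_id: f.sequence.upper() for f in refs}
    missing = [f for f in counts_row.index if counts_row[f] > 0 and f not in ref_map]
    if missing:
        raise SimulationError(f"no reference sequence for feature(s): {missing}")
    from .oligo import reverse_complement

    reads: list[tuple[str, str]] = []
    truth_ids: list[str] = []
    truth_labels: list[str] = []
    counter = 0
    for feature in counts_row.index:
        n = int(counts_row[feature])
        if n == 0:
            continue
        template = ref_map[feature]
        base_matrix = np.tile(
            np.frombuffer(template.encode(), dtype=np.uint8), (n, 1)
        )
        base_matrix = _mutate_reads(base_matrix, spec.error_rate, rng)
        flip = rng.random(n) < 0.5
        for i in range(n):
            seq = base_matrix[i].tobytes().decode()
            if flip[i]:
                seq = reverse_complement(seq)
            read_id = f"read{counter}"
            reads.append((read_id, seq))
            truth_ids.append(read_id)
            truth_labels.append(feature)
            counter += 1
    truth = pd.Series(truth_labels, index=truth_ids, name="true_feature")
    return reads, truth


def generate_dilution_series(
    spec: CommunitySpec,
    masses: Sequence[float],
    *,
    lognormal_sigma: float = 0.0,
    depth: int | None = None,
) -> list[tuple[float, pd.Series]]:
    """Samples of a spike-2 dilution series, everything else held fixed.

    The secondary spike's propensity scales proportionally to its mass
    (optionally jittered by multiplicative lognormal noise with the given
    sigma, in natural-log units); the community, primary spike and plant
    features are untouched.  Returns ``(mass, count row)`` pairs.
    """
    if len(masses) == 0:
        raise SimulationError("empty mass list")
    if any(m <= 0 for m in masses):
        raise SimulationError("all masses must be positive")
    if spec.spike.secondary_spike_feature is None:
        raise SimulationError("spec's spike design names no secondary spike feature")
    rng = np.random.default_rng(spec.seed)
    depth = depth or spec.depth
    samples: list[tuple[float, pd.Series]] = []
    for mass in masses:
        prop = spec.propensities(secondary_spike_mass_ng=mass)
        if lognormal_sigma > 0:
            jitter = float(np.exp(rng.normal(0.0, lognormal_sigma)))
            prop[spec.spike.secondary_spike_feature] *= jitter
        p = prop.to_numpy() / prop.sum()
        row = pd.Series(rng.multinomial(depth, p), index=prop.index)
        samples.append((float(mass), row))
    return samples


def generate_calibration_pairs(
    tag_bias: float,
    n_samples: int = 16,
    *,
    mean_16s: float = 1000.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Pure-culture calibration samples ``(N_tag, N_16S)`` for one tag.

    Per-sample 16S intensity varies uniformly within +/-50% of
    ``mean_16s`` (libraries differ in depth); tag and 16S counts are
    independent Poisson draws around ``tag_bias * intensity`` and
    ``intensity``.
    """
    rng = np.random.default_rng(seed)
    lam = rng.uniform(0.5, 1.5, size=n_samples) * mean_16s
    n_16s = rng.poisson(lam).astype(float)
    n_tag = rng.poisson(tag_bias * lam).astype(float)
    return list(zip(n_tag, n_16s))


# -- spec (de)serialization --------------------------------------------

def spec_to_yaml(spec: CommunitySpec, path) -> None:
    data = {
        "strains": [
            {
                "strain_id": s.strain_id,
                "abundance": s.abundance,
                "copy_number": s.copy_number,
                "tag_id": s.tag_id,
                "tag_bias": s.tag_bias,
                "shared_16s_feature": s.shared_16s_feature,
            }
            for s in spec.strains
        ],
        "spike": {
            "spike_16s_feature": spec.spike.spike_16s_feature,
            "spike_plant_feature": spec.spike.spike_plant_feature,
            "secondary_spike_feature": spec.spike.secondary_spike_feature,
            "spike_mass_ng": spec.spike.spike_mass_ng,
            "sample_mass_ng": spec.spike.sample_mass_ng,
        },
        "spike_read_propensity": spec.spike_read_propensity,
        "plant_read_propensity": spec.plant_read_propensity,
        "plant_spike_read_propensity": spec.plant_spike_read_propensity,
        "reference_mass_ng": spec.reference_mass_ng,
        "depth": spec.depth,
        "error_rate": spec.error_rate,
        "read_length": spec.read_length,
        "overdispersion": spec.overdispersion,
        "seed": spec.seed,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


def spec_from_yaml(path) -> CommunitySpec:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    strains = tuple(StrainSpec(**s) for s in data.pop("strains"))
    spike = SpikeDesign(**data.pop("spike"))
    return CommunitySpec(strains=strains, spike=spike, **data)
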
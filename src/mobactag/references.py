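"""Reference amplicon sets for read assignment.

A reference set holds one amplicon sequence per feature: endogenous 16S
V5-V7 per strain, barcode tags, spike tags, plant ITS and fungal ITS.
Near-isogenic strains (wild type vs point/insertion mutants) share an
identical 16S amplicon and must be collapsed into one shared 16S feature;
their resolution comes exclusively from their barcode-tag features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import SeqIO

from .oligo import reverse_complement

FEATURE_CLASSES = (
    "endogenous_16S",
    "barcode_tag",
    "spike_tag",
    "plant_ITS",
    "fungal_ITS",
)


class ReferenceError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceFeature:
    feature_id: str
    feature_class: str
    sequence: str
    source_id: str | None = None  # strain or host the feature belongs to

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ReferenceError(
                f"unknown feature class {self.feature_class!r} for {self.feature_id!r}"
            )
        if not self.sequence:
            raise ReferenceError(f"empty sequence for feature {self.feature_id!r}")


@dataclass(frozen=True)
class ReferenceSet:
    features: tuple[ReferenceFeature, ...]

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_seqs: dict[str, str] = {}
        for feat in self.features:
            if feat.feature_id in seen_ids:
                raise ReferenceError(f"duplicate feature id {feat.feature_id!r}")
            seen_ids.add(feat.feature_id)
            seq = feat.sequence.upper()
            rc = reverse_complement(seq)
            for variant in (seq, rc):
                if variant in seen_seqs:
                    raise ReferenceError(
                        f"features {seen_seqs[variant]!r} and {feat.feature_id!r} share an "
                        "identical sequence (forward or reverse complement); identical-16S "
                        "strains must be collapsed into one shared endogenous_16S feature"
                    )
            seen_seqs[seq] = feat.feature_id
            seen_seqs[rc] = feat.feature_id

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def classes(self) -> dict[str, str]:
        return {f.feature_id: f.feature_class for f in self.features}

    def of_class(self, feature_class: str) -> list[ReferenceFeature]:
        return [f for f in self.features if f.feature_class == feature_class]


def build_reference_set(
    inputs: Iterable[ReferenceFeature] | str,
    default_class: str | None = None,
) -> ReferenceSet:
    """Build a validated :class:`ReferenceSet`.

    ``inputs`` is either an iterable of :class:`ReferenceFeature` or a path
    to a FASTA whose headers carry structured tokens, e.g.::

        >R13D_16S class=endogenous_16S source=R13D

    ``default_class`` applies to records lacking a ``class=`` token.
    """
    if isinstance(inputs, (str, bytes)) or hasattr(inputs, "__fspath__"):
        features = list(_parse_fasta(inputs, default_class))
    else:
        features = list(inputs)
    if not features:
        raise ReferenceError("reference set is empty")
    return ReferenceSet(features=tuple(features))


def _parse_fasta(path, default_class: str | None) -> Iterable[ReferenceFeature]:
    for record in SeqIO.parse(str(path), "fasta"):
        cls, source = default_class, None
        for token in record.description.split():
            if token.startswith("class="):
                cls = token.split("=", 1)[1]
            elif token.startswith("source="):
                source = token.split("=", 1)[1]
        if cls is None:
            raise ReferenceError(
                f"record {record.id!r} has no class= token and no default class was given"
            )
        yield ReferenceFeature(
            feature_id=record.id,
            feature_class=cls,
            sequence=str(record.seq).upper(),
            source_id=source,
        )


def write_reference_fasta(refs: ReferenceSet, path) -> None:
    with open(path, "w") as handle:
        for feat in refs:
            source = f" source={feat.source_id}" if feat.source_id else ""
            handle.write(f">{feat.feature_id} class={feat.feature_class}{source}\n")
            handle.write(feat.sequence + "\n")
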
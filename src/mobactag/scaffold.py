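"""Tag scaffolds: a barcode array nested inside four primer-pair binding sites.

The chromosomally integrated barcode region carries, around the array,
binding sites for the bacterial 16S V5-V7 primer pair (799/1192), a fungal
ITS pair, a plant ITS pair and a barcode-specific pair.  Any of the four
marker PCRs therefore co-amplifies the tag together with the endogenous
marker of that kingdom, and the tag amplicon is shorter than the
endogenous 16S V5-V7 amplicon, so the two products are size-separable on
a gel.

The default primer-site set uses the canonical 799F/1192R sequences with
degenerate positions resolved to single bases; the fungal sites are the
standard ITS1F/ITS2 oligos; the plant-ITS and barcode-specific sites are
synthetic stand-ins (concrete oligo sequences are not redistributed here).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .ligation import BarcodeArray
from .oligo import max_dinucleotide_repeats, max_homopolymer_run, reverse_complement


class ScaffoldError(ValueError):
    """Scaffold assembly violated a primer-site or amplicon invariant."""


@dataclass(frozen=True)
class PrimerSite:
    """A primer binding site: the primer oligo sequence and its strand.

    ``strand`` is ``+`` for forward primers (site equals the primer
    sequence on the top strand) and ``-`` for reverse primers (the top
    strand carries the reverse complement of the primer).
    """

    name: str
    sequence: str
    strand: str

    def top_strand(self) -> str:
        return self.sequence if self.strand == "+" else reverse_complement(self.sequence)


#: Primer pairs, outermost to innermost in the default layout.
DEFAULT_LAYOUT: tuple[str, ...] = ("16S", "fungal_ITS", "plant_ITS", "barcode")

DEFAULT_PRIMER_SITES: dict[str, PrimerSite] = {
    # 799F / 1192R with degeneracies resolved (M->A, K->T).
    "16S_fwd": PrimerSite("16S_fwd", "AACAGGATTAGATACCCTG", "+"),
    "16S_rev": PrimerSite("16S_rev", "ACGTCATCCCCACCTTCC", "-"),
    # ITS1F / ITS2.
    "fungal_ITS_fwd": PrimerSite("fungal_ITS_fwd", "CTTGGTCATTTAGAGGAAGTAA", "+"),
    "fungal_ITS_rev": PrimerSite("fungal_ITS_rev", "GCTGCGTTCTTCATCGATGC", "-"),
    # Synthetic stand-ins for the plant-ITS p4/p5 pair.
    "plant_ITS_fwd": PrimerSite("plant_ITS_fwd", "GTCCACTGAACCTTATCATT", "+"),
    "plant_ITS_rev": PrimerSite("plant_ITS_rev", "CAGTTGAATCCGAGGTCACT", "-"),
    # Synthetic stand-ins for the barcode-specific pair.
    "barcode_fwd": PrimerSite("barcode_fwd", "TGACCAGTTCGGATAACTGC", "+"),
    "barcode_rev": PrimerSite("barcode_rev", "GACTTCGAGTTACCAGGTCA", "-"),
}

#: Typical endogenous 16S V5-V7 amplicon length (799F..1192R), bp.
ENDOGENOUS_V5V7_BP = 393

_SPACER = "ACT"


@dataclass(frozen=True)
class TagScaffold:
    """A complete barcode region: array, primer sites and their coordinates.

    ``site_locations`` and ``array_location`` are 0-based half-open
    intervals on ``full_sequence``; GenBank output converts to that
    format's 1-based inclusive convention.
    """

    array: BarcodeArray
    primer_sites: Mapping[str, PrimerSite]
    full_sequence: str
    site_locations: Mapping[str, tuple[int, int]]
    array_location: tuple[int, int]
    layout: tuple[str, ...] = DEFAULT_LAYOUT

    def amplicon(self, pair: str) -> str:
        """The in-silico PCR product of one of the four primer pairs."""
        products = in_silico_pcr(
            self.full_sequence,
            self.primer_sites[f"{pair}_fwd"].sequence,
            self.primer_sites[f"{pair}_rev"].sequence,
        )
        if len(products) != 1:
            raise ScaffoldError(
                f"{pair} pair yields {len(products)} amplicons on the scaffold"
            )
        return products[0]


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str) -> list[str]:
    """All products delimited by ``fwd_primer`` and ``rev_primer`` on ``template``.

    The forward primer anneals to the top strand as given; the reverse
    primer anneals where its reverse complement appears downstream.
    """
    rc_rev = reverse_complement(rev_primer)
    products = []
    for start in _find_all(template, fwd_primer):
        for hit in _find_all(template, rc_rev):
            end = hit + len(rc_rev)
            if hit >= start + len(fwd_primer):
                products.append(template[start:end])
    return products


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def assemble_scaffold(
    array: BarcodeArray,
    primer_sites: Mapping[str, PrimerSite] | None = None,
    spacer_layout: Sequence[str] | None = None,
    *,
    spacer: str = _SPACER,
    endogenous_16s_bp: int = ENDOGENOUS_V5V7_BP,
) -> TagScaffold:
    """Nest the array inside the four primer pairs and validate the result.

    The layout lists pairs outermost to innermost; every pair's amplicon
    must span the complete array.  Assembly fails if any primer site (on
    its strand) occurs more than once in the finished sequence -- e.g.
    because the array happens to contain a site verbatim -- or if the 16S
    pair's scaffold amplicon is not shorter than the endogenous V5-V7
    amplicon it must be separable from.
    """
    sites = dict(primer_sites or DEFAULT_PRIMER_SITES)
    layout = tuple(spacer_layout or DEFAULT_LAYOUT)
    required = [f"{pair}_{end}" for pair in layout for end in ("fwd", "rev")]
    missing = [name for name in required if name not in sites]
    if missing:
        raise ScaffoldError(f"missing primer sites: {missing}")

    left_parts: list[tuple[str, str]] = []  # (site name, top-strand seq)
    right_parts: list[tuple[str, str]] = []
    for pair in layout:
        left_parts.append((f"{pair}_fwd", sites[f"{pair}_fwd"].top_strand()))
        right_parts.insert(0, (f"{pair}_rev", sites[f"{pair}_rev"].top_strand()))

    pieces: list[str] = []
    locations: dict[str, tuple[int, int]] = {}
    pos = 0

    def _append(seq: str, name: str | None = None) -> None:
        nonlocal pos
        if name is not None:
            locations[name] = (pos, pos + len(seq))
        pieces.append(seq)
        pos += len(seq)

    for name, seq in left_parts:
        _append(seq, name)
        _append(spacer)
    array_start = pos
    _append(array.sequence)
    array_location = (array_start, pos)
    for name, seq in right_parts:
        _append(spacer)
        _append(seq, name)
    full = "".join(pieces)

    for name in required:
        top = sites[name].top_strand()
        hits = _find_all(full, top)
        if len(hits) != 1:
            raise ScaffoldError(
                f"primer site {name} occurs {len(hits)} times in the scaffold "
                "(expected exactly once on its strand)"
            )

    scaffold = TagScaffold(
        array=array,
        primer_sites=sites,
        full_sequence=full,
        site_locations=locations,
        array_location=array_location,
        layout=layout,
    )
    a0, a1 = array_location
    for pair in layout:
        product = scaffold.amplicon(pair)
        if array.sequence not in product:
            raise ScaffoldError(f"{pair} amplicon does not span the barcode array")
    if len(scaffold.amplicon("16S")) >= endogenous_16s_bp:
        raise ScaffoldError(
            "scaffold 16S amplicon is not shorter than the endogenous V5-V7 "
            f"amplicon ({len(scaffold.amplicon('16S'))} >= {endogenous_16s_bp} bp); "
            "products would not be size-separable"
        )
    return scaffold


def scaffold_to_record(scaffold: TagScaffold, name: str = "tag_scaffold") -> SeqRecord:
    """Annotated GenBank-style record (features in 1-based inclusive coords)."""
    record = SeqRecord(Seq(scaffold.full_sequence), id=name, name=name[:16],
                       description="barcode tag scaffold")
    record.annotations["molecule_type"] = "DNA"
    for site_name, (start, end) in scaffold.site_locations.items():
        strand = 1 if scaffold.primer_sites[site_name].strand == "+" else -1
        record.features.append(
            SeqFeature(
                FeatureLocation(start, end, strand=strand),
                type="primer_bind",
                qualifiers={"label": [site_name]},
            )
        )
    a0, a1 = scaffold.array_location
    units = ",".join(f"{label}{orient}" for label, orient in scaffold.array.units)
    record.features.append(
        SeqFeature(
            FeatureLocation(a0, a1, strand=1),
            type="misc_feature",
            qualifiers={"label": ["barcode_array"], "note": [f"units={units}"]},
        )
    )
    return record


def write_scaffold_genbank(scaffold: TagScaffold, path, name: str = "tag_scaffold") -> None:
    SeqIO.write([scaffold_to_record(scaffold, name)], str(path), "genbank")


def extract_array_from_record(record: SeqRecord) -> BarcodeArray:
    """Re-extract the barcode array from an annotated scaffold record."""
    for feature in record.features:
        if feature.type == "misc_feature" and feature.qualifiers.get("label") == ["barcode_array"]:
            seq = str(feature.extract(record.seq)).upper()
            units: tuple[tuple[str, str], ...] = ()
            for note in feature.qualifiers.get("note", []):
                if note.startswith("units="):
                    units = tuple((u[:-1], u[-1]) for u in note[6:].split(",") if u)
            return BarcodeArray(units=units, sequence=seq)
    raise ScaffoldError("record carries no barcode_array feature")


def _both_strand_distance(a: str, b: str) -> int:
    fwd = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    rev = edlib.align(a, reverse_complement(b), task="distance", mode="NW")["editDistance"]
    return min(fwd, rev)


@dataclass
class TagSetReport:
    """Pairwise-distinguishability report for a set of tag scaffolds."""

    pairwise_distances: dict[tuple[str, str], int]
    flagged_pairs: list[tuple[str, str, int]]
    tract_violations: list[tuple[str, str]]
    min_distance_threshold: int

    @property
    def passed(self) -> bool:
        return not self.flagged_pairs and not self.tract_violations


def check_tag_set(
    tags: Mapping[str, TagScaffold] | Sequence[TagScaffold],
    min_pairwise_edit_distance: int,
    *,
    max_homopolymer: int = 2,
    max_dinucleotide: int = 2,
) -> TagSetReport:
    """Validate that a tag set is mutually distinguishable and tract-free.

    Distances are Levenshtein distances between array sequences, minimized
    over strand pairings (a tag and its reverse complement are the same
    molecule).  Pairs below the threshold and arrays with homopolymer or
    dinucleotide tract violations are flagged; the set passes iff nothing
    is flagged.
    """
    if not isinstance(tags, Mapping):
        tags = {f"tag{i}": t for i, t in enumerate(tags)}
    if not tags:
        raise ValueError("check_tag_set requires at least one tag")
    distances: dict[tuple[str, str], int] = {}
    flagged: list[tuple[str, str, int]] = []
    for (na, ta), (nb, tb) in itertools.combinations(tags.items(), 2):
        d = _both_strand_distance(ta.array.sequence, tb.array.sequence)
        distances[(na, nb)] = d
        if d < min_pairwise_edit_distance:
            flagged.append((na, nb, d))
    tract_violations: list[tuple[str, str]] = []
    for name, tag in tags.items():
        seq = tag.array.sequence
        if max_homopolymer_run(seq) > max_homopolymer:
            tract_violations.append((name, "homopolymer"))
        if max_dinucleotide_repeats(seq) > max_dinucleotide:
            tract_violations.append((name, "dinucleotide"))
    return TagSetReport(
        pairwise_distances=distances,
        flagged_pairs=flagged,
        tract_violations=tract_violations,
        min_distance_threshold=min_pairwise_edit_distance,
    )


def enumerate_marker_combinations(
    antibiotics: Sequence[str], fluorophores: Sequence[str]
) -> list[tuple[str, str]]:
    """Cartesian product of selection markers, in deterministic input order.

    Four antibiotic resistances crossed with five fluorescent proteins give
    the 20 marker combinations a vector kit provides.
    """
    if not antibiotics or not fluorophores:
        raise ValueError("antibiotic and fluorophore lists must both be non-empty")
    return [(a, f) for a in antibiotics for f in fluorophores]
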
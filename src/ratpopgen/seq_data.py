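"""Per-locus coding alignments and codon-aware site classification.

A locus is a pre-aligned set of allele sequences from one or two populations,
each tagged with the individual it came from and which of the individual's
two alleles it is.  The reading frame is supplied as metadata.  Sites are
partitioned into synonymous and replacement classes by Nei-Gojobori counting
under the standard nuclear genetic code: each codon position contributes a
fraction of a synonymous site equal to the proportion of its three possible
single-base changes that preserve the encoded amino acid.

FASTA header convention: ``>individualID|allele|populationID`` with allele in
{1, 2}, e.g. ``>CH04|2|China``.  The locus metadata table is tab-separated
with columns ``locus_id``, ``fasta_path``, ``frame_offset`` and an optional
``outgroup_path`` (FASTA with a single aligned outgroup sequence).

Coordinates are 0-based half-open internally; report layers use 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from ratpopgen.errors import (
    AlignmentLengthError,
    CoordinateError,
    EmptyCountsError,
    InputError,
    MetadataError,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"

SYNONYMOUS = "synonymous"
REPLACEMENT = "replacement"
EXCLUDED = "excluded"

#: Codon -> amino acid (one letter), "*" for stops.  Built from the standard
#: (vertebrate nuclear) code; the table is data so alternate codes could be
#: substituted.
STANDARD_CODE: dict[str, str] = {}
_table = CodonTable.unambiguous_dna_by_id[1]
for _codon, _aa in _table.forward_table.items():
    STANDARD_CODE[_codon] = _aa
for _codon in _table.stop_codons:
    STANDARD_CODE[_codon] = "*"
del _table, _codon


@lru_cache(maxsize=None)
def synonymous_fraction(codon: str, position: int) -> float:
    """Fraction of the three single-base changes at ``position`` (0-2) of
    ``codon`` that preserve the amino acid.  Changes to a stop codon count as
    non-preserving."""
    aa = STANDARD_CODE[codon]
    preserved = 0
    for base in BASES:
        if base == codon[position]:
            continue
        mutant = codon[:position] + base + codon[position + 1 :]
        if STANDARD_CODE[mutant] == aa:
            preserved += 1
    return preserved / 3.0


@dataclass(frozen=True)
class AlleleLabel:
    individual_id: str
    allele_index: int  # 1 or 2
    population_id: str


@dataclass(frozen=True)
class LocusMetadata:
    locus_id: str
    fasta_path: str
    frame_offset: int
    outgroup_path: str | None = None


@dataclass
class LocusAlignment:
    """One coding locus: aligned allele sequences with individual and
    population labels, a reading frame, and an optional outgroup sequence."""

    locus_id: str
    sequences: list[str]
    allele_labels: list[AlleleLabel]
    frame_offset: int = 0
    outgroup_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise InputError(f"locus {self.locus_id}: no sequences")
        lengths = {len(s) for s in self.sequences}
        if self.outgroup_seq is not None:
            lengths.add(len(self.outgroup_seq))
        if len(lengths) != 1:
            raise AlignmentLengthError(
                f"locus {self.locus_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        if len(self.allele_labels) != len(self.sequences):
            raise MetadataError(
                f"locus {self.locus_id}: {len(self.allele_labels)} labels for "
                f"{len(self.sequences)} sequences"
            )
        if not 0 <= self.frame_offset <= 2:
            raise MetadataError(
                f"locus {self.locus_id}: frame_offset {self.frame_offset} not in 0-2"
            )
        if self.length - self.frame_offset < 3:
            raise MetadataError(f"locus {self.locus_id}: no complete codon in frame")
        self.sequences = [s.upper() for s in self.sequences]
        if self.outgroup_seq is not None:
            self.outgroup_seq = self.outgroup_seq.upper()
        allowed = set("ACGTN-")
        for lab, s in zip(self.allele_labels, self.sequences):
            bad = set(s) - allowed
            if bad:
                raise InputError(
                    f"locus {self.locus_id}, {lab.individual_id}: illegal characters {bad}"
                )
        # at most two alleles per individual
        seen: dict[tuple[str, int], int] = {}
        for lab in self.allele_labels:
            key = (lab.individual_id, lab.allele_index)
            seen[key] = seen.get(key, 0) + 1
            if seen[key] > 1:
                raise MetadataError(
                    f"locus {self.locus_id}: duplicate allele {key[0]}|{key[1]}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_alleles(self) -> int:
        return len(self.sequences)

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for lab in self.allele_labels:
            if lab.population_id not in out:
                out.append(lab.population_id)
        return out

    def indices_for(self, population: str | None) -> list[int]:
        """Row indices of sequences belonging to ``population`` (all if None)."""
        if population is None:
            return list(range(self.n_alleles))
        idx = [
            i
            for i, lab in enumerate(self.allele_labels)
            if lab.population_id == population
        ]
        if not idx:
            raise MetadataError(
                f"locus {self.locus_id}: no sequences for population {population!r}"
            )
        return idx

    def subset(self, population: str | None) -> list[str]:
        return [self.sequences[i] for i in self.indices_for(population)]

    def codon_starts(self) -> list[int]:
        """Start coordinates of complete codons in the declared frame."""
        return list(range(self.frame_offset, self.length - 2, 3))

    def variable_positions(self, population: str | None = None) -> list[int]:
        """Aligned columns with >= 2 distinct non-missing states among the
        chosen ingroup alleles."""
        seqs = self.subset(population)
        out = []
        for pos in range(self.length):
            states = {s[pos] for s in seqs} - {"N", "-"}
            if len(states) >= 2:
                out.append(pos)
        return out


@dataclass
class SiteClassCounts:
    """Effective (fractional) synonymous and replacement site totals for a
    locus plus the class of every variable coding position."""

    syn_sites: float
    repl_sites: float
    site_class_by_position: dict[int, str] = field(default_factory=dict)
    exclusion_reasons: dict[int, str] = field(default_factory=dict)
    n_codons_included: int = 0
    n_codons_excluded: int = 0

    def n_variable(self, site_class: str) -> int:
        return sum(1 for c in self.site_class_by_position.values() if c == site_class)


def _parse_header(header: str) -> AlleleLabel:
    parts = header.split("|")
    if len(parts) != 3:
        raise InputError(
            f"header {header!r} does not follow individual|allele|population"
        )
    indiv, allele, pop = parts
    if allele not in ("1", "2"):
        raise InputError(f"header {header!r}: allele index must be 1 or 2")
    if not indiv or not pop:
        raise InputError(f"header {header!r}: empty individual or population field")
    return AlleleLabel(indiv, int(allele), pop)


def read_locus_alignment(
    path: str | Path,
    metadata: LocusMetadata,
    known_populations: Iterable[str] | None = None,
) -> LocusAlignment:
    """Read one locus FASTA into a validated :class:`LocusAlignment`.

    Headers that do not parse raise :class:`InputError` rather than being
    skipped.  If ``known_populations`` is given, any other population label is
    a :class:`MetadataError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: empty FASTA")
    labels = [_parse_header(r.description.strip()) for r in records]
    if known_populations is not None:
        known = set(known_populations)
        for lab in labels:
            if lab.population_id not in known:
                raise MetadataError(
                    f"{path}: unknown population label {lab.population_id!r}"
                )
    outgroup = None
    if metadata.outgroup_path:
        og = list(SeqIO.parse(str(metadata.outgroup_path), "fasta"))
        if len(og) != 1:
            raise InputError(
                f"{metadata.outgroup_path}: expected exactly one outgroup sequence"
            )
        outgroup = str(og[0].seq).upper()
    return LocusAlignment(
        locus_id=metadata.locus_id,
        sequences=[str(r.seq) for r in records],
        allele_labels=labels,
        frame_offset=metadata.frame_offset,
        outgroup_seq=outgroup,
    )


def read_locus_table(path: str | Path) -> list[LocusMetadata]:
    """Read the tab-separated locus metadata table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "fasta_path", "frame_offset"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: missing columns {sorted(missing)}")
    base = Path(path).parent
    out = []
    for _, row in df.iterrows():
        og = row.get("outgroup_path")
        og = None if (og is None or pd.isna(og) or og == "") else str(base / og)
        out.append(
            LocusMetadata(
                locus_id=row["locus_id"],
                fasta_path=str(base / row["fasta_path"]),
                frame_offset=int(row["frame_offset"]),
                outgroup_path=og,
            )
        )
    if not out:
        raise MetadataError(f"{path}: empty locus table")
    return out


def read_study(path: str | Path) -> list[LocusAlignment]:
    """Read every locus listed in a metadata table."""
    return [
        read_locus_alignment(m.fasta_path, m) for m in read_locus_table(path)
    ]


def _consensus_codon(codons: Sequence[str]) -> str:
    """Majority base per position; ties broken by the first-listed allele."""
    out = []
    for pos in range(3):
        counts: dict[str, int] = {}
        for c in codons:
            counts[c[pos]] = counts.get(c[pos], 0) + 1
        best = max(counts.values())
        # first-listed allele among the tied bases
        for c in codons:
            if counts[c[pos]] == best:
                out.append(c[pos])
                break
    return "".join(out)


def _codon_ok(codon: str) -> bool:
    return all(b in BASES for b in codon)


def count_site_classes(
    aln: LocusAlignment, population: str | None = None
) -> SiteClassCounts:
    """Nei-Gojobori synonymous/replacement site totals for a locus.

    Codons containing N or a gap in any analysed ingroup sequence are
    excluded for all sequences (complete-case per codon), as is any codon
    whose majority-consensus translates to a stop.  Fractions are computed on
    the consensus codon.  Variable positions within included codons are
    classified by translating the observed codon variants; codons segregating
    at more than one position are excluded (ambiguous mutational pathway).
    """
    seqs = aln.subset(population)
    syn = 0.0
    repl = 0.0
    classes: dict[int, str] = {}
    reasons: dict[int, str] = {}
    n_inc = 0
    n_exc = 0

    def mark_excluded(start: int, codon_cols: list[set[str]], why: str) -> None:
        for off in range(3):
            states = codon_cols[off] - {"N", "-"}
            if len(states) >= 2:
                classes[start + off] = EXCLUDED
                reasons[start + off] = why

    for start in aln.codon_starts():
        codons = [s[start : start + 3] for s in seqs]
        cols = [{c[off] for c in codons} for off in range(3)]
        if not all(_codon_ok(c) for c in codons):
            n_exc += 1
            mark_excluded(start, cols, "missing_data_in_codon")
            continue
        consensus = _consensus_codon(codons)
        if STANDARD_CODE[consensus] == "*":
            n_exc += 1
            logger.warning(
                "locus %s: stop codon %s in consensus at %d-%d, codon excluded",
                aln.locus_id,
                consensus,
                start,
                start + 3,
            )
            mark_excluded(start, cols, "stop_codon_in_consensus")
            continue
        n_inc += 1
        for off in range(3):
            syn += synonymous_fraction(consensus, off)
        variable_offs = [off for off in range(3) if len(cols[off]) >= 2]
        if not variable_offs:
            continue
        if len(variable_offs) > 1:
            mark_excluded(start, cols, "multiple_segregating_positions_in_codon")
            logger.info(
                "locus %s: codon at %d segregates at %d positions, excluded",
                aln.locus_id,
                start,
                len(variable_offs),
            )
            continue
        off = variable_offs[0]
        aas = {STANDARD_CODE[c] for c in set(codons)}
        classes[start + off] = SYNONYMOUS if len(aas) == 1 else REPLACEMENT

    if n_inc == 0:
        raise EmptyCountsError(f"locus {aln.locus_id}: no complete codon to count")
    # recompute repl exactly from the identity syn+repl = 3 per included codon
    repl = 3.0 * n_inc - syn
    return SiteClassCounts(
        syn_sites=syn,
        repl_sites=repl,
        site_class_by_position=classes,
        exclusion_reasons=reasons,
        n_codons_included=n_inc,
        n_codons_excluded=n_exc,
    )


def classify_variable_site(
    aln: LocusAlignment, position: int, population: str | None = None
) -> str:
    """Class of one variable aligned position: ``synonymous``, ``replacement``
    or ``excluded``.

    Raises :class:`CoordinateError` for an out-of-range position and
    ``ValueError`` if the position is monomorphic (classification of an
    invariant site is undefined).
    """
    if not 0 <= position < aln.length:
        raise CoordinateError(
            f"position {position} outside alignment of length {aln.length}"
        )
    seqs = aln.subset(population)
    states = {s[position] for s in seqs} - {"N", "-"}
    if len(states) < 2:
        raise ValueError(f"position {position} is not variable")
    if position < aln.frame_offset or position >= aln.frame_offset + 3 * (
        (aln.length - aln.frame_offset) // 3
    ):
        return EXCLUDED  # outside the complete-codon region
    counts = count_site_classes(aln, population)
    return counts.site_class_by_position.get(position, EXCLUDED)


def complete_case_alleles(
    aln: LocusAlignment,
    population: str | None = None,
    max_missing_fraction: float = 0.2,
) -> list[int]:
    """Indices of alleles with < ``max_missing_fraction`` missing sites,
    used as the per-locus n for Watterson-type statistics."""
    idx = aln.indices_for(population)
    keep = []
    for i in idx:
        s = aln.sequences[i]
        miss = sum(1 for b in s if b in "N-") / len(s)
        if miss < max_missing_fraction:
            keep.append(i)
        else:
            logger.info(
                "locus %s: allele %s|%d dropped (%.0f%% missing)",
                aln.locus_id,
                aln.allele_labels[i].individual_id,
                aln.allele_labels[i].allele_index,
                100 * miss,
            )
    return keep
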
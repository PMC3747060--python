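"""Reference-anchored mitogenome I/O and variant profiling.

Every position in this package is a 1-based coordinate on the bovine
mitochondrial reference sequence (BRS numbering, ~16.3 kb, circular).
Sample genomes are aligned globally against the reference and their
differences are stored as sparse :class:`Variant` records, so downstream
modules (haplogroup classification, diversity statistics, haplotype
networks) never have to re-derive coordinates. Insertions are anchored
to the preceding reference base and printed with a ``.1`` suffix
(e.g. ``16201.1A``), which keeps reference numbering stable downstream
of the event. Circularity is recorded on the reference but alignment is
linear from position 1, matching how complete mitogenomes are deposited.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from Bio import Align

VALID_BASES = frozenset("ACGT")
PURINES = frozenset("AG")

#: Transition partner of each base (purine<->purine, pyrimidine<->pyrimidine).
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

TRANSITION = "transition"
TRANSVERSION = "transversion"
INDEL = "indel"

# Fixed alignment scores; near-identical mitogenomes are insensitive to the
# exact values but they are pinned here for reproducibility.
DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = -5.0
DEFAULT_GAP_EXTEND = -2.0


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class InvalidAlleleError(ValueError):
    """Raised for alleles outside {A,C,G,T} or inconsistent variant fields."""


class NotHomologousError(ValueError):
    """Raised when a query cannot be treated as a same-locus mitogenome."""


class SiteSpecError(ValueError):
    """Raised for invalid or conflicting symbolic site specifications."""


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Classify a single-base substitution as transition or transversion.

    Purine<->purine and pyrimidine<->pyrimidine changes are transitions;
    all purine<->pyrimidine changes are transversions. The classification
    is symmetric in its arguments.
    """
    ref_base = str(ref_base).upper()
    alt_base = str(alt_base).upper()
    if ref_base not in VALID_BASES or alt_base not in VALID_BASES:
        raise InvalidAlleleError(
            f"substitution alleles must be in A/C/G/T, got {ref_base!r}->{alt_base!r}"
        )
    if ref_base == alt_base:
        raise InvalidAlleleError(f"substitution with identical alleles {ref_base!r}")
    same_family = (ref_base in PURINES) == (alt_base in PURINES)
    return TRANSITION if same_family else TRANSVERSION


@dataclass(frozen=True)
class ReferenceGenome:
    """A mitochondrial reference sequence defining the coordinate system."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("reference sequence must be non-empty")
        bad = set(seq) - (VALID_BASES | {"N"})
        if bad:
            raise ValueError(f"reference contains invalid characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Return the reference base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValueError(f"position {position} outside reference [1, {len(self)}]")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Variant:
    """A single difference from the reference, in reference coordinates.

    ``position`` is 1-based; insertions sit between ``position`` and
    ``position + 1`` (anchored to the preceding reference base) with an
    empty ``ref_allele``; deletions carry the removed reference bases and
    an empty ``alt_allele``.
    """

    position: int
    kind: str
    ref_allele: str = ""
    alt_allele: str = ""
    mutation_class: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.kind == SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise InvalidAlleleError("substitution alleles must be single bases")
            cls = classify_substitution(self.ref_allele, self.alt_allele)
        elif self.kind == INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise InvalidAlleleError(
                    "insertion requires empty ref_allele and non-empty alt_allele"
                )
            cls = INDEL
        elif self.kind == DELETION:
            if self.alt_allele or not self.ref_allele:
                raise InvalidAlleleError(
                    "deletion requires non-empty ref_allele and empty alt_allele"
                )
            cls = INDEL
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.mutation_class and self.mutation_class != cls:
            raise InvalidAlleleError(
                f"mutation_class {self.mutation_class!r} inconsistent with alleles"
            )
        object.__setattr__(self, "mutation_class", cls)

    @classmethod
    def substitution(cls, position: int, ref: str, alt: str) -> "Variant":
        return cls(position, SUBSTITUTION, ref, alt)

    @classmethod
    def insertion(cls, position: int, alt: str) -> "Variant":
        return cls(position, INSERTION, "", alt)

    @classmethod
    def deletion(cls, position: int, ref: str) -> "Variant":
        return cls(position, DELETION, ref, "")

    @property
    def sort_key(self) -> tuple:
        return (self.position, self.kind, self.alt_allele, self.ref_allele)

    @property
    def label(self) -> str:
        """Compact text form, e.g. ``16050C>T``, ``16201.1A``, ``42delG``."""
        if self.kind == SUBSTITUTION:
            return f"{self.position}{self.ref_allele}>{self.alt_allele}"
        if self.kind == INSERTION:
            return f"{self.position}.1{self.alt_allele}"
        return f"{self.position}del{self.ref_allele}"


class VariantProfile:
    """A sample's set of differences from the reference.

    Variants are unique by ``(position, kind)`` — in particular no two
    substitutions can share a position — and iteration is sorted by
    position. ``ambiguous_sites`` records reference positions where the
    sample carried an N (never emitted as variants; downstream statistics
    can exclude them).
    """

    def __init__(
        self,
        sample_id: str,
        population: str = "",
        variants: Iterable[Variant] = (),
        ambiguous_sites: Iterable[int] = (),
    ) -> None:
        self.sample_id = sample_id
        self.population = population
        self._variants: dict[tuple[int, str], Variant] = {}
        self.ambiguous_sites: set[int] = set(ambiguous_sites)
        for v in variants:
            self.add(v)

    def add(self, variant: Variant) -> None:
        key = (variant.position, variant.kind)
        if key in self._variants and self._variants[key] != variant:
            raise SiteSpecError(
                f"conflicting {variant.kind} entries at position {variant.position} "
                f"for sample {self.sample_id!r}"
            )
        self._variants[key] = variant

    def __iter__(self) -> Iterator[Variant]:
        return iter(sorted(self._variants.values(), key=lambda v: v.sort_key))

    def __len__(self) -> int:
        return len(self._variants)

    def __contains__(self, variant: Variant) -> bool:
        return self._variants.get((variant.position, variant.kind)) == variant

    def __repr__(self) -> str:
        return (
            f"VariantProfile({self.sample_id!r}, {self.population!r}, "
            f"{len(self)} variants)"
        )

    def substitution_at(self, position: int) -> Variant | None:
        return self._variants.get((position, SUBSTITUTION))

    def insertion_at(self, position: int) -> Variant | None:
        return self._variants.get((position, INSERTION))

    def deletion_at(self, position: int) -> Variant | None:
        return self._variants.get((position, DELETION))

    def variant_set(self) -> frozenset[Variant]:
        """Hashable identity of the profile, used for haplotype condensation."""
        return frozenset(self._variants.values())


# ---------------------------------------------------------------------------
# FASTA I/O
#
# Parsing is done directly (rather than through Bio.SeqIO) because the
# contract here includes line-numbered structural errors and a warning on
# duplicate record ids, neither of which SeqIO reports.
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path], keep_gaps: bool = False) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` tuples in file order.

    Sequences are uppercased with whitespace removed; alignment gap
    characters (``-``/``.``) are stripped unless ``keep_gaps`` is set
    (use ``keep_gaps=True`` to read a multiple alignment). The record id
    is the first whitespace-delimited token of the header. Duplicated ids
    are returned but reported through the warnings channel.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: str | None = None
    parts: list[str] = []

    def flush() -> None:
        if header is not None:
            records.append((header, "".join(parts)))

    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                tokens = line[1:].split()
                if not tokens:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                flush()
                header = tokens[0]
                parts = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                seq = "".join(line.split()).upper()
                if not keep_gaps:
                    seq = seq.replace("-", "").replace(".", "")
                parts.append(seq)
    flush()
    if not records:
        raise FastaParseError(f"{path}: empty FASTA file (no records) at line 1")
    ids = [r[0] for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        warnings.warn(f"{path}: duplicate FASTA ids: {', '.join(dupes)}", UserWarning)
    return records


def write_fasta(
    path: Union[str, Path], records: Iterable[tuple[str, str]], width: int = 70
) -> Path:
    """Write ``(id, sequence)`` records as FASTA with fixed line wrapping."""
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Alignment-based variant extraction
# ---------------------------------------------------------------------------

def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_to_reference(
    sequence: str,
    reference: ReferenceGenome,
    sample_id: str = "query",
    population: str = "",
    *,
    match_score: float = DEFAULT_MATCH,
    mismatch_score: float = DEFAULT_MISMATCH,
    open_gap_score: float = DEFAULT_GAP_OPEN,
    extend_gap_score: float = DEFAULT_GAP_EXTEND,
    min_identity: float = 0.90,
    max_length_deviation: float = 0.05,
) -> VariantProfile:
    """Globally align a mitogenome to the reference and extract its variants.

    Aligned mismatches become substitution variants at the reference
    coordinate; gap runs in the reference become insertions anchored to
    the preceding reference position, and gap runs in the query become
    deletions. Columns involving an N on either side are recorded in
    ``ambiguous_sites`` and never emitted as variants.
    """
    seq = "".join(str(sequence).split()).upper()
    ref = reference.sequence
    if abs(len(seq) - len(ref)) > max_length_deviation * len(ref):
        raise NotHomologousError(
            f"query length {len(seq)} deviates more than "
            f"{max_length_deviation:.0%} from reference length {len(ref)}"
        )
    aligner = _make_aligner(match_score, mismatch_score, open_gap_score, extend_gap_score)
    alignment = aligner.align(ref, seq)[0]
    ref_aln, qry_aln = str(alignment[0]), str(alignment[1])

    aligned_cols = matches = 0
    for r, q in zip(ref_aln, qry_aln):
        if r != "-" and q != "-":
            aligned_cols += 1
            matches += r == q
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < min_identity:
        raise NotHomologousError(
            f"alignment identity {identity:.3f} below {min_identity:.2f}; "
            f"query is not homologous to reference {reference.id}"
        )

    profile = VariantProfile(sample_id, population)
    n_cols = len(ref_aln)
    ref_pos = 0  # last consumed 1-based reference position
    i = 0
    while i < n_cols:
        r, q = ref_aln[i], qry_aln[i]
        if r != "-" and q != "-":
            ref_pos += 1
            if r != q:
                if "N" in (r, q):
                    profile.ambiguous_sites.add(ref_pos)
                else:
                    profile.add(Variant.substitution(ref_pos, r, q))
            i += 1
        elif r == "-":
            j = i
            while j < n_cols and ref_aln[j] == "-":
                j += 1
            inserted = qry_aln[i:j].replace("-", "")
            if "N" in inserted:
                profile.ambiguous_sites.add(max(ref_pos, 1))
            elif ref_pos >= 1:  # leading insertions have no anchor; skip
                profile.add(Variant.insertion(ref_pos, inserted))
            i = j
        else:  # deletion in query
            j = i
            while j < n_cols and qry_aln[j] == "-" and ref_aln[j] != "-":
                j += 1
            deleted = ref_aln[i:j]
            if "N" in deleted:
                profile.ambiguous_sites.update(range(ref_pos + 1, ref_pos + 1 + len(deleted)))
            else:
                profile.add(Variant.deletion(ref_pos + 1, deleted))
            ref_pos += len(deleted)
            i = j
    return profile


# ---------------------------------------------------------------------------
# Symbolic site lists ("16255:Ts" notation)
# ---------------------------------------------------------------------------

SiteEntry = Union[str, tuple]


def profile_from_site_list(
    sample_id: str,
    population: str,
    site_spec: Sequence[SiteEntry],
    reference: ReferenceGenome,
) -> VariantProfile:
    """Build a profile from symbolic site entries against a reference.

    Entries are ``(position, code)`` pairs or ``"position:code"`` strings
    with codes:

    - ``"Ts"`` — transition relative to the reference base;
    - two bases such as ``"AT"`` — explicit substitution (ref ``A`` to
      alt ``T``; the stated ref base must match the reference);
    - ``"+X"`` — single/multi-base insertion after the position;
    - ``"-"`` — deletion of the reference base at the position.
    """
    profile = VariantProfile(sample_id, population)
    seen: set[tuple[int, str]] = set()
    for entry in site_spec:
        if isinstance(entry, str):
            pos_str, _, code = entry.partition(":")
            try:
                position = int(pos_str)
            except ValueError as exc:
                raise SiteSpecError(f"invalid site entry {entry!r}") from exc
        else:
            position, code = entry
            position = int(position)
        code = str(code).strip()
        if not 1 <= position <= len(reference):
            raise SiteSpecError(
                f"position {position} outside reference [1, {len(reference)}]"
            )
        ref_base = reference.base(position)
        if code == "Ts":
            if ref_base == "N":
                raise SiteSpecError(f"reference base at {position} is N")
            variant = Variant.substitution(position, ref_base, TRANSITION_PARTNER[ref_base])
        elif code.startswith("+"):
            variant = Variant.insertion(position, code[1:])
        elif code == "-":
            variant = Variant.deletion(position, ref_base)
        elif len(code) == 2 and set(code.upper()) <= VALID_BASES:
            stated_ref, alt = code.upper()
            if stated_ref != ref_base:
                raise SiteSpecError(
                    f"site {position}: spec ref allele {stated_ref!r} does not match "
                    f"reference base {ref_base!r}"
                )
            variant = Variant.substitution(position, stated_ref, alt)
        else:
            raise SiteSpecError(f"unrecognised allele code {code!r} at {position}")
        key = (variant.position, variant.kind)
        if key in seen:
            raise SiteSpecError(
                f"duplicate {variant.kind} entry at position {variant.position} "
                f"for sample {sample_id!r}"
            )
        seen.add(key)
        profile.add(variant)
    return profile


# ---------------------------------------------------------------------------
# TSV export/import of profiles
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["sample_id", "population", "position", "kind", "ref", "alt", "class"]


def profiles_to_tsv(profiles: Iterable[VariantProfile], path: Union[str, Path]) -> Path:
    """Write variant profiles as a flat TSV (one row per variant)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for profile in profiles:
            if len(profile) == 0:
                writer.writerow([profile.sample_id, profile.population, "", "", "", "", ""])
            for v in profile:
                writer.writerow(
                    [
                        profile.sample_id,
                        profile.population,
                        v.position,
                        v.kind,
                        v.ref_allele,
                        v.alt_allele,
                        v.mutation_class,
                    ]
                )
    return path


def profiles_from_tsv(path: Union[str, Path]) -> list[VariantProfile]:
    """Read profiles written by :func:`profiles_to_tsv` (inverse mapping)."""
    path = Path(path)
    profiles: dict[str, VariantProfile] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sid = row["sample_id"]
            if sid not in profiles:
                profiles[sid] = VariantProfile(sid, row["population"])
            if not row["position"]:
                continue  # placeholder row for an empty profile
            pos = int(row["position"])
            kind = row["kind"]
            if kind == SUBSTITUTION:
                v = Variant.substitution(pos, row["ref"], row["alt"])
            elif kind == INSERTION:
                v = Variant.insertion(pos, row["alt"])
            elif kind == DELETION:
                v = Variant.deletion(pos, row["ref"])
            else:
                raise SiteSpecError(f"{path}: unknown variant kind {kind!r}")
            profiles[sid].add(v)
    return list(profiles.values())
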
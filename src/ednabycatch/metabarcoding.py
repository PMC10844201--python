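"""Simplified metabarcoding read processing: length filter and identity ladder.

Amplicon reads (a ~340-380 bp COI fragment) are first filtered by length,
then assigned taxonomically by pairwise alignment against two reference
amplicons (herring, Clupea harengus, and sprat, Sprattus sprattus).  The
tiered assignment requires an alignment overlap of at least 80% of the
340 bp amplicon (272 bp) and places a read at

* species level when the best identity is >= 85%,
* genus level when >= 82%,
* family level when >= 80%,
* otherwise unassigned.

Identity is computed as matches over aligned columns within the overlapping
region of a semi-global alignment (free end gaps; match/mismatch/gap =
+1/-1/-2).  Ties in best identity between references are resolved
conservatively: the read is assigned at the deepest taxonomic level on
which the tied references agree (for herring vs sprat that is the shared
family Clupeidae), never at species level.

Species-level read counts yield the herring read fraction used as an
alternative observed eDNA fraction; genus/family-level and unassigned
reads are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import Align

__all__ = [
    "ReadRecord",
    "Reference",
    "AssignmentResult",
    "LEVELS",
    "SPECIES_IDENTITY",
    "GENUS_IDENTITY",
    "FAMILY_IDENTITY",
    "MIN_OVERLAP_BP",
    "DEFAULT_LENGTH_RANGE",
    "filter_by_length",
    "classify_read",
    "compute_read_fractions",
    "load_references",
    "bundled_references",
]

SPECIES_IDENTITY = 0.85
GENUS_IDENTITY = 0.82
FAMILY_IDENTITY = 0.80
#: Minimum alignment overlap: 80% of the 340 bp amplicon.
MIN_OVERLAP_BP = 272
#: Length filter bounds in bp, inclusive on both ends.
DEFAULT_LENGTH_RANGE = (340, 380)

#: Assignment levels from deepest to shallowest.
LEVELS = ("species", "genus", "family", "unassigned")
_LEVEL_DEPTH = {lvl: i for i, lvl in enumerate(LEVELS)}

_ALLOWED = set("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - _ALLOWED:
            raise ValueError(f"read {self.read_id}: alphabet outside ACGTN")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Reference:
    """A reference amplicon with its taxonomy."""

    name: str
    sequence: str
    species: str
    genus: str
    family: str

    def taxon_at(self, level: str) -> str:
        return {"species": self.species, "genus": self.genus, "family": self.family}[level]


@dataclass(frozen=True)
class AssignmentResult:
    read_id: str
    level: str  # species | genus | family | unassigned
    taxon: str | None
    best_identity: float
    overlap: int


def filter_by_length(
    reads: list[ReadRecord],
    min_bp: int = DEFAULT_LENGTH_RANGE[0],
    max_bp: int = DEFAULT_LENGTH_RANGE[1],
) -> list[ReadRecord]:
    """Retain reads with min_bp <= length <= max_bp (both ends inclusive)."""
    if min_bp > max_bp:
        raise ValueError("min_bp must not exceed max_bp")
    return [r for r in reads if min_bp <= r.length <= max_bp]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    # free end gaps: semi-global overlap alignment
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _identity_and_overlap(ref_seq: str, read_seq: str) -> tuple[float, int]:
    """Identity over aligned columns in the overlap, and overlap width in ref bp."""
    alignment = _ALIGNER.align(ref_seq, read_seq)[0]
    blocks_ref, blocks_read = alignment.aligned
    if len(blocks_ref) == 0:
        return 0.0, 0
    matches = 0
    n_pairs = 0
    for (ts, te), (qs, qe) in zip(blocks_ref, blocks_read):
        n_pairs += te - ts
        matches += sum(ref_seq[ts + k] == read_seq[qs + k] for k in range(te - ts))
    t_span = int(blocks_ref[-1][1] - blocks_ref[0][0])
    q_span = int(blocks_read[-1][1] - blocks_read[0][0])
    columns = t_span + q_span - n_pairs  # internal gaps count as columns
    return matches / columns, t_span


def _ladder_level(identity: float) -> str:
    if identity >= SPECIES_IDENTITY:
        return "species"
    if identity >= GENUS_IDENTITY:
        return "genus"
    if identity >= FAMILY_IDENTITY:
        return "family"
    return "unassigned"


def classify_read(
    read: ReadRecord,
    references: list[Reference],
    min_overlap: int = MIN_OVERLAP_BP,
) -> AssignmentResult:
    """Assign a read against the references via the tiered identity ladder."""
    if not references:
        raise ValueError("references must not be empty")
    if not read.sequence:
        raise ValueError("empty read")

    scored = [(ref, *_identity_and_overlap(ref.sequence, read.sequence)) for ref in references]
    best_identity = max(s[1] for s in scored)
    best = [s for s in scored if s[1] == best_identity]
    overlap = max(s[2] for s in best)

    if overlap < min_overlap:
        return AssignmentResult(read.read_id, "unassigned", None, best_identity, overlap)

    level = _ladder_level(best_identity)
    if level == "unassigned":
        return AssignmentResult(read.read_id, "unassigned", None, best_identity, overlap)

    if len(best) > 1:
        # tie: deepest level on which the tied references agree, never species
        # unless the tied references are the same species
        for candidate in LEVELS[:-1]:
            if _LEVEL_DEPTH[candidate] < _LEVEL_DEPTH[level]:
                continue  # identity too low for this depth
            taxa = {ref.taxon_at(candidate) for ref, _, _ in best}
            if len(taxa) == 1:
                return AssignmentResult(
                    read.read_id, candidate, taxa.pop(), best_identity, overlap
                )
        return AssignmentResult(read.read_id, "unassigned", None, best_identity, overlap)

    ref = best[0][0]
    return AssignmentResult(read.read_id, level, ref.taxon_at(level), best_identity, overlap)


def compute_read_fractions(
    assignments: list[AssignmentResult],
) -> dict[str, float] | None:
    """Per-species read fractions from species-level assignments only.

    Returns None when no read was assigned at species level (the fraction
    is then undefined, reported as missing).
    """
    counts: dict[str, int] = {}
    for a in assignments:
        if a.level == "species" and a.taxon is not None:
            counts[a.taxon] = counts.get(a.taxon, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return None
    return {taxon: n / total for taxon, n in counts.items()}


def load_references(fasta_path) -> list[Reference]:
    """Load reference amplicons from FASTA.

    Taxonomy is read from ``key=value`` tokens in the description
    (``species=...``, ``genus=...``, ``family=...``); missing keys fall
    back to the record id.
    """
    from Bio import SeqIO

    refs = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        tokens = dict(
            tok.split("=", 1) for tok in record.description.split() if "=" in tok
        )
        refs.append(
            Reference(
                name=record.id,
                sequence=str(record.seq).upper(),
                species=tokens.get("species", record.id),
                genus=tokens.get("genus", record.id),
                family=tokens.get("family", record.id),
            )
        )
    if not refs:
        raise ValueError(f"no references found in {fasta_path}")
    return refs


def bundled_references() -> list[Reference]:
    """The two bundled synthetic herring/sprat reference amplicons.

    These are synthetic stand-ins with clupeid-like pairwise divergence
    (~12%), not real mitogenome sequences; real references may be supplied
    to :func:`load_references` by path.
    """
    path = resources.files("ednabycatch.data") / "synthetic_references.fasta"
    with resources.as_file(path) as p:
        return load_references(p)
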
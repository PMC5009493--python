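"""Reduce sequence data to networked OTUs and match OTUs to reference genomes.

The first two pipeline stages: (1) keep only the 16S rDNA sequences for OTUs
that actually appear in the user's association network; (2) assign each OTU a
genome id by best local alignment against a reference FASTA of genome-derived
16S sequences, reporting the percent identity of the best hit so downstream
network plots can expose imperfect OTU-genome pairings.

Alignment uses BLASTN-like scoring (match +2, mismatch −3, gap open −5, gap
extend −2) via Biopython's PairwiseAligner in local (Smith–Waterman) mode.
Percent identity follows BLAST's ``pident`` convention: identical columns
divided by total alignment columns, gap columns included.
"""

from __future__ import annotations

import logging
import math
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, MissingSequenceError, PairmintError

__all__ = [
    "AssociationTable",
    "SequenceRecord",
    "GenomeMatch",
    "read_associations",
    "read_fasta",
    "write_fasta",
    "filter_sequences",
    "match_genomes",
    "alignment_score",
    "write_matches",
    "read_matches",
]

logger = logging.getLogger(__name__)

MATCH_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN_SCORE = -5.0   # score of the first residue of a gap
GAP_EXTEND_SCORE = -2.0  # score of each further residue
MIN_QUERY_LENGTH = 16

_UNAMBIGUOUS = "ACGT"


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (IUPAC alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} must be non-empty")


@dataclass
class GenomeMatch:
    """Best reference genome for one OTU, with BLAST-style percent identity."""

    otu_id: str
    genome_id: str
    percent_identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )


class AssociationTable:
    """Undirected, deduplicated OTU-OTU association weights."""

    def __init__(self, rows: Iterable[tuple[str, str, float]]):
        self.rows: list[tuple[str, str, float]] = []
        seen: set[frozenset[str]] = set()
        for a, b, w in rows:
            if a == b:
                logger.warning("dropping self-association for OTU %r", a)
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            if not math.isfinite(w):
                raise FormatError(f"non-finite association weight for pair ({a}, {b})")
            seen.add(key)
            self.rows.append((a, b, float(w)))

    def otu_ids(self) -> list[str]:
        """Distinct OTU ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for a, b, _ in self.rows:
            for o in (a, b):
                if o not in seen:
                    seen.add(o)
                    out.append(o)
        return out

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def read_associations(path: str | Path) -> AssociationTable:
    """Read a TSV of ``otu_a<TAB>otu_b<TAB>weight`` rows.

    A header row is auto-detected (non-numeric third field on the first line).
    Duplicate unordered pairs keep their first occurrence; self-pairs are
    dropped with a warning.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected ≥3 tab-separated columns, got {len(fields)}"
                )
            try:
                weight = float(fields[2])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header row
                raise FormatError(
                    f"{path}:{lineno}: non-numeric association weight {fields[2]!r}"
                ) from None
            rows.append((fields[0], fields[1], weight))
    return AssociationTable(rows)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate sequence ids {dupes}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> Path:
    path = Path(path)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )
    return path


def filter_sequences(
    seqs: Sequence[SequenceRecord], assoc: AssociationTable
) -> list[SequenceRecord]:
    """Keep exactly the records whose id appears in the association network.

    Input order is preserved.  Any networked OTU without a sequence is an
    error (the pipeline could not analyze that node).
    """
    wanted = set(assoc.otu_ids())
    have = {r.id for r in seqs}
    missing = sorted(wanted - have)
    if missing:
        raise MissingSequenceError(
            f"association table references OTUs with no sequence: {missing}"
        )
    return [r for r in seqs if r.id in wanted]


# ---------------------------------------------------------------------------
# Genome matching
# ---------------------------------------------------------------------------


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _make_aligner(alphabet: str) -> Align.PairwiseAligner:
    letters = sorted(set(alphabet) | set(_UNAMBIGUOUS))
    matrix = substitution_matrices.Array(alphabet="".join(letters), dims=2)
    for a in letters:
        for b in letters:
            # Ambiguity codes never score as matches.
            matrix[a, b] = (
                MATCH_SCORE if (a == b and a in _UNAMBIGUOUS) else MISMATCH_SCORE
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    return aligner


def alignment_score(query: str, subject: str) -> float:
    """Best local alignment score between two raw sequences."""
    q, s = _normalize(query), _normalize(subject)
    aligner = _make_aligner(q + s)
    return float(aligner.score(q, s))


def match_genomes(
    queries: Sequence[SequenceRecord], reference: Sequence[SequenceRecord]
) -> list[GenomeMatch]:
    """Best-hit genome assignment for each query by local alignment.

    For each query the reference with the highest Smith–Waterman score wins;
    equal scores are broken in favor of the reference listed first.  Percent
    identity is 100 × identical columns / alignment columns of the best local
    alignment.  Queries shorter than 16 nt are skipped with a warning.
    """
    if not reference:
        raise PairmintError("reference set is empty; cannot match genomes")
    ref_norm = [(r.id, _normalize(r.sequence)) for r in reference]
    matches: list[GenomeMatch] = []
    for query in queries:
        q = _normalize(query.sequence)
        if len(q) < MIN_QUERY_LENGTH:
            logger.warning(
                "query %r is shorter than %d nt; skipped", query.id, MIN_QUERY_LENGTH
            )
            continue
        aligner = _make_aligner(q + "".join(s for _, s in ref_norm))
        best_score = -math.inf
        best_id = ref_norm[0][0]
        best_seq = ref_norm[0][1]
        for gid, ref_seq in ref_norm:
            score = float(aligner.score(q, ref_seq))
            if score > best_score:  # strict: first listed wins ties
                best_score, best_id, best_seq = score, gid, ref_seq
        matches.append(
            GenomeMatch(query.id, best_id, _percent_identity(aligner, q, best_seq))
        )
    return matches


def _percent_identity(aligner: Align.PairwiseAligner, q: str, s: str) -> float:
    alignments = aligner.align(q, s)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0
    top, bottom = str(aln[0]), str(aln[1])
    columns = len(top)
    if columns == 0:
        return 0.0
    identical = sum(
        1 for a, b in zip(top, bottom) if a == b and a in _UNAMBIGUOUS
    )
    return 100.0 * identical / columns


def write_matches(matches: Sequence[GenomeMatch], path: str | Path) -> Path:
    """Write the percent-similarity table as TSV."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("otu_id\tgenome_id\tpercent_identity\n")
        for m in matches:
            handle.write(f"{m.otu_id}\t{m.genome_id}\t{m.percent_identity:.6g}\n")
    return path


def read_matches(path: str | Path) -> list[GenomeMatch]:
    path = Path(path)
    matches: list[GenomeMatch] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("otu_id"):
            raise FormatError(f"{path}: expected header 'otu_id\\tgenome_id\\t...'")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            matches.append(GenomeMatch(fields[0], fields[1], float(fields[2])))
    return matches


def blast_match_genomes(
    query_fasta: str | Path,
    reference_fasta: str | Path,
    blastn_bin: str = "blastn",
) -> list[GenomeMatch]:
    """Optional hook: best-hit matching via an external ``blastn`` binary.

    Provided for users with large reference sets; the built-in
    :func:`match_genomes` is the default and the only path exercised by the
    test suite.
    """
    with tempfile.NamedTemporaryFile(suffix=".tsv", mode="r") as out:
        subprocess.run(
            [
                blastn_bin,
                "-query",
                str(query_fasta),
                "-subject",
                str(reference_fasta),
                "-outfmt",
                "6 qseqid sseqid pident bitscore",
            ],
            check=True,
            stdout=open(out.name, "w"),
        )
        best: dict[str, tuple[float, GenomeMatch]] = {}
        for line in open(out.name):
            qid, sid, pident, bits = line.split("\t")
            score = float(bits)
            if qid not in best or score > best[qid][0]:
                best[qid] = (score, GenomeMatch(qid, sid, float(pident)))
    return [m for _, m in best.values()]
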
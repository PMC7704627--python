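"""Data model and plain-text readers/writers for comparative promoter studies.

A *study* pairs one upstream promoter window per species (FASTA) with a
species metadata table (TSV) carrying the binary phenotype of interest —
here, whether telomerase is transcriptionally active in somatic cells —
plus position count matrices describing transcription-factor binding
motifs in a TRANSFAC-style plain-text dialect.

Coordinate convention
---------------------
Positions are 1-based negative *upstream offsets* relative to the
translation start: offset -1 is the base immediately 5' of the ATG, and a
promoter of length L spans offsets -L .. -1.  Internally, forward-strand
string index ``i`` of a sequence of length L corresponds to offset
``i - L``.  A window of length ``w`` whose 5'-most forward-strand base
sits at offset ``v`` occupies ``v .. v + w - 1``.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"

MAX_PROMOTER_LENGTH = 1000

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over the A,C,G,T,N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def index_to_offset(index: int, seq_len: int) -> int:
    """Forward-strand string index -> upstream offset (-seq_len .. -1)."""
    return index - seq_len


def offset_to_index(offset: int, seq_len: int) -> int:
    """Upstream offset -> forward-strand string index (0 .. seq_len-1)."""
    return offset + seq_len


class StudyError(ValueError):
    """Raised when study inputs are malformed or inconsistent."""


class MatrixParseError(StudyError):
    """Raised when a count-matrix file cannot be parsed."""


@dataclass(frozen=True)
class SpeciesMeta:
    """One species of the study and its phenotype label.

    ``telomerase_state`` is ``"active"`` or ``"inactive"``; ``group_label``
    is an optional free-text grouping (e.g. cluster names assigned after
    the fact) that the statistics never consult.
    """

    species_id: str
    telomerase_state: str
    display_name: str = ""
    group_label: str = ""

    def __post_init__(self):
        if self.telomerase_state not in (ACTIVE, INACTIVE):
            raise StudyError(
                f"telomerase_state must be '{ACTIVE}' or '{INACTIVE}', "
                f"got {self.telomerase_state!r} for {self.species_id!r}"
            )


@dataclass(frozen=True)
class PromoterSequence:
    """An upstream promoter window (<= 1000 bp) for one species.

    ``bases`` is uppercase over {A,C,G,T,N}; the 3'-most base is the one
    adjacent to the translation start (offset -1).
    """

    species_id: str
    bases: str
    origin_note: str = ""

    def __post_init__(self):
        if not self.bases:
            raise StudyError(f"empty promoter sequence for {self.species_id!r}")
        if len(self.bases) > MAX_PROMOTER_LENGTH:
            raise StudyError(
                f"promoter {self.species_id!r} is {len(self.bases)} bp; "
                f"upstream windows are at most {MAX_PROMOTER_LENGTH} bp"
            )
        if re.search("[^ACGTN]", self.bases):
            raise StudyError(
                f"promoter {self.species_id!r} contains characters outside "
                "A,C,G,T,N (normalise on read)"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def codes(self) -> np.ndarray:
        """Integer encoding A=0 C=1 G=2 T=3, N=-1."""
        return _encode(self.bases)


_ENCODE_TABLE = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i


def _encode(bases: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


CORE_LENGTH = 5


@dataclass
class FrequencyMatrix:
    """Position count matrix of a binding motif with derived scoring terms.

    ``counts`` holds per-position base counts (or frequencies) in A,C,G,T
    column order, one row per motif position.  Frequencies are the
    pseudocount-adjusted, row-normalised counts.  The information vector

        I(i) = sum_b f(i,b) * ln(4 * f(i,b)),   with 0*ln(0) = 0,

    weighs each position by its conservation (0 for a uniform position,
    ln 4 for a fully conserved one) and drives Match-style similarity
    scoring.  The *core* is the run of ``min(5, L)`` consecutive positions
    maximising the summed information, leftmost on ties.
    """

    matrix_id: str
    counts: np.ndarray
    factor_name: str = ""
    pseudocount: float = 0.0

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise StudyError(
                f"matrix {self.matrix_id!r}: counts must be an Lx4 array, "
                f"got shape {counts.shape}"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise StudyError(f"matrix {self.matrix_id!r}: counts must be finite and non-negative")
        if self.pseudocount < 0:
            raise StudyError(f"matrix {self.matrix_id!r}: pseudocount must be non-negative")
        self.counts = counts
        rowsums = counts.sum(axis=1) + 4 * self.pseudocount
        if np.any(rowsums <= 0):
            bad = int(np.nonzero(rowsums <= 0)[0][0])
            raise StudyError(
                f"matrix {self.matrix_id!r}: position {bad + 1} has zero "
                "total count and pseudocount 0"
            )
        if not np.any(self.information > 0):
            raise StudyError(
                f"matrix {self.matrix_id!r}: all positions are uniform; the "
                "similarity score is undefined for a fully degenerate matrix"
            )

    def __len__(self) -> int:
        return self.counts.shape[0]

    @cached_property
    def frequencies(self) -> np.ndarray:
        """Row-stochastic Lx4 frequency matrix f(i, b)."""
        adj = self.counts + self.pseudocount
        return adj / adj.sum(axis=1, keepdims=True)

    @cached_property
    def information(self) -> np.ndarray:
        """Per-position information vector I(i), each entry in [0, ln 4]."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
        return terms.sum(axis=1)

    @cached_property
    def core_start(self) -> int:
        """Start index of the core window (leftmost max-information run)."""
        w = min(CORE_LENGTH, len(self))
        sums = np.convolve(self.information, np.ones(w), mode="valid")
        # leftmost tie within floating tolerance
        return int(np.nonzero(sums >= sums.max() - 1e-12)[0][0])

    @property
    def core_slice(self) -> slice:
        w = min(CORE_LENGTH, len(self))
        return slice(self.core_start, self.core_start + w)

    @cached_property
    def consensus(self) -> str:
        """Per-position argmax base (leftmost base on ties)."""
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=1))


# ---------------------------------------------------------------------------
# FASTA promoters

def read_promoters(fasta_text: str) -> list[PromoterSequence]:
    """Parse promoter FASTA text into :class:`PromoterSequence` records.

    The first whitespace-delimited header token is the species id.  Bases
    are uppercased, U is mapped to T, and any other character outside
    {A,C,G,T} is mapped to N with a logged warning.  Duplicate species ids
    and records longer than 1000 bp are errors.
    """
    records: list[PromoterSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_stdio.StringIO(fasta_text), "fasta"):
        species_id = rec.id
        if species_id in seen:
            raise StudyError(f"duplicate species_id in FASTA: {species_id!r}")
        seen.add(species_id)
        bases = str(rec.seq).upper().replace("U", "T")
        cleaned = re.sub("[^ACGTN]", "N", bases)
        n_replaced = sum(a != b for a, b in zip(bases, cleaned))
        if n_replaced:
            logger.warning(
                "promoter %s: %d non-ACGT characters mapped to N",
                species_id, n_replaced,
            )
        note = rec.description[len(rec.id):].strip()
        records.append(PromoterSequence(species_id=species_id, bases=cleaned, origin_note=note))
    return records


def write_promoters(promoters: list[PromoterSequence], width: int = 60) -> str:
    """Serialise promoters as FASTA; byte-stable for identical inputs."""
    chunks = []
    for p in promoters:
        header = f">{p.species_id}" + (f" {p.origin_note}" if p.origin_note else "")
        body = "\n".join(p.bases[i:i + width] for i in range(0, len(p.bases), width))
        chunks.append(f"{header}\n{body}\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# Species metadata TSV

_STATE_TOKENS = {
    "active": ACTIVE, "+": ACTIVE,
    "inactive": INACTIVE, "-": INACTIVE, "−": INACTIVE, "–": INACTIVE,
}


def parse_state(token: str) -> str:
    """Parse a telomerase-state token (active/inactive/+/−, any case)."""
    state = _STATE_TOKENS.get(str(token).strip().lower())
    if state is None:
        raise StudyError(f"unknown telomerase_state token: {token!r}")
    return state


def read_species_meta(tsv_text: str) -> list[SpeciesMeta]:
    """Parse the species metadata TSV.

    Requires header columns ``species_id`` and ``telomerase_state``;
    ``display_name`` and ``group_label`` are optional.
    """
    import pandas as pd

    df = pd.read_csv(_stdio.StringIO(tsv_text), sep="\t", dtype=str).fillna("")
    for col in ("species_id", "telomerase_state"):
        if col not in df.columns:
            raise StudyError(f"metadata TSV is missing required column {col!r}")
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        sid = str(row.species_id).strip()
        if sid in seen:
            raise StudyError(f"duplicate species_id in metadata: {sid!r}")
        seen.add(sid)
        records.append(SpeciesMeta(
            species_id=sid,
            telomerase_state=parse_state(row.telomerase_state),
            display_name=str(getattr(row, "display_name", "")),
            group_label=str(getattr(row, "group_label", "")),
        ))
    return records


def write_species_meta(meta: list[SpeciesMeta]) -> str:
    lines = ["species_id\ttelomerase_state\tdisplay_name\tgroup_label"]
    for m in meta:
        lines.append(f"{m.species_id}\t{m.telomerase_state}\t{m.display_name}\t{m.group_label}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Count matrices (TRANSFAC-style dialect)

_NUMERIC = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _is_number(tok: str) -> bool:
    return bool(_NUMERIC.match(tok))


def read_matrices(matrix_text: str, pseudocount: float = 0.0) -> list[FrequencyMatrix]:
    """Parse one or more matrices from TRANSFAC-style text.

    Recognised lines: ``ID <token>`` opens a matrix; ``NA <name>`` sets the
    factor name; ``P0 ...`` column headers and ``XX`` separators are
    skipped; numbered rows carry a position index followed by exactly four
    counts (A C G T) and an optional consensus letter; ``//`` closes a
    matrix.  A bare four-column dialect without ``ID`` lines is accepted by
    :func:`read_matrix` where the caller supplies the id.
    """
    matrices: list[FrequencyMatrix] = []
    cur_id: str | None = None
    cur_name = ""
    rows: list[list[float]] = []

    def finalize(lineno: int):
        nonlocal cur_id, cur_name, rows
        if cur_id is None and not rows:
            return
        if cur_id is None:
            raise MatrixParseError(f"line {lineno}: count rows without an ID line")
        if not rows:
            raise MatrixParseError(f"line {lineno}: matrix {cur_id!r} has no count rows")
        matrices.append(FrequencyMatrix(
            matrix_id=cur_id, counts=np.array(rows), factor_name=cur_name,
            pseudocount=pseudocount,
        ))
        cur_id, cur_name, rows = None, "", []

    for lineno, raw in enumerate(matrix_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        key = tokens[0].upper()
        if key == "ID":
            finalize(lineno)
            if len(tokens) < 2:
                raise MatrixParseError(f"line {lineno}: ID line without an identifier")
            cur_id = tokens[1]
        elif key == "NA":
            cur_name = " ".join(tokens[1:])
        elif key in ("P0", "PO", "XX", "BF", "CC", "DE"):
            continue
        elif key == "//":
            finalize(lineno)
        else:
            numeric = [t for t in tokens if _is_number(t)]
            # numbered row: index + 4 counts (+ optional consensus letter)
            if _is_number(tokens[0]) and len(numeric) >= 1 and cur_id is not None:
                counts = numeric[1:]
            else:
                counts = numeric
            if len(counts) != 4:
                raise MatrixParseError(
                    f"line {lineno}: expected 4 counts (A C G T), got "
                    f"{len(counts)}: {line!r}"
                )
            rows.append([float(c) for c in counts])
    finalize(lineno if matrix_text.strip() else 0)
    return matrices


def read_matrix(matrix_text: str, matrix_id: str | None = None,
                pseudocount: float = 0.0) -> FrequencyMatrix:
    """Parse a single matrix; ``matrix_id`` names a bare 4-column dialect."""
    if matrix_id is not None and "ID " not in matrix_text and "id " not in matrix_text:
        rows = []
        for lineno, raw in enumerate(matrix_text.splitlines(), start=1):
            line = raw.strip()
            if not line or line in ("//",) or line.startswith("#"):
                continue
            tokens = [t for t in line.split() if _is_number(t)]
            if len(tokens) != 4:
                raise MatrixParseError(
                    f"line {lineno}: expected 4 counts (A C G T), got "
                    f"{len(tokens)}: {line!r}"
                )
            rows.append([float(t) for t in tokens])
        if not rows:
            raise MatrixParseError("no count rows found")
        return FrequencyMatrix(matrix_id=matrix_id, counts=np.array(rows),
                               pseudocount=pseudocount)
    matrices = read_matrices(matrix_text, pseudocount=pseudocount)
    if len(matrices) != 1:
        raise MatrixParseError(f"expected exactly one matrix, found {len(matrices)}")
    if matrix_id is not None:
        matrices[0].matrix_id = matrix_id
    return matrices[0]


def write_matrices(matrices: list[FrequencyMatrix]) -> str:
    """Serialise matrices in the TRANSFAC-style dialect read_matrices accepts."""
    chunks = []
    for m in matrices:
        lines = [f"ID {m.matrix_id}"]
        if m.factor_name:
            lines.append(f"NA {m.factor_name}")
        lines.append("P0      A      C      G      T")
        for i, row in enumerate(m.counts, start=1):
            cells = "  ".join(f"{c:g}".rjust(5) for c in row)
            lines.append(f"{i:02d}  {cells}")
        lines.append("//")
        chunks.append("\n".join(lines) + "\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# Study assembly

@dataclass
class Study:
    """Validated pairing of promoters with species metadata.

    Every promoter maps to exactly one metadata row and vice versa; this
    bijection is enforced at assembly so group labels can never silently
    drift from the sequences.
    """

    promoters: dict[str, PromoterSequence] = field(default_factory=dict)
    meta: dict[str, SpeciesMeta] = field(default_factory=dict)

    @property
    def species_ids(self) -> list[str]:
        return list(self.meta)

    def states(self) -> dict[str, str]:
        return {sid: m.telomerase_state for sid, m in self.meta.items()}


def assemble_study(promoters: list[PromoterSequence],
                   meta: list[SpeciesMeta]) -> Study:
    """Pair promoters with metadata, enforcing a species bijection."""
    prom_ids = {p.species_id for p in promoters}
    meta_ids = {m.species_id for m in meta}
    missing_meta = sorted(prom_ids - meta_ids)
    missing_prom = sorted(meta_ids - prom_ids)
    if missing_meta:
        raise StudyError(f"promoters without metadata: {', '.join(missing_meta)}")
    if missing_prom:
        raise StudyError(f"metadata without promoters: {', '.join(missing_prom)}")
    prom_by_id = {p.species_id: p for p in promoters}
    return Study(
        promoters={m.species_id: prom_by_id[m.species_id] for m in meta},
        meta={m.species_id: m for m in meta},
    )
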
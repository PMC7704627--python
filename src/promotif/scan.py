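"""Match-style and TFbind-style PWM similarity scoring and promoter scanning.

Both dialects share one information-weighted kernel.  For a matrix with
frequencies ``f(i, b)`` and information vector ``I(i)`` (see
:class:`promotif.io.FrequencyMatrix`), a window ``w`` of matrix length is
scored

    Current = sum_i I(i) * f(i, w_i)
    MSS     = (Current - Min) / (Max - Min)

where ``Min``/``Max`` substitute the per-position minimum/maximum
frequency.  MSS is 1 exactly on a per-position argmax (consensus) window
and 0 on a per-position argmin window.  The *core similarity* CSS applies
the same normalised formula restricted to the matrix core (the
min(5, L)-position run of maximal summed information).

``match`` mode requires CSS >= core_cutoff (default 1.0) and
MSS >= mss_cutoff (default 0.94); ``tfbind`` mode applies a single
full-matrix MSS cutoff (default 0.9) with no core filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import (
    BASES,
    FrequencyMatrix,
    PromoterSequence,
    _encode,
    revcomp,
)

logger = logging.getLogger(__name__)

MATCH_CORE_CUTOFF = 1.0
MATCH_MSS_CUTOFF = 0.94
TFBIND_MSS_CUTOFF = 0.9


class UnscorableWindowError(ValueError):
    """Signalled when a window contains N and therefore has no score."""


@dataclass(frozen=True)
class ScanProfile:
    """Scoring mode and cut-offs for a scan.

    ``match`` filters on core similarity (default cut-off 1.0) and overall
    matrix similarity (default 0.94); ``tfbind`` filters on the overall
    similarity alone (default 0.9) and ignores ``core_cutoff``.
    """

    mode: str = "match"
    core_cutoff: float = MATCH_CORE_CUTOFF
    mss_cutoff: float = field(default=None)  # type: ignore[assignment]
    both_strands: bool = True

    def __post_init__(self):
        if self.mode not in ("match", "tfbind"):
            raise ValueError(f"mode must be 'match' or 'tfbind', got {self.mode!r}")
        if self.mss_cutoff is None:
            object.__setattr__(
                self, "mss_cutoff",
                MATCH_MSS_CUTOFF if self.mode == "match" else TFBIND_MSS_CUTOFF,
            )
        for name in ("core_cutoff", "mss_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class MotifHit:
    """One above-cut-off window.

    ``offset`` is the upstream offset of the window's 5'-most base on the
    *forward* strand regardless of hit strand; ``css`` is None in tfbind
    mode.
    """

    matrix_id: str
    species_id: str
    offset: int
    strand: str
    mss: float
    css: float | None = None

    def sort_key(self):
        return (self.matrix_id, self.species_id, self.offset, self.strand)


# ---------------------------------------------------------------------------
# scoring kernel

def _kernel(matrix: FrequencyMatrix):
    """Per-position weighted score table and Min/Max sums (full + core)."""
    f = matrix.frequencies
    info = matrix.information
    table = info[:, None] * f  # L x 4
    lo = (info * f.min(axis=1)).sum()
    hi = (info * f.max(axis=1)).sum()
    core = matrix.core_slice
    core_lo = (info[core] * f[core].min(axis=1)).sum()
    core_hi = (info[core] * f[core].max(axis=1)).sum()
    return table, lo, hi, core_lo, core_hi


def information_vector(matrix: FrequencyMatrix) -> np.ndarray:
    """Per-position information I(i) = sum_b f(i,b) ln(4 f(i,b))."""
    return matrix.information.copy()


def _check_window(matrix: FrequencyMatrix, window: str) -> np.ndarray:
    if len(window) != len(matrix):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(matrix)}"
        )
    codes = _encode(window.upper())
    if np.any(codes < 0):
        raise UnscorableWindowError(f"window {window!r} contains non-ACGT bases")
    return codes


def matrix_similarity(matrix: FrequencyMatrix, window: str) -> float:
    """Normalised information-weighted similarity MSS in [0, 1]."""
    codes = _check_window(matrix, window)
    table, lo, hi, _, _ = _kernel(matrix)
    current = table[np.arange(len(matrix)), codes].sum()
    return float((current - lo) / (hi - lo))


def core_similarity(matrix: FrequencyMatrix, window: str) -> float:
    """Similarity restricted to the matrix core (min(5, L) positions)."""
    codes = _check_window(matrix, window)
    table, _, _, core_lo, core_hi = _kernel(matrix)
    core = matrix.core_slice
    idx = np.arange(len(matrix))[core]
    current = table[idx, codes[core]].sum()
    return float((current - core_lo) / (core_hi - core_lo))


# ---------------------------------------------------------------------------
# scanning

def _scan_codes(matrix: FrequencyMatrix, codes: np.ndarray):
    """Score every window of an encoded strand; returns (mss, css, valid)."""
    L = len(matrix)
    table, lo, hi, core_lo, core_hi = _kernel(matrix)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    pos = np.arange(L)
    current = table[pos[None, :], safe].sum(axis=1)
    mss = (current - lo) / (hi - lo)
    core = matrix.core_slice
    core_current = table[pos[core][None, :], safe[:, core]].sum(axis=1)
    css = (core_current - core_lo) / (core_hi - core_lo)
    return mss, css, valid


def scan_sequence(matrix: FrequencyMatrix, promoter: PromoterSequence,
                  profile: ScanProfile) -> list[MotifHit]:
    """All above-cut-off windows of one promoter, both strands by default.

    Windows containing N are skipped (counted to the module logger, not
    scored).  Hits are sorted by forward-strand offset then strand; a
    promoter shorter than the matrix yields an empty list.
    """
    L = len(matrix)
    n = len(promoter)
    if n < L:
        return []
    strands = ["+", "-"] if profile.both_strands else ["+"]
    hits: list[MotifHit] = []
    n_unscorable = 0
    for strand in strands:
        seq = promoter.bases if strand == "+" else revcomp(promoter.bases)
        mss, css, valid = _scan_codes(matrix, _encode(seq))
        n_unscorable += int((~valid).sum())
        keep = valid & (mss >= profile.mss_cutoff)
        if profile.mode == "match":
            keep &= css >= profile.core_cutoff
        for j in np.nonzero(keep)[0]:
            start = int(j) if strand == "+" else n - L - int(j)
            hits.append(MotifHit(
                matrix_id=matrix.matrix_id,
                species_id=promoter.species_id,
                offset=start - n,
                strand=strand,
                mss=float(mss[j]),
                css=float(css[j]) if profile.mode == "match" else None,
            ))
    if n_unscorable:
        logger.info(
            "scan %s x %s: %d unscorable windows (N overlap)",
            matrix.matrix_id, promoter.species_id, n_unscorable,
        )
    hits.sort(key=lambda h: (h.offset, 0 if h.strand == "+" else 1))
    return hits


def unscorable_window_count(matrix: FrequencyMatrix, promoter: PromoterSequence,
                            both_strands: bool = True) -> int:
    """Number of windows skipped for containing N (both strands pooled)."""
    L = len(matrix)
    if len(promoter) < L:
        return 0
    codes = promoter.codes
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    per_strand = int((windows < 0).any(axis=1).sum())
    return per_strand * (2 if both_strands else 1)


def scan_study(matrices: list[FrequencyMatrix],
               promoters: list[PromoterSequence],
               profile: ScanProfile) -> list[MotifHit]:
    """Concatenated scans over all matrix x promoter pairs.

    Output is deterministically ordered by (matrix_id, species_id, offset,
    strand).
    """
    hits: list[MotifHit] = []
    for matrix in matrices:
        for promoter in promoters:
            hits.extend(scan_sequence(matrix, promoter, profile))
    hits.sort(key=MotifHit.sort_key)
    return hits


# ---------------------------------------------------------------------------
# serialisation

HIT_COLUMNS = ("matrix_id", "species_id", "offset", "strand", "mss", "css")


def write_hits(hits: list[MotifHit]) -> str:
    """Hits as TSV; css column empty in tfbind mode. Byte-stable."""
    lines = ["\t".join(HIT_COLUMNS)]
    for h in hits:
        css = "" if h.css is None else repr(h.css)
        lines.append(
            f"{h.matrix_id}\t{h.species_id}\t{h.offset}\t{h.strand}"
            f"\t{h.mss!r}\t{css}"
        )
    return "\n".join(lines) + "\n"


def read_hits(tsv_text: str) -> list[MotifHit]:
    lines = tsv_text.strip().splitlines()
    if not lines or lines[0].split("\t") != list(HIT_COLUMNS):
        raise ValueError("not a hits TSV (bad header)")
    hits = []
    for line in lines[1:]:
        mid, sid, off, strand, mss, css = line.split("\t")
        hits.append(MotifHit(
            matrix_id=mid, species_id=sid, offset=int(off), strand=strand,
            mss=float(mss), css=float(css) if css else None,
        ))
    return hits


def hits_to_bed(hits: list[MotifHit], matrices: list[FrequencyMatrix],
                promoter_lengths: dict[str, int]) -> str:
    """BED-like export with promoter-local 0-based half-open coordinates.

    chrom=species_id, name=matrix_id, score=round(1000*mss).
    """
    length = {m.matrix_id: len(m) for m in matrices}
    lines = []
    for h in hits:
        seq_len = promoter_lengths[h.species_id]
        start = h.offset + seq_len
        end = start + length[h.matrix_id]
        lines.append(
            f"{h.species_id}\t{start}\t{end}\t{h.matrix_id}"
            f"\t{round(1000 * h.mss)}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
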
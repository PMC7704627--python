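"""Positional distribution of motif hits along the upstream window.

Hits are binned by the upstream offset of their 5'-most forward-strand
base into fixed-width bins partitioning -1000..-1 (default width 50, so
"-200 to -151" is one bin), and stratified by telomerase state.  Minus-
strand hits are binned by the same forward coordinate, so the histogram
is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ACTIVE, SpeciesMeta, StudyError
from .scan import MotifHit

REGION_START = -1000  # inclusive 5' end of the histogram range
REGION_END = -1       # inclusive 3' end (base adjacent to the start codon)


@dataclass
class PositionHistogram:
    """Binned hit positions for one matrix, stratified by state.

    ``bin_edges`` lists (lo, hi) offset pairs, lo ascending from -1000;
    each bin covers offsets lo..hi inclusive (half-open [lo, hi+1) on the
    integer offset line, with the -1-adjacent bin closed at -1).
    Invariant: counts_all = counts_active + counts_inactive per bin.
    """

    matrix_id: str
    bin_edges: list[tuple[int, int]]
    counts_all: np.ndarray
    counts_active: np.ndarray
    counts_inactive: np.ndarray

    def mode_bin(self) -> tuple[int, int]:
        """Edges of the fullest bin (leftmost on ties)."""
        return self.bin_edges[int(np.argmax(self.counts_all))]


def position_histogram(hits: list[MotifHit], meta: list[SpeciesMeta],
                       bin_width: int = 50) -> dict[str, PositionHistogram]:
    """Per-matrix positional histograms over the -1000..-1 window.

    ``bin_width`` must divide 1000.  A hit is binned by its 5'-most-base
    offset; hits of species absent from the metadata are an error.
    """
    span = REGION_END - REGION_START + 1
    if bin_width < 1 or span % bin_width != 0:
        raise StudyError(f"bin_width must divide {span}, got {bin_width}")
    n_bins = span // bin_width
    edges = [(REGION_START + i * bin_width, REGION_START + (i + 1) * bin_width - 1)
             for i in range(n_bins)]
    state = {m.species_id: m.telomerase_state for m in meta}
    out: dict[str, PositionHistogram] = {}
    by_matrix: dict[str, list[MotifHit]] = {}
    for h in hits:
        if h.species_id not in state:
            raise StudyError(f"hit references unknown species {h.species_id!r}")
        by_matrix.setdefault(h.matrix_id, []).append(h)
    for mid in sorted(by_matrix):
        c_act = np.zeros(n_bins, dtype=int)
        c_inact = np.zeros(n_bins, dtype=int)
        for h in by_matrix[mid]:
            if not REGION_START <= h.offset <= REGION_END:
                continue
            b = (h.offset - REGION_START) // bin_width
            if state[h.species_id] == ACTIVE:
                c_act[b] += 1
            else:
                c_inact[b] += 1
        out[mid] = PositionHistogram(
            matrix_id=mid, bin_edges=edges, counts_all=c_act + c_inact,
            counts_active=c_act, counts_inactive=c_inact,
        )
    return out


def write_histograms(histograms: dict[str, PositionHistogram]) -> str:
    """Histograms as TSV (matrix_id, bin_lo, bin_hi, n_all, n_active, n_inactive)."""
    lines = ["matrix_id\tbin_lo\tbin_hi\tn_all\tn_active\tn_inactive"]
    for mid in sorted(histograms):
        h = histograms[mid]
        for (lo, hi), na, nact, nin in zip(h.bin_edges, h.counts_all,
                                           h.counts_active, h.counts_inactive):
            lines.append(f"{mid}\t{lo}\t{hi}\t{na}\t{nact}\t{nin}")
    return "\n".join(lines) + "\n"


def plot_histogram(hist: PositionHistogram, path: str) -> None:
    """Grouped bar plot of a matrix's positional distribution by stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = np.array([(lo + hi) / 2 for lo, hi in hist.bin_edges])
    width = (hist.bin_edges[0][1] - hist.bin_edges[0][0] + 1) * 0.28
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(centers - width, hist.counts_all, width=width, label="all",
           color="seagreen")
    ax.bar(centers, hist.counts_active, width=width, label="active",
           color="gold")
    ax.bar(centers + width, hist.counts_inactive, width=width,
           label="inactive", color="steelblue")
    ax.set_xlabel("upstream offset (bp)")
    ax.set_ylabel("predicted sites")
    ax.set_title(hist.matrix_id)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
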
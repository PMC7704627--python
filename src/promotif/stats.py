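"""Group-comparison statistics for site counts.

Two complementary tests compare telomerase-active with -inactive species
per matrix:

* a **three-hypothesis resampling bootstrap**: each of B replicates
  resamples both groups with replacement (each to its own size) and
  tallies whether the resampled inactive-group mean count is greater
  than, equal to, or less than the active-group mean.  The three tallies
  divided by B estimate the probabilities of the three hypotheses
  (inactive > active, inactive = active, inactive < active); a low value
  marks the corresponding hypothesis as failed.  The three probabilities
  sum to 1 exactly because every replicate lands in exactly one bin.

* a **two-tailed Fisher exact test** on presence/absence (count >= 1),
  suited to near-binary site distributions.  The p-value follows the
  standard "sum of small p" rule: the total hypergeometric probability of
  all tables with the observed margins whose probability does not exceed
  that of the observed table.  It is computed in exact rational
  arithmetic.

Mean comparison in the bootstrap uses integer cross-multiplication
(sum_inactive * n_active vs sum_active * n_inactive), so "equal" is exact
and never depends on a floating-point tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .io import ACTIVE, INACTIVE, SpeciesMeta, StudyError
from .scan import MotifHit

logger = logging.getLogger(__name__)


@dataclass
class SiteCountTable:
    """Species x matrix hit-count table with telomerase labels.

    ``counts`` rows follow metadata order; every metadata species has a
    row even with zero hits.  ``presence`` binarises at count >= 1.
    """

    counts: pd.DataFrame
    states: pd.Series

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    @property
    def matrix_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_counts(self, matrix_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(active counts, inactive counts) for one matrix."""
        col = self.counts[matrix_id]
        return (col[self.states == ACTIVE].to_numpy(),
                col[self.states == INACTIVE].to_numpy())

    def to_tsv(self) -> str:
        df = self.counts.copy()
        df.insert(0, "telomerase_state", self.states)
        return df.to_csv(sep="\t", index_label="species_id")


def count_table(hits: list[MotifHit], meta: list[SpeciesMeta],
                matrix_ids: list[str] | None = None) -> SiteCountTable:
    """Tabulate hits per (species, matrix); both strands pooled.

    ``matrix_ids`` fixes the column set and order (zero-filled where a
    matrix has no hits); by default columns are the sorted matrix ids
    present in the hit list.  Hits for species absent from the metadata
    are an error.
    """
    species = [m.species_id for m in meta]
    known = set(species)
    for h in hits:
        if h.species_id not in known:
            raise StudyError(f"hit references unknown species {h.species_id!r}")
    if matrix_ids is None:
        matrix_ids = sorted({h.matrix_id for h in hits})
    counts = pd.DataFrame(0, index=pd.Index(species, name="species_id"),
                          columns=list(matrix_ids), dtype=int)
    for h in hits:
        if h.matrix_id in counts.columns:
            counts.loc[h.species_id, h.matrix_id] += 1
    states = pd.Series({m.species_id: m.telomerase_state for m in meta},
                       name="telomerase_state").loc[species]
    return SiteCountTable(counts=counts, states=states)


# ---------------------------------------------------------------------------
# three-hypothesis bootstrap

@dataclass(frozen=True)
class BootstrapResult:
    """Tallies of the three hypotheses over B resampling replicates.

    ``p_greater`` estimates P(resampled inactive mean > active mean), and
    so on; tallies always sum to B, so the probabilities sum to 1 exactly
    (as rationals n/B).
    """

    matrix_id: str
    n_greater: int
    n_equal: int
    n_less: int
    B: int
    seed: int

    def __post_init__(self):
        assert self.n_greater + self.n_equal + self.n_less == self.B

    @property
    def p_greater(self) -> float:
        return self.n_greater / self.B

    @property
    def p_equal(self) -> float:
        return self.n_equal / self.B

    @property
    def p_less(self) -> float:
        return self.n_less / self.B

    def fractions(self) -> tuple[Fraction, Fraction, Fraction]:
        return (Fraction(self.n_greater, self.B),
                Fraction(self.n_equal, self.B),
                Fraction(self.n_less, self.B))


def bootstrap_three_way(counts, labels, B: int, seed, *,
                        matrix_id: str = "") -> BootstrapResult:
    """Three-hypothesis bootstrap comparing inactive vs active mean counts.

    ``counts`` are per-species non-negative integers aligned with
    ``labels`` (telomerase states).  Each replicate resamples both groups
    with replacement to their own sizes and compares the resampled group
    means exactly via integer cross-multiplication.  Deterministic given
    ``seed`` (an int or a numpy SeedSequence).
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    counts = np.asarray(counts)
    labels = np.asarray([str(s) for s in labels])
    if counts.shape != labels.shape:
        raise ValueError("counts and labels must have equal length")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.floor(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
    active = counts[labels == ACTIVE].astype(np.int64)
    inactive = counts[labels == INACTIVE].astype(np.int64)
    if active.size == 0 or inactive.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_i = active.size, inactive.size
    rng = np.random.default_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    idx_a = rng.integers(0, n_a, size=(B, n_a))
    idx_i = rng.integers(0, n_i, size=(B, n_i))
    sum_a = active[idx_a].sum(axis=1)
    sum_i = inactive[idx_i].sum(axis=1)
    # inactive mean vs active mean, exact: s_i/n_i <> s_a/n_a
    lhs = sum_i * n_a
    rhs = sum_a * n_i
    n_greater = int((lhs > rhs).sum())
    n_equal = int((lhs == rhs).sum())
    n_less = int((lhs < rhs).sum())
    return BootstrapResult(matrix_id=matrix_id, n_greater=n_greater,
                           n_equal=n_equal, n_less=n_less, B=B,
                           seed=int(seed_int))


# ---------------------------------------------------------------------------
# Fisher presence test

@dataclass(frozen=True)
class FisherResult:
    """Two-tailed Fisher exact test of presence vs telomerase state.

    ``table`` rows are (active, inactive), columns (present, absent).
    ``p_exact`` is the exact rational p; ``p_two_tailed`` its float value.
    ``note`` flags degenerate margins (all present or all absent), for
    which p is 1 by convention.
    """

    matrix_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_exact: Fraction
    note: str = ""

    @property
    def p_two_tailed(self) -> float:
        return float(self.p_exact)


def fisher_exact_two_tailed(table) -> Fraction:
    """Exact two-tailed Fisher p for a 2x2 table, "sum of small p" rule.

    Enumerates every table with the observed margins; returns the summed
    conditional hypergeometric probability of those no more probable than
    the observed table.  Exact rational arithmetic throughout.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n1, n2 = a + b, c + d  # row margins (group sizes)
    k = a + c              # first-column margin (present total)
    n = n1 + n2
    denom = comb(n, k)
    obs = Fraction(comb(n1, a) * comb(n2, c), denom)
    total = Fraction(0)
    for x in range(max(0, k - n2), min(k, n1) + 1):
        p = Fraction(comb(n1, x) * comb(n2, k - x), denom)
        if p <= obs:
            total += p
    return total


def fisher_presence(presence, labels, *, matrix_id: str = "") -> FisherResult:
    """Fisher exact presence test from per-species booleans and states."""
    presence = np.asarray(presence, dtype=bool)
    labels = np.asarray([str(s) for s in labels])
    if presence.shape != labels.shape:
        raise ValueError("presence and labels must have equal length")
    act = presence[labels == ACTIVE]
    inact = presence[labels == INACTIVE]
    if act.size == 0 or inact.size == 0:
        raise ValueError("both groups must be non-empty")
    table = ((int(act.sum()), int((~act).sum())),
             (int(inact.sum()), int((~inact).sum())))
    k = table[0][0] + table[1][0]
    n = act.size + inact.size
    if k == 0 or k == n:
        logger.info(
            "fisher %s: degenerate margins (present in %d/%d species); p = 1",
            matrix_id or "<unnamed>", k, n,
        )
        return FisherResult(matrix_id=matrix_id, table=table,
                            p_exact=Fraction(1), note="degenerate margins")
    return FisherResult(matrix_id=matrix_id, table=table,
                        p_exact=fisher_exact_two_tailed(table))


# ---------------------------------------------------------------------------
# per-matrix report

REPORT_COLUMNS = ("matrix_id", "p_greater", "p_equal", "p_less",
                  "fisher_p", "significant", "note")


def enrichment_report(table: SiteCountTable, B: int = 10_000,
                      seed: int | None = None, *, alpha: float = 0.05,
                      use_presence: bool = False,
                      fdr: bool = False) -> pd.DataFrame:
    """One row per matrix: bootstrap probabilities, Fisher p, and a flag.

    The ``significant`` flag requires agreement of both approaches at
    ``alpha``: some directional bootstrap probability below alpha *and*
    Fisher p below alpha.  The bootstrap runs on raw counts by default
    (``use_presence`` switches to 0/1 presence).  Per-matrix random
    streams are spawned deterministically from ``seed``.  ``fdr`` adds
    Benjamini-Hochberg q-values for the Fisher column.
    """
    if seed is None:
        raise ValueError("seed is required for a reproducible report")
    if table.counts.empty or not table.matrix_ids:
        raise ValueError("empty site-count table")
    children = np.random.SeedSequence(seed).spawn(len(table.matrix_ids))
    rows = []
    labels = table.states.to_numpy()
    for child, mid in zip(children, table.matrix_ids):
        col = table.counts[mid].to_numpy()
        data = (col >= 1).astype(int) if use_presence else col
        boot = bootstrap_three_way(data, labels, B=B, seed=child, matrix_id=mid)
        fisher = fisher_presence(col >= 1, labels, matrix_id=mid)
        note = ""
        if col.sum() == 0:
            note = "no hits"
        elif fisher.note:
            note = fisher.note
        significant = (
            not note
            and min(boot.p_greater, boot.p_less) < alpha
            and fisher.p_two_tailed < alpha
        )
        rows.append({
            "matrix_id": mid,
            "p_greater": boot.p_greater,
            "p_equal": boot.p_equal,
            "p_less": boot.p_less,
            "fisher_p": fisher.p_two_tailed,
            "significant": significant,
            "note": note,
        })
    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    if fdr:
        from scipy.stats import false_discovery_control

        report["fisher_q"] = false_discovery_control(report["fisher_p"], method="bh")
    return report


def write_report(report: pd.DataFrame) -> str:
    return report.to_csv(sep="\t", index=False, float_format="%.6g")
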